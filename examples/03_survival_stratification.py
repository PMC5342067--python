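"""Dichotomize MetDiv and test its prognostic value.

Generates a cohort, computes measured MetDiv per patient, finds the
optimal low/high cutpoint by the log-rank scan, and fits univariate and
multivariate Cox models.
"""

import pandas as pd

from metdiv import (CohortConfig, cox_fit, generate_cohort, grouped_univariate_fit,
                    iterative_threshold, median_split, patient_table, section_table)

cohort = generate_cohort(CohortConfig(n_patients=61, count_scale=0.002, seed=42))
profiles = (patient_table(section_table(cohort.cells))
            .merge(cohort.clinical, on="patient_id").set_index("patient_id"))

grp = iterative_threshold(profiles["metdiv"], profiles["os_months"],
                          profiles["os_event"], variable="metdiv")
print(f"MetDiv cutpoint {grp.threshold:.3f} -> low/high = {grp.n_low}/{grp.n_high}")
print(f"  ({grp.note})")

fit = grouped_univariate_fit(profiles["os_months"], profiles["os_event"],
                             grp.labels.loc[profiles.index], name="metdiv")
print(f"\nunivariate OS: HR {fit.hr['metdiv']:.2f} "
      f"({fit.ci_low['metdiv']:.2f}-{fit.ci_high['metdiv']:.2f}), "
      f"log-rank p = {fit.logrank_p:.2g}, concordance {fit.concordance:.2f}")
# HR > 1 means the high-MetDiv group has worse overall survival

age_grp = median_split(profiles["age"], variable="age")
design = pd.DataFrame({
    "metdiv_high": (grp.labels.loc[profiles.index] == "high").astype(int).to_numpy(),
    "age_high": (age_grp.labels.loc[profiles.index] == "high").astype(int).to_numpy(),
    "t": profiles["os_months"].to_numpy(), "e": profiles["os_event"].to_numpy(),
})
multi = cox_fit(design, "t", "e", ["metdiv_high", "age_high"])
for c in multi.covariates:
    print(f"multivariate {c}: HR {multi.hr[c]:.2f} "
          f"({multi.ci_low[c]:.2f}-{multi.ci_high[c]:.2f}), p = {multi.p[c]:.3g}")
# when MetDiv stays significant alongside age, its prognostic value is
# not explained by the clinical covariate; at n=61 individual cohorts
# can land near the significance boundary, as resampling stability
# analyses (example 04) make explicit
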