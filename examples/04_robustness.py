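"""Stability of the MetDiv survival analysis and of the score itself.

Three procedures: resample 70-100% of patients and re-test; recompute a
section's Shannon diversity on 75%/50% cell subsamples; split a section
in half and compare each half's diversity with the whole.
"""

from metdiv import (CohortConfig, cell_subsampling_stability, generate_cohort,
                    generate_section, half_split_stability, resampling_stability)

cohort = generate_cohort(CohortConfig(n_patients=200, seed=3), with_cells=False)
curve = resampling_stability(
    cohort.clinical["os_months"].to_numpy(), cohort.clinical["os_event"].to_numpy(),
    labels=cohort.truth_patients["true_group"].to_numpy(),
    fractions=(0.7, 0.8, 0.9, 1.0), n_reps=500, seed=0)
print("patient-fraction resampling (univariate OS, fixed labels):")
print(curve.as_frame().to_string(index=False))
# pct_significant is the share of resamples in which the high/low MetDiv
# log-rank test stays below alpha=0.05 -- a stable marker stays high

section = generate_section("omentum", CohortConfig(count_scale=0.05, seed=0), seed=9)
sub = cell_subsampling_stability(section, fractions=(1.0, 0.75, 0.5),
                                 n_reps=200, seed=1)
print(f"\ncell subsampling ({sub.n_cells:,} cells):")
print(sub.as_frame().to_string(index=False))
# the SD of Shannon under 50% subsampling is tiny: the score barely
# depends on how much of the section is analyzed

for orientation in ("vertical", "horizontal"):
    split = half_split_stability(section, orientation)
    print(f"\n{orientation} half-split: H_whole = {split.shannon_whole:.4f}, "
          f"|dH| halves = {split.abs_delta_a:.4f} / {split.abs_delta_b:.4f}")
# spatially homogeneous tissue gives near-zero |dH|; strong spatial
# segregation of cell types would inflate it
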