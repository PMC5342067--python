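# Methods

## Diversity scoring

Each section's composition is the plug-in (maximum-likelihood) estimate
p̂ = counts / total over the closed three-class vocabulary (cancer,
lymphocyte, stromal); classes absent from a section contribute p = 0.
Shannon diversity uses the natural logarithm (the ecology convention), so
its range is [0, ln 3], with 0·ln 0 := 0 by continuity. The Simpson index
is Σp², range [1/3, 1]. No small-sample bias correction is applied to the
Shannon estimate: real sections carry 10⁴–10⁵ classified nuclei, where
the plug-in bias (≈ (R−1)/2N nats) is far below every effect of interest;
the bias is visible only in deliberately tiny test fixtures.

MetDiv is the *unweighted* arithmetic mean of Shannon diversity over a
patient's non-ovary sections — sections are the unit of analysis, not
cells, so a large omentum block does not outweigh a small lymph-node
block. The sibling aggregates follow the same rule: mean including the
ovary, the n−1 sample SD of Shannon over non-ovary sections (undefined
with fewer than two), and per-class cell-ratio means. A patient needs at
least one non-ovary section for MetDiv; otherwise the profile is flagged
undefined, the patient is excluded downstream, and the exclusion is
logged. Exactly one ovary section is expected; more than one is an error
rather than a silent average.

Shannon and Simpson move in opposite directions, so their raw Pearson
correlation is negative. Because the orientation used when summarizing
their agreement is a reporting choice, `index_agreement` returns both
orientations (H vs D and H vs 1−D), the Spearman correlation, and the
absolute Pearson value.

## Stratification

Continuous per-patient scores are dichotomized; ties at any threshold go
to "high" (label = score ≥ threshold). Three rules:

- **median split** (stromal ratio, age): threshold = sample median;
- **tertile split** (lymphocyte ratio): threshold = 33.33rd percentile
  with linear interpolation, so group sizes are reproducible (n = 61 all
  distinct gives 20 or 21 in the lower group depending only on the
  interpolation convention, which is fixed and documented here);
- **iterative threshold** (MetDiv): a scan over all midpoints of
  consecutive sorted unique scores whose induced groups both exceed
  `min_group_frac · n` (default 0.1), selecting the cutpoint with the
  smallest two-group log-rank p; if no cutpoint is admissible the median
  rule is used and the fallback is recorded.

The scan's selected p is a minimum over many tests and is therefore
optimistically biased; no multiplicity correction is applied (the
analysis convention being mirrored reports raw p), and the result carries
an explicit warning note instead. As a changepoint estimator the min-p
cutpoint has cube-root (n^{1/3}) sampling spread: even with a planted
threshold and a strong hazard contrast, individual datasets select a cut
a few order statistics away from the boundary. Tests of recovery
therefore check the median over replicate datasets, plus exact agreement
with an independent exhaustive-scan oracle on each dataset.

Association tests are Kruskal–Wallis (continuous vs categorical, tie
corrected, chi-square p) and a two-sided Fisher's exact test (sum of
hypergeometric probabilities no larger than the observed table's).

## Survival analysis

Kaplan–Meier product-limit estimation, the k-group log-rank test, and
Cox proportional-hazards fitting are delegated to lifelines: Efron
handling of ties (the less biased default when ties exist), Wald 95% CIs
and p-values on the log-hazard scale, Harrell's concordance. Continuous
covariates enter dichotomized, matching the grouped analyses the package
reproduces. Multivariate models admit covariates with univariate
p < 0.05 (strict), preserving input order; forced covariates can be added
explicitly, which is how a grouping retained for comparability despite a
non-significant univariate p enters the model.

Landmark survival reads S(t) from the KM step function. Beyond observed
follow-up the estimate is undefined unless the curve already reached 0
through events, in which case it stays 0.

A vectorized two-group log-rank statistic (identical
observed-minus-expected chi-square, validated against lifelines to 1e-8
and against a hand tableau in the tests) backs the resampling-heavy
callers — the cutpoint scan and the stability curves — where thousands of
tests per second are needed.

## Robustness procedures

- **Patient-fraction resampling**: for each fraction f ∈ [0.7, 1.0],
  draw ⌊f·n⌋ patients without replacement `n_reps` times and record the
  share of draws in which the grouped test keeps p < α (α = 0.05).
  Group labels are computed once on the full cohort and held fixed —
  this isolates marker stability and is exactly reproducible; re-deriving
  the median threshold inside every draw is available behind a flag. The
  univariate mode uses the log-rank test; the multivariate mode records
  the Cox Wald p of the covariate of interest. At f = 1 every draw is the
  full cohort, so the percentage is exactly 0 or 100. Note the
  conditional nature of the statistic: for a single cohort the subsample
  rejection rate concentrates near that cohort's own full-sample result;
  nominal-level behaviour under the null (≈5%) emerges in expectation
  over cohorts, which is how the calibration tests evaluate it.
- **Cell subsampling**: sampling ⌊f·N⌋ cells without replacement touches
  only the class counts, so replicates draw multivariate hypergeometric
  count vectors — exact and fast at 10⁵ cells. The SD of Shannon over
  replicates follows the delta-method approximation
  √(Σ (ln p_i + H)² p_i (1−f)/(fN)), which the tests use as an
  independent oracle (agreement within a factor of 2).
- **Half-tissue splits**: the section is cut at the midpoint of the cell
  bounding box on the chosen axis (vertical = left/right on x,
  horizontal = top/bottom on y; cell extent is the natural proxy for the
  image frame when only coordinates are available). Each half's Shannon
  diversity is compared with the whole-section value by absolute
  difference. Zero extent or an empty half flags the split degenerate.
  The full per-section distribution of |ΔH| is reported rather than a
  single pooled SD, whose pooling set would otherwise be ambiguous.

## Classifier validation

Per-class sensitivity and specificity use one-vs-rest binarization (the
standard choice for a three-class problem), with the balanced average
defined as exactly their arithmetic mean; metrics are available pooled
and per site. Proportion agreement over fields of view is computed with
Pearson correlation by default and Spearman as an option — both appear in
the combined report, since either convention is defensible and the two
can be quoted inconsistently.

## Synthetic cohort generator

The generator is the package's test bed: it produces cell maps, clinical
outcomes and the ground truth that parameter-recovery tests need. Its
defaults emulate the printed structure of a 61-patient HGSOC cohort with
192 lesions across 7 sites; none of the distributional forms below are
observed — they are this module's modelling choices, fitted to printed
summaries.

- **Sites.** Every patient gets exactly one ovary section plus k−1
  metastasis sections, k drawn from {2,3,4,5} with probabilities
  (0.25, 0.45, 0.20, 0.10) — median 3 sites, mean ≈ 3.15 ≈ 192/61.
  Metastasis sites are drawn iid from the observed non-ovary section
  frequencies (omentum 51/131, peritoneum 48/131, lymph node 20/131,
  appendix 9/131, umbilicus 2/131, spleen 1/131). iid draws (a patient
  may contribute two lesions of the same type) were chosen deliberately:
  weighted sampling *without* replacement distorts realized section-type
  frequencies (frequent sites get compressed), and matching the marginal
  frequencies was judged the more important property to preserve.
- **Compositions.** Each section's (cancer, lymphocyte, stromal) mixture
  is Dirichlet with site-specific means — cancer-dominated overall
  (matching mean per-class counts of 362k/67k/93k per section),
  lymphocyte-shifted in lymph node, stromal/lymphocyte-shifted in
  appendix — and total concentration 15, giving realistic
  section-to-section spread within a site. Sections are independent given
  their site: within-patient correlation between the ovary and metastasis
  compositions is *not* modelled, so ovary-vs-metastasis correlation
  analyses run on synthetic data hover near zero rather than the weak
  positive correlations real cohorts show. Tests of that operation use
  explicit bivariate draws instead.
- **Cell counts and positions.** Per-class per-section counts are
  log-normal with the mean matched exactly to the printed value and the
  log-SD fitted from the printed IQR; a desk-scale multiplier (default
  1/100) shrinks counts so tests run on thousands of cells per section,
  with full scale available (`count_scale=1`). Positions are uniform in a
  20 × 20 mm footprint by default; a Matérn-style parent–offspring
  clustered mode (30 parents, 800 μm Gaussian spread) exists to make
  spatial-split tests non-trivial. No nucleus morphology or image pixels
  are simulated.
- **Survival.** Outcomes follow an exponential proportional-hazards
  model acting through the *true* MetDiv group: the top `high_fraction`
  (default 11/61) of ground-truth MetDiv carries the configured log-HR
  (defaults ln 3.18 for OS, ln 2.83 for PFS) over baselines with medians
  43.33 (OS) and 19.8 (PFS) months. Coupling through the dichotomized
  latent group, not the continuous score, mirrors the grouped analyses
  downstream. The PFS event time is capped at the OS event time, so its
  realized median sits slightly below nominal. Censoring is an
  independent exponential whose rate solves
  rate/(rate+λ₀) = `censoring_fraction` (default 0.33) against the
  baseline OS hazard, truncated by administrative follow-up at 120
  months; the realized censored share slightly exceeds the nominal
  fraction. Clinical covariates (age, FIGO stage, debulking,
  chemotherapy regimen) are sampled to match the printed cohort mix and
  are independent of outcome — the generator plants no clinical
  confounding.
- **Validation data.** Synthetic annotation pairs use a fixed
  row-stochastic confusion matrix tuned so expected balanced averages at
  the printed class counts (2,668 / 1,120 / 845) land near 0.90 / 0.82 /
  0.89; field-of-view scores add per-class Gaussian noise whose SD is set
  via the Pearson attenuation formula r = 1/√(1+σ²/var) to target
  correlations near 0.8 / 0.7 / 0.9.
- **Determinism.** One root seed feeds a spawned stream per concern
  (structure, cell placement, clinical, survival), so regenerating with
  the same config is bit-identical, and skipping cell placement
  (`with_cells=False`, used by large simulation studies) leaves truth and
  clinical tables unchanged.

What passing tests on this generator do and do not show: they verify the
estimators and procedures (index arithmetic, HR recovery within 10% with
93–97% CI coverage at n = 500, type-I error of log-rank and
Kruskal–Wallis near 5%, stability-curve calibration) under clean
proportional hazards with independent censoring and site-exchangeable
sections. They do not certify behaviour under real-data features the
generator omits: within-patient composition correlation, spatially
structured microenvironments, non-proportional hazards, informative
censoring, or classifier error that varies with tissue context.

## Numerical conventions and problem sizes

Compositions must sum to 1 within 1e-12; diversity indices agree with a
direct-summation oracle to 1e-12. Percentile definition: linear
interpolation. Tie rule at all thresholds: ≥ goes high. The default test
and acceptance runs use desk-scale cohorts (61–500 patients, 10³–10⁵
cells per section, 200 simulation seeds for recovery experiments, 500
cohorts × 20 draws per fraction for null stability calibration) — sizes
chosen so the full statistical battery completes in minutes on one core
while keeping Monte-Carlo noise well inside each test's tolerance.

## Known limitations

- The ovary/metastasis composition coupling is absent from the generator
  (see above); parameters for it would be pure invention.
- The iterative cutpoint's selected p is reported uncorrected (with a
  warning), matching the mirrored analysis rather than best current
  practice (permutation or cross-validated cutpoints).
- Proportional-hazards diagnostics are out of scope; fits warn on low
  event counts but do not test the PH assumption.
- Spatial analyses are limited to half-splits; no neighborhood-level
  diversity or spatial statistics are computed.
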