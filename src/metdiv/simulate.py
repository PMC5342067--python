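"""Synthetic multi-site cohort generation.

Emulates a cohort of locally advanced high-grade serous ovarian cancer
patients in which each patient contributes one ovary tumor section plus
one to four local metastasis sections (omentum, peritoneum, lymph node,
appendix, spleen, umbilicus), each section being a classified cell map
over three classes (cancer / lymphocyte / stromal). The generator's
defaults reproduce the published cohort's printed summaries: 61 patients,
2-5 sites per patient with median 3, the observed site frequencies, and
per-section cell counts whose log-normal mean/IQR match the reported
classification totals. Site-specific Dirichlet composition priors encode
the reported composition gradients (lymph node lymphocyte-rich; appendix
stromal- and lymphocyte-rich).

Survival is generated by an exponential proportional-hazards model acting
through the *true* high-MetDiv group: patients in the top fraction of the
ground-truth MetDiv score (mean Shannon diversity of the generating
mixtures of their non-ovary sections) carry a configurable log hazard
ratio. Ground truth (mixtures, groups, hazards) is returned alongside the
data so downstream estimators can be tested for parameter recovery.

Cell counts carry a desk-scale multiplier (default 1/100) so that tests
run on thousands rather than hundreds of thousands of cells per section;
full scale is ``count_scale=1.0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .io import CELL_CLASSES, SITES

NON_OVARY_SITES = tuple(s for s in SITES if s != "ovary")

# Observed lesion counts across the cohort's 131 non-ovary blocks.
_NON_OVARY_COUNTS = {
    "omentum": 51, "peritoneum": 48, "lymph_node": 20,
    "appendix": 9, "umbilicus": 2, "spleen": 1,
}
DEFAULT_SITE_FREQUENCIES = {s: c / 131 for s, c in _NON_OVARY_COUNTS.items()}

# 2-5 sites per patient, median 3, mean ~3.15 (192 sections / 61 patients).
DEFAULT_SITES_PER_PATIENT = {2: 0.25, 3: 0.45, 4: 0.20, 5: 0.10}

# Mean (cancer, lymphocyte, stromal) mixture per site. The overall level
# tracks the reported mean per-class counts (cancer-dominated sections);
# lymph node is shifted toward lymphocytes and appendix toward stromal
# cells and lymphocytes, per the reported site contrasts. Concentration 15
# gives realistic section-to-section variability within a site.
_SITE_COMPOSITION_MEANS = {
    "ovary":      (0.66, 0.13, 0.21),
    "omentum":    (0.70, 0.10, 0.20),
    "peritoneum": (0.68, 0.11, 0.21),
    "appendix":   (0.45, 0.20, 0.35),
    "lymph_node": (0.45, 0.40, 0.15),
    "spleen":     (0.60, 0.15, 0.25),
    "umbilicus":  (0.65, 0.12, 0.23),
}
_CONCENTRATION = 15.0
DEFAULT_COMPOSITION_PRIORS = {
    s: tuple(_CONCENTRATION * m for m in means)
    for s, means in _SITE_COMPOSITION_MEANS.items()
}

# Printed per-class per-section classification totals: mean, Q1, Q3.
CELL_COUNT_SUMMARY = {
    "cancer": (362_417, 208_129, 502_789),
    "stromal": (92_861, 39_075, 106_220),
    "lymphocyte": (67_433, 27_944, 90_852),
}
_Z75 = 0.6744897501960817  # 75th normal percentile


def _lognormal_sigma(q1: float, q3: float) -> float:
    return math.log(q3 / q1) / (2 * _Z75)


#: Per-class log-normal count models as (mean, sigma-of-log); the mean is
#: matched exactly and sigma is fitted from the printed IQR.
DEFAULT_CELL_COUNT_PARAMS = {
    cls: {"mean": float(mean), "sigma": _lognormal_sigma(q1, q3)}
    for cls, (mean, q1, q3) in CELL_COUNT_SUMMARY.items()
}


@dataclass
class ClusterParams:
    """Matérn-style parent-offspring clustering of cell positions."""

    n_clusters: int = 30
    spread_um: float = 800.0


@dataclass
class SurvivalModel:
    """Exponential proportional-hazards outcome model.

    Baseline medians follow the reported cohort (OS 43.33, PFS 19.8
    months); the high-MetDiv group's default log-HRs match the reported
    hazard ratios (3.18 for OS, 2.83 for PFS); follow-up is capped at 120
    months with extra random censoring to a nominal ~33% censored.
    """

    median_os: float = 43.33
    median_pfs: float = 19.8
    log_hr_os: float = math.log(3.18)
    log_hr_pfs: float = math.log(2.83)
    high_fraction: float = 11 / 61
    admin_censor_months: float = 120.0
    censoring_fraction: float = 0.33


@dataclass
class CohortConfig:
    n_patients: int = 61
    site_frequencies: dict = field(default_factory=lambda: dict(DEFAULT_SITE_FREQUENCIES))
    sites_per_patient: dict = field(default_factory=lambda: dict(DEFAULT_SITES_PER_PATIENT))
    composition_priors: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITION_PRIORS))
    cells_per_section: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CELL_COUNT_PARAMS.items()})
    count_scale: float = 0.01
    spatial_mode: str = "uniform"
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    section_size_um: float = 20_000.0
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if "ovary" in self.site_frequencies:
            raise ConfigError("site_frequencies are over non-ovary sites only")
        tot = sum(self.site_frequencies.values())
        if abs(tot - 1.0) > 1e-9:
            raise ConfigError(f"site_frequencies must sum to 1, got {tot}")
        for k, p in self.sites_per_patient.items():
            if int(k) not in (2, 3, 4, 5) or p < 0:
                raise ConfigError("sites_per_patient supported on {2..5} with p >= 0")
        if abs(sum(self.sites_per_patient.values()) - 1.0) > 1e-9:
            raise ConfigError("sites_per_patient must sum to 1")
        for site, alpha in self.composition_priors.items():
            if len(alpha) != 3 or any(a <= 0 for a in alpha):
                raise ConfigError(f"Dirichlet concentration for {site} must be 3 positive values")
        for cls, prm in self.cells_per_section.items():
            if prm["mean"] <= 0 or prm["sigma"] < 0:
                raise ConfigError(f"cell count model for {cls}: mean > 0, sigma >= 0 required")
        if self.count_scale <= 0:
            raise ConfigError("count_scale must be > 0")
        if self.spatial_mode not in ("uniform", "clustered"):
            raise ConfigError("spatial_mode must be 'uniform' or 'clustered'")
        sm = self.survival_model
        if sm.median_os <= 0 or sm.median_pfs <= 0:
            raise ConfigError("survival medians must be positive")
        if not 0 < sm.high_fraction < 1:
            raise ConfigError("high_fraction must be in (0,1)")
        if not 0 <= sm.censoring_fraction < 1:
            raise ConfigError("censoring_fraction must be in [0,1)")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "cluster_params" in d and isinstance(d["cluster_params"], dict):
            d["cluster_params"] = ClusterParams(**d["cluster_params"])
        if "survival_model" in d and isinstance(d["survival_model"], dict):
            d["survival_model"] = SurvivalModel(**d["survival_model"])
        if "sites_per_patient" in d:
            d["sites_per_patient"] = {int(k): float(v) for k, v in d["sites_per_patient"].items()}
        if "composition_priors" in d:
            d["composition_priors"] = {k: tuple(v) for k, v in d["composition_priors"].items()}
        cfg = cls(**d)
        return cfg.validate()

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SyntheticCohort:
    """Generated cohort: cell maps, clinical outcomes and ground truth."""

    cells: pd.DataFrame | None
    clinical: pd.DataFrame
    truth_sections: pd.DataFrame
    truth_patients: pd.DataFrame
    config: CohortConfig
    seed: int


def cells_per_section_sampler(config: CohortConfig, cell_class: str, rng) -> int:
    """Draw a desk-scaled per-class cell count (log-normal; >= 1).

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed. With
    ``sigma = 0`` the draw is the configured mean exactly (times scale).
    """
    if cell_class not in config.cells_per_section:
        raise ConfigError(f"unknown cell class {cell_class!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    prm = config.cells_per_section[cell_class]
    mu = math.log(prm["mean"]) - prm["sigma"] ** 2 / 2
    draw = rng.lognormal(mu, prm["sigma"]) if prm["sigma"] > 0 else prm["mean"]
    return max(1, int(round(config.count_scale * draw)))


def _place_cells(n: int, config: CohortConfig, rng) -> np.ndarray:
    size = config.section_size_um
    if config.spatial_mode == "uniform":
        return rng.uniform(0, size, size=(n, 2))
    cp = config.cluster_params
    parents = rng.uniform(0, size, size=(cp.n_clusters, 2))
    assign = rng.integers(0, cp.n_clusters, size=n)
    xy = parents[assign] + rng.normal(0, cp.spread_um, size=(n, 2))
    return np.clip(xy, 0, size)


def _section_frame(patient_id, section_id, site, p, n, config, rng) -> pd.DataFrame:
    counts = rng.multinomial(n, p)
    xy = _place_cells(n, config, rng)
    return pd.DataFrame({
        "patient_id": patient_id,
        "section_id": section_id,
        "site": site,
        "x": xy[:, 0],
        "y": xy[:, 1],
        "cell_class": np.repeat(list(CELL_CLASSES), counts),
    })[["patient_id", "section_id", "site", "x", "y", "cell_class"]]


def generate_section(site: str, config: CohortConfig, seed: int,
                     patient_id: str = "P000", section_id: str | None = None) -> pd.DataFrame:
    """Generate one section's cell table.

    The composition is drawn from the site's Dirichlet prior, the cell
    count from the per-class log-normal models (desk-scaled), and
    positions are placed by ``spatial_mode`` inside the square section
    footprint. Deterministic in ``(site, config, seed)``.
    """
    if site not in config.composition_priors:
        raise ConfigError(f"unknown site {site!r}; configured: {sorted(config.composition_priors)}")
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.asarray(config.composition_priors[site], dtype=float))
    n = sum(cells_per_section_sampler(config, c, rng) for c in CELL_CLASSES)
    sid = section_id or f"{patient_id}_{site}"
    return _section_frame(patient_id, sid, site, p, n, config, rng)


def generate_cohort(config: CohortConfig, with_cells: bool = True) -> SyntheticCohort:
    """Generate a full cohort: cell maps (optional), clinical table, truth.

    Structure, compositions and outcomes are drawn from streams separate
    from cell placement, so ``with_cells=False`` (fast; ground truth and
    clinical only) produces exactly the same truth and clinical tables as
    ``with_cells=True`` for the same config.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_cells, rng_clin, rng_surv = (np.random.default_rng(s) for s in ss.spawn(4))

    non_ovary = list(config.site_frequencies)
    freqs = np.array([config.site_frequencies[s] for s in non_ovary], dtype=float)
    k_support = np.array(sorted(config.sites_per_patient), dtype=int)
    k_probs = np.array([config.sites_per_patient[int(k)] for k in k_support], dtype=float)

    pad = len(str(config.n_patients))
    sec_rows, frames = [], []
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{pad}d}"
        k = int(rng_struct.choice(k_support, p=k_probs))
        # iid site draws keep the realized non-ovary section frequencies
        # multinomial around the configured ones; a patient may contribute
        # more than one lesion of the same site type.
        mets = list(rng_struct.choice(non_ovary, size=k - 1, replace=True, p=freqs))
        for j, site in enumerate(["ovary"] + mets):
            p = rng_struct.dirichlet(np.asarray(config.composition_priors[site], dtype=float))
            n = sum(cells_per_section_sampler(config, c, rng_struct) for c in CELL_CLASSES)
            sid = f"{pid}_s{j}_{site}"
            h = float(-(p[p > 0] * np.log(p[p > 0])).sum())
            sec_rows.append((pid, sid, site, *p, h, n))
            if with_cells:
                frames.append(_section_frame(pid, sid, site, p, n, config, rng_cells))

    truth_sections = pd.DataFrame(
        sec_rows,
        columns=["patient_id", "section_id", "site",
                 "true_p_cancer", "true_p_lymphocyte", "true_p_stromal",
                 "true_shannon", "n_cells"],
    )
    cells = pd.concat(frames, ignore_index=True) if with_cells else None

    pids = truth_sections["patient_id"].unique()
    met_mask = truth_sections["site"] != "ovary"
    true_metdiv = (
        truth_sections[met_mask].groupby("patient_id")["true_shannon"].mean().reindex(pids)
    )

    sm = config.survival_model
    thr = float(np.quantile(true_metdiv.to_numpy(), 1.0 - sm.high_fraction))
    high = (true_metdiv.to_numpy() >= thr)
    n = len(pids)

    lam_os = math.log(2) / sm.median_os * np.exp(sm.log_hr_os * high)
    lam_pfs = math.log(2) / sm.median_pfs * np.exp(sm.log_hr_pfs * high)
    t_os = rng_surv.exponential(1.0 / lam_os)
    t_pfs = np.minimum(rng_surv.exponential(1.0 / lam_pfs), t_os)

    if sm.censoring_fraction > 0:
        lam0 = math.log(2) / sm.median_os
        rate_c = lam0 * sm.censoring_fraction / (1 - sm.censoring_fraction)
        cens = np.minimum(rng_surv.exponential(1.0 / rate_c, size=n), sm.admin_censor_months)
    else:
        cens = np.full(n, sm.admin_censor_months)

    os_months = np.maximum(np.minimum(t_os, cens), 1e-3)
    os_event = (t_os <= cens).astype(int)
    pfs_months = np.maximum(np.minimum(t_pfs, cens), 1e-3)
    pfs_event = (t_pfs <= cens).astype(int)

    age = np.clip(np.round(rng_clin.normal(55, 11, size=n)), 22, 82).astype(int)
    figo = np.where(rng_clin.random(n) < 0.9, "IIIc", "IV")
    debulk = np.where(rng_clin.random(n) < 0.5, "optimal", "suboptimal")
    chemo = np.where(rng_clin.random(n) < 0.886, "TC/TP", "CBP")

    clinical = pd.DataFrame({
        "patient_id": pids, "age": age, "figo_stage": figo,
        "debulking": debulk, "chemo_regimen": chemo,
        "os_months": os_months, "os_event": os_event,
        "pfs_months": pfs_months, "pfs_event": pfs_event,
    })

    truth_patients = pd.DataFrame({
        "patient_id": pids,
        "true_metdiv": true_metdiv.to_numpy(),
        "true_group": np.where(high, "high", "low"),
        "log_hr_os": sm.log_hr_os,
        "log_hr_pfs": sm.log_hr_pfs,
        "metdiv_threshold": thr,
        "seed": config.seed,
    })
    return SyntheticCohort(cells=cells, clinical=clinical,
                           truth_sections=truth_sections,
                           truth_patients=truth_patients,
                           config=config, seed=config.seed)


# ---------------------------------------------------------------------------
# Synthetic classifier-validation data

#: Row-stochastic confusion matrix P(predicted | true), rows/cols ordered as
#: CELL_CLASSES. Chosen so that, at the reported annotation class counts,
#: the expected per-class balanced averages land near the reported
#: classifier performance (~0.90 cancer, ~0.82 lymphocyte, ~0.89 stromal).
DEFAULT_CONFUSION = np.array([
    [0.91, 0.05, 0.04],
    [0.12, 0.70, 0.18],
    [0.09, 0.06, 0.85],
])

#: Reported expert annotation counts per true class.
DEFAULT_ANNOTATION_COUNTS = {"cancer": 2668, "lymphocyte": 1120, "stromal": 845}


def generate_annotations(seed: int, class_counts: dict | None = None,
                         confusion: np.ndarray | None = None) -> pd.DataFrame:
    """Synthetic expert-vs-automated single-cell annotation pairs.

    Expert labels follow ``class_counts``; predicted labels are drawn from
    the per-class ``confusion`` rows. Sites are assigned from the default
    non-ovary site frequencies.
    """
    counts = class_counts or DEFAULT_ANNOTATION_COUNTS
    conf = DEFAULT_CONFUSION if confusion is None else np.asarray(confusion, dtype=float)
    rng = np.random.default_rng(seed)
    expert = np.repeat(list(counts), [counts[c] for c in counts])
    n = len(expert)
    preds = np.empty(n, dtype=object)
    for i, cls in enumerate(CELL_CLASSES):
        mask = expert == cls
        preds[mask] = rng.choice(list(CELL_CLASSES), size=mask.sum(), p=conf[i])
    sites = rng.choice(list(DEFAULT_SITE_FREQUENCIES),
                       size=n, p=list(DEFAULT_SITE_FREQUENCIES.values()))
    return pd.DataFrame({
        "cell_id": [f"cell{i + 1}" for i in range(n)],
        "site": sites, "expert_class": expert, "predicted_class": preds,
    })


#: Per-class noise SD for field-of-view proportion scores; via the Pearson
#: attenuation r = 1/sqrt(1 + sd^2/var) these target correlations near the
#: reported FOV agreement (~0.8 cancer, ~0.7 lymphocyte, ~0.9 stromal).
DEFAULT_FOV_NOISE_SD = {"cancer": 0.089, "lymphocyte": 0.091, "stromal": 0.048}


def generate_fov_scores(seed: int, n_fov: int = 24,
                        noise_sd: dict | None = None):
    """Synthetic (automated, expert) per-class proportions for fields of view.

    Expert proportions are Dirichlet-distributed across fields of view;
    automated scores add independent per-class Gaussian noise and are
    renormalized. Returns ``(automated, expert)`` DataFrames with one
    column per cell class.
    """
    sd = noise_sd or DEFAULT_FOV_NOISE_SD
    rng = np.random.default_rng(seed)
    expert = rng.dirichlet(_CONCENTRATION * np.array([0.65, 0.15, 0.20]), size=n_fov)
    noise = np.column_stack([rng.normal(0, sd[c], size=n_fov) for c in CELL_CLASSES])
    auto = np.clip(expert + noise, 1e-6, None)
    auto = auto / auto.sum(axis=1, keepdims=True)
    cols = list(CELL_CLASSES)
    return (pd.DataFrame(auto, columns=cols), pd.DataFrame(expert, columns=cols))
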