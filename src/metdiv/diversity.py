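"""Ecological diversity of cell-type compositions, per section and per patient.

Every tumor section is summarized by its cell-type composition
``p = (p_cancer, p_lymphocyte, p_stromal)`` and two ecological indices:

* Shannon diversity ``H = -Σ p_i ln p_i`` (nats; 0 for a single-class
  section, ln 3 for an even three-class mixture);
* Simpson index ``D = Σ p_i²`` (the probability two random cells share a
  class; 1 for a single-class section, 1/3 for an even mixture).

Patient-level aggregation yields the MetDiv score: the unweighted mean of
Shannon diversity over all of a patient's lesions *excluding* the ovary
tumor, alongside sibling aggregates (mean including ovary, SD of Shannon,
per-class cell-ratio means).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, ValidationError
from .io import CELL_CLASSES

LN3 = float(np.log(3.0))


@dataclass(frozen=True)
class CompositionVector:
    """Cell-class proportions of one section, ordered as ``CELL_CLASSES``."""

    p: np.ndarray
    n_cells: int

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.shape != (len(CELL_CLASSES),):
            raise ValidationError(f"composition must have {len(CELL_CLASSES)} entries")
        if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError(f"proportions must lie in [0,1] and sum to 1; got {p}")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")


def composition(cells) -> CompositionVector:
    """Cell-class proportions of a section (counts / total; absent classes 0).

    ``cells`` is a DataFrame with a ``cell_class`` column, or a sequence of
    class labels.
    """
    labels = cells["cell_class"] if isinstance(cells, pd.DataFrame) else pd.Series(list(cells))
    n = len(labels)
    if n == 0:
        raise ValidationError("empty section: composition undefined")
    counts = labels.value_counts()
    p = np.array([counts.get(c, 0) for c in CELL_CLASSES], dtype=float) / n
    return CompositionVector(p=p, n_cells=n)


def _as_p(p) -> np.ndarray:
    if isinstance(p, CompositionVector):
        return p.p
    return np.asarray(p, dtype=float)


def shannon(p) -> float:
    """Shannon diversity ``H = -Σ p_i ln p_i`` in nats, with 0·ln 0 := 0."""
    q = _as_p(p)
    nz = q[q > 0]
    return float(-(nz * np.log(nz)).sum())


def simpson(p) -> float:
    """Simpson index ``D = Σ p_i²``."""
    q = _as_p(p)
    return float((q * q).sum())


@dataclass(frozen=True)
class SectionDiversity:
    section_id: str
    site: str
    shannon: float
    simpson: float
    composition: CompositionVector


def section_diversity(cells: pd.DataFrame) -> SectionDiversity:
    """Composition and both diversity indices for one section's cells."""
    comp = composition(cells)
    sid = str(cells["section_id"].iloc[0]) if "section_id" in cells else ""
    site = str(cells["site"].iloc[0]) if "site" in cells else ""
    return SectionDiversity(
        section_id=sid, site=site,
        shannon=shannon(comp), simpson=simpson(comp), composition=comp,
    )


def section_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-section summary of a cell table.

    One row per section: patient, site, total cell count, class proportions
    (cell ratios) and the two diversity indices. Count-based, so it scales to
    sections with 10^5+ cells without materializing per-section frames.
    """
    counts = (
        cells.groupby(["patient_id", "section_id", "site"], sort=False)["cell_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CELL_CLASSES), fill_value=0)
    )
    n = counts.sum(axis=1).to_numpy()
    if (n == 0).any():
        raise ValidationError("section with zero cells")
    p = counts.to_numpy(dtype=float) / n[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    out = counts.reset_index()[["patient_id", "section_id", "site"]]
    out["n_cells"] = n
    for i, c in enumerate(CELL_CLASSES):
        out[f"p_{c}"] = p[:, i]
    out["shannon"] = -plogp.sum(axis=1)
    out["simpson"] = (p * p).sum(axis=1)
    return out


@dataclass(frozen=True)
class PatientDiversityProfile:
    """Patient-level diversity aggregates; ``metdiv`` is NaN when undefined."""

    patient_id: str
    n_sites: int
    metdiv: float
    metdiv_incl_ovary: float
    shannon_sd: float
    ovary_shannon: float
    ovary_stromal_ratio: float
    ovary_lym_ratio: float
    mean_met_stromal_ratio: float
    mean_met_lym_ratio: float
    mean_met_cancer_ratio: float = field(default=np.nan)


PROFILE_COLUMNS = [
    "patient_id", "n_sites", "metdiv", "metdiv_incl_ovary", "shannon_sd",
    "ovary_shannon", "ovary_stromal_ratio", "ovary_lym_ratio",
    "mean_met_stromal_ratio", "mean_met_lym_ratio", "mean_met_cancer_ratio",
]


def patient_profile(sections: pd.DataFrame) -> PatientDiversityProfile:
    """Aggregate one patient's section rows (from :func:`section_table`).

    MetDiv is the unweighted mean Shannon diversity over non-ovary sections;
    ``shannon_sd`` is the n−1 sample SD over those sections (NaN with <2).
    Exactly one ovary section is expected for the ovary-based fields; more
    than one raises, none leaves them NaN. A patient with no non-ovary
    section gets ``metdiv = NaN`` with a warning (excluded downstream).
    """
    pid = str(sections["patient_id"].iloc[0])
    is_ovary = sections["site"] == "ovary"
    n_ov = int(is_ovary.sum())
    if n_ov > 1:
        raise ValidationError(f"patient {pid}: {n_ov} ovary sections (at most 1 expected)")
    met = sections[~is_ovary]
    h_met = met["shannon"].to_numpy(dtype=float)
    if len(h_met) == 0:
        warnings.warn(f"patient {pid}: no non-ovary section; MetDiv undefined", stacklevel=2)
    ov = sections[is_ovary]
    return PatientDiversityProfile(
        patient_id=pid,
        n_sites=len(sections),
        metdiv=float(h_met.mean()) if len(h_met) else np.nan,
        metdiv_incl_ovary=float(sections["shannon"].mean()),
        shannon_sd=float(h_met.std(ddof=1)) if len(h_met) >= 2 else np.nan,
        ovary_shannon=float(ov["shannon"].iloc[0]) if n_ov else np.nan,
        ovary_stromal_ratio=float(ov["p_stromal"].iloc[0]) if n_ov else np.nan,
        ovary_lym_ratio=float(ov["p_lymphocyte"].iloc[0]) if n_ov else np.nan,
        mean_met_stromal_ratio=float(met["p_stromal"].mean()) if len(met) else np.nan,
        mean_met_lym_ratio=float(met["p_lymphocyte"].mean()) if len(met) else np.nan,
        mean_met_cancer_ratio=float(met["p_cancer"].mean()) if len(met) else np.nan,
    )


def patient_table(section_df: pd.DataFrame) -> pd.DataFrame:
    """Per-patient profiles for every patient in a section summary table."""
    rows = [
        patient_profile(sub)
        for _, sub in section_df.groupby("patient_id", sort=False)
    ]
    return pd.DataFrame([vars(r) for r in rows])[PROFILE_COLUMNS]


def compare_ovary_vs_metastases(profiles: pd.DataFrame, cell_class: str):
    """Pearson correlation between ovary and mean-metastasis cell ratio.

    Across patients, correlates the ratio of ``cell_class`` in the ovary
    section with its mean over non-ovary sections. Returns
    ``(r, p, n_pairs)``.
    """
    col_ov = {"stromal": "ovary_stromal_ratio", "lymphocyte": "ovary_lym_ratio"}.get(cell_class)
    col_met = {"stromal": "mean_met_stromal_ratio", "lymphocyte": "mean_met_lym_ratio",
               "cancer": "mean_met_cancer_ratio"}.get(cell_class)
    if col_ov is None or col_met is None:
        raise ValidationError(f"cell_class must be stromal or lymphocyte, got {cell_class!r}")
    sub = profiles[[col_ov, col_met]].dropna()
    if len(sub) < 3:
        raise DegenerateDataError(f"need >= 3 complete pairs, got {len(sub)}")
    res = stats.pearsonr(sub[col_ov], sub[col_met])
    return float(res.statistic), float(res.pvalue), len(sub)


def index_agreement(section_df: pd.DataFrame) -> dict:
    """Agreement between Shannon and Simpson over sections.

    Simpson decreases as Shannon increases, so the raw Pearson r is
    negative; both orientations (H vs D and H vs 1−D) are reported, plus a
    Spearman rank correlation (orientation-free up to sign).
    """
    if len(section_df) < 3:
        raise DegenerateDataError("need >= 3 sections")
    h = section_df["shannon"].to_numpy(dtype=float)
    d = section_df["simpson"].to_numpy(dtype=float)
    if np.ptp(h) == 0 or np.ptp(d) == 0:
        raise DegenerateDataError("zero variance in an index; correlation undefined")
    r_raw = stats.pearsonr(h, d)
    rho = stats.spearmanr(h, d)
    return {
        "pearson_h_vs_d": float(r_raw.statistic),
        "pearson_h_vs_1md": float(stats.pearsonr(h, 1.0 - d).statistic),
        "spearman_h_vs_d": float(rho.statistic),
        "abs_pearson": abs(float(r_raw.statistic)),
        "n_sections": len(section_df),
    }


def shannon_simplex_field(grid_resolution: int) -> pd.DataFrame:
    """Shannon diversity on a barycentric lattice of the 3-simplex.

    Returns rows ``(p_cancer, p_lymphocyte, p_stromal, shannon)`` for all
    lattice points ``(i, j, k)/grid_resolution`` with ``i+j+k = grid_resolution``
    — the theoretical background of a ternary diversity plot.
    """
    if grid_resolution < 2:
        raise ValidationError("grid_resolution must be >= 2")
    g = grid_resolution
    rows = []
    for i in range(g + 1):
        for j in range(g + 1 - i):
            k = g - i - j
            p = np.array([i, j, k], dtype=float) / g
            rows.append((*p, shannon(p)))
    return pd.DataFrame(rows, columns=[f"p_{c}" for c in CELL_CLASSES] + ["shannon"])
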