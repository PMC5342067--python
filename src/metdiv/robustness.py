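"""Stability procedures for the diversity-survival analysis.

Three resampling checks of marker robustness:

* :func:`resampling_stability` — redraw 70-100% of patients without
  replacement many times and record how often the grouped survival test
  stays significant (marker stability under cohort perturbation);
* :func:`cell_subsampling_stability` — recompute a section's Shannon
  diversity on random cell subsets (score stability against the amount of
  tissue analyzed);
* :func:`half_split_stability` — split a section at the midpoint of its
  cell bounding box and compare each half's diversity with the whole
  (score stability against using half the tissue).

Group labels are computed once on the full cohort and held fixed during
patient resampling (marker stability, reproducible); re-deriving the
threshold per draw is available via ``rederive_threshold=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import shannon
from .exceptions import ValidationError
from .io import CELL_CLASSES
from .stratify import median_split
from .survival import cox_fit, logrank_2group


@dataclass(frozen=True)
class StabilityCurve:
    fractions: tuple
    pct_significant: tuple   # per fraction, % of resamples with p < alpha
    n_reps: int
    alpha: float
    seed: int
    analysis: str            # e.g. "univariate OS" / "multivariate OS (metdiv)"
    unreliable: tuple        # per fraction: >50% of reps had an empty group

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fraction": self.fractions,
            "pct_significant": self.pct_significant,
            "unreliable": self.unreliable,
        })


def resampling_stability(times, events, labels=None, *, covariate_df=None,
                         covariate: str | None = None, scores=None,
                         fractions=(0.7, 0.8, 0.9, 1.0), n_reps: int = 1000,
                         alpha: float = 0.05, seed: int = 0,
                         rederive_threshold: bool = False,
                         endpoint: str = "OS") -> StabilityCurve:
    """Patient-fraction resampling of a grouped survival test.

    Univariate mode (default): ``labels`` is the fixed high/low grouping;
    each resample of ``floor(f*n)`` patients without replacement is tested
    with the two-group log-rank test. Multivariate mode: pass
    ``covariate_df`` (numeric covariates incl. ``covariate``) and the Cox
    Wald p of ``covariate`` is recorded instead. With
    ``rederive_threshold=True`` (univariate only), the median split of
    ``scores`` is recomputed inside every resample.

    At fraction 1.0 every draw is the full cohort, so the percentage is
    exactly 0 or 100.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(times)
    rng = np.random.default_rng(seed)
    multivariate = covariate_df is not None

    if multivariate:
        if covariate is None or covariate not in covariate_df.columns:
            raise ValidationError("multivariate mode needs covariate_df and covariate name")
        cov = covariate_df.reset_index(drop=True)
        analysis = f"multivariate {endpoint} ({covariate})"

        def test_p(idx):
            df = cov.iloc[idx].copy()
            df["_t"] = times[idx]
            df["_e"] = events[idx]
            try:
                fit = cox_fit(df, "_t", "_e", list(cov.columns), endpoint=endpoint)
            except Exception:
                return np.nan
            return fit.p[covariate]
    else:
        if rederive_threshold:
            if scores is None:
                raise ValidationError("rederive_threshold needs scores")
            scores = np.asarray(scores, dtype=float)
            analysis = f"univariate {endpoint} (rederived median split)"

            def test_p(idx):
                sub = pd.Series(scores[idx])
                if sub.nunique() == 1:
                    return np.nan
                grp = median_split(sub)
                h = (grp.labels == "high").to_numpy()
                if h.all() or not h.any():
                    return np.nan
                return logrank_2group(times[idx], events[idx], h).p
        else:
            if labels is None:
                raise ValidationError("univariate mode needs fixed labels")
            lab = np.asarray(labels)
            high = (lab == "high") if lab.dtype.kind in "OUS" else lab.astype(bool)
            analysis = f"univariate {endpoint} (fixed labels)"

            def test_p(idx):
                h = high[idx]
                if h.all() or not h.any():
                    return np.nan
                return logrank_2group(times[idx], events[idx], h).p

    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")

    pcts, flags = [], []
    full_idx = np.arange(n)
    for f in fractions:
        if not 0 < f <= 1:
            raise ValidationError(f"fraction {f} outside (0, 1]")
        m = int(np.floor(f * n))
        if m < 2:
            raise ValidationError(f"fraction {f} leaves < 2 patients")
        if m == n:
            p = test_p(full_idx)
            pcts.append(100.0 if (np.isfinite(p) and p < alpha) else 0.0)
            flags.append(bool(np.isnan(p)))
            continue
        ps = np.array([test_p(rng.choice(n, size=m, replace=False)) for _ in range(n_reps)])
        bad = np.isnan(ps)
        pcts.append(float(100.0 * np.mean(ps[~bad] < alpha)) if (~bad).any() else np.nan)
        flags.append(bool(bad.sum() > n_reps / 2))
    return StabilityCurve(
        fractions=tuple(fractions), pct_significant=tuple(pcts),
        n_reps=n_reps, alpha=alpha, seed=seed, analysis=analysis,
        unreliable=tuple(flags),
    )


@dataclass(frozen=True)
class SubsampleReport:
    section_id: str
    fractions: tuple
    shannon_sd: tuple    # SD of Shannon over reps, per fraction
    shannon_mean: tuple
    n_reps: int
    n_cells: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fraction": self.fractions,
            "shannon_sd": self.shannon_sd,
            "shannon_mean": self.shannon_mean,
        })


def cell_subsampling_stability(cells: pd.DataFrame, fractions=(1.0, 0.75, 0.5),
                               n_reps: int = 100, seed: int = 0) -> SubsampleReport:
    """SD of Shannon diversity under random cell subsampling.

    Subsampling ``floor(f*N)`` cells without replacement only touches the
    class counts, so each replicate draws a multivariate hypergeometric
    count vector; this is exact and fast for sections with 10^5+ cells.
    """
    n = len(cells)
    if n < 10:
        raise ValidationError("need a section with >= 10 cells")
    counts = cells["cell_class"].value_counts()
    full = np.array([counts.get(c, 0) for c in CELL_CLASSES], dtype=np.int64)
    sid = str(cells["section_id"].iloc[0]) if "section_id" in cells else ""
    rng = np.random.default_rng(seed)
    sds, means = [], []
    for f in fractions:
        m = int(np.floor(f * n))
        if m < 1:
            raise ValidationError(f"fraction {f} yields an empty subsample")
        if m == n:
            h = shannon(full / n)
            sds.append(0.0)
            means.append(h)
            continue
        draws = rng.multivariate_hypergeometric(full, m, size=n_reps)
        p = draws / m
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        hs = -plogp.sum(axis=1)
        sds.append(float(hs.std(ddof=1)))
        means.append(float(hs.mean()))
    return SubsampleReport(section_id=sid, fractions=tuple(fractions),
                           shannon_sd=tuple(sds), shannon_mean=tuple(means),
                           n_reps=n_reps, n_cells=n, seed=seed)


@dataclass(frozen=True)
class SplitReport:
    section_id: str
    orientation: str          # horizontal | vertical
    shannon_whole: float
    shannon_half_a: float
    shannon_half_b: float
    abs_delta_a: float
    abs_delta_b: float
    n_half_a: int
    n_half_b: int
    degenerate: bool


def half_split_stability(cells: pd.DataFrame, orientation: str = "vertical") -> SplitReport:
    """Shannon diversity of each tissue half versus the whole section.

    The section is split at the midpoint of the cells' bounding box:
    ``vertical`` splits along x (left/right halves), ``horizontal`` along
    y (top/bottom). A zero-extent axis or an empty half flags the split
    degenerate.
    """
    if orientation not in ("horizontal", "vertical"):
        raise ValidationError("orientation must be 'horizontal' or 'vertical'")
    if len(cells) < 2:
        raise ValidationError("need >= 2 cells")
    axis = "x" if orientation == "vertical" else "y"
    coord = cells[axis].to_numpy(dtype=float)
    sid = str(cells["section_id"].iloc[0]) if "section_id" in cells else ""
    h_whole = shannon(np.bincount(
        pd.Categorical(cells["cell_class"], categories=list(CELL_CLASSES)).codes,
        minlength=len(CELL_CLASSES)) / len(cells))
    lo, hi = coord.min(), coord.max()
    if hi - lo <= 0:
        return SplitReport(sid, orientation, h_whole, np.nan, np.nan, np.nan, np.nan,
                           0, 0, degenerate=True)
    mid = (lo + hi) / 2.0
    mask = coord < mid
    halves = [cells[mask], cells[~mask]]
    if any(len(h) == 0 for h in halves):
        return SplitReport(sid, orientation, h_whole, np.nan, np.nan, np.nan, np.nan,
                           int(mask.sum()), int((~mask).sum()), degenerate=True)
    hs = []
    for half in halves:
        codes = pd.Categorical(half["cell_class"], categories=list(CELL_CLASSES)).codes
        p = np.bincount(codes, minlength=len(CELL_CLASSES)) / len(half)
        hs.append(shannon(p))
    return SplitReport(
        section_id=sid, orientation=orientation, shannon_whole=h_whole,
        shannon_half_a=hs[0], shannon_half_b=hs[1],
        abs_delta_a=abs(hs[0] - h_whole), abs_delta_b=abs(hs[1] - h_whole),
        n_half_a=int(mask.sum()), n_half_b=int((~mask).sum()), degenerate=False,
    )
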