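"""Dichotomization of continuous prognostic scores and association tests.

Continuous per-patient scores (MetDiv, cell ratios, age) are skewed, so
the analyses work on two-level groupings. Three rules are provided:

* ``median_split`` — equal-size groups at the median (stromal ratio, age);
* ``tertile_split`` — lower 33% vs upper 67% (lymphocyte ratio);
* ``iterative_threshold`` — a constrained scan over candidate cutpoints
  minimizing the two-group log-rank p, with median fallback when no
  admissible cutpoint exists.

Ties at a threshold always go to "high" (label = score >= threshold).
The cutpoint scan performs no multiplicity correction; its selected p is
optimistically biased by construction and the result carries a warning
note saying so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, ValidationError
from .survival import logrank_2group


@dataclass(frozen=True)
class GroupAssignment:
    variable: str
    method: str                # median | tertile_33_67 | iterative
    threshold: float
    labels: pd.Series          # 'low' / 'high' per patient, NaN scores dropped
    n_low: int
    n_high: int
    fallback: bool = False     # iterative scan fell back to the median rule
    selected_p: float = field(default=np.nan)  # iterative: minimized log-rank p
    note: str = ""


def _labels_from_threshold(scores: pd.Series, thr: float) -> pd.Series:
    return pd.Series(np.where(scores >= thr, "high", "low"), index=scores.index)


def _clean(scores, min_n: int) -> pd.Series:
    s = pd.Series(scores).dropna().astype(float)
    if len(s) < min_n:
        raise ValidationError(f"need >= {min_n} defined scores, got {len(s)}")
    if s.nunique() == 1:
        raise DegenerateDataError("all scores identical; no split possible")
    return s


def median_split(scores, variable: str = "score") -> GroupAssignment:
    """Two equal-size groups at the median; ties at the median go high."""
    s = _clean(scores, 4)
    thr = float(np.median(s))
    labels = _labels_from_threshold(s, thr)
    return GroupAssignment(
        variable=variable, method="median", threshold=thr, labels=labels,
        n_low=int((labels == "low").sum()), n_high=int((labels == "high").sum()),
    )


def tertile_split(scores, variable: str = "score") -> GroupAssignment:
    """Lower-33% vs upper-67% split (linear-interpolation percentile)."""
    s = _clean(scores, 6)
    thr = float(np.percentile(s, 100.0 / 3.0, method="linear"))
    labels = _labels_from_threshold(s, thr)
    return GroupAssignment(
        variable=variable, method="tertile_33_67", threshold=thr, labels=labels,
        n_low=int((labels == "low").sum()), n_high=int((labels == "high").sum()),
    )


def iterative_threshold(scores, times, events, min_group_frac: float = 0.1,
                        variable: str = "score") -> GroupAssignment:
    """Optimal-cutpoint scan: minimize the log-rank p over admissible cuts.

    Candidates are midpoints between consecutive sorted unique scores whose
    induced groups both exceed ``min_group_frac * n`` patients. If no
    candidate is admissible the median rule is used instead and
    ``fallback`` is set. The selected p is the minimum over the scan and is
    optimistic (no multiplicity correction); ``note`` records this.
    """
    s = _clean(scores, 10)
    t = pd.Series(np.asarray(times, dtype=float), index=pd.Series(scores).index).loc[s.index]
    e = pd.Series(np.asarray(events, dtype=int), index=pd.Series(scores).index).loc[s.index]
    n = len(s)
    uniq = np.unique(s.to_numpy())
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    min_size = min_group_frac * n
    best = None
    for thr in candidates:
        hi = (s.to_numpy() >= thr)
        n_hi = int(hi.sum())
        if n_hi <= min_size or (n - n_hi) <= min_size:
            continue
        res = logrank_2group(t.to_numpy(), e.to_numpy(), hi)
        if best is None or res.p < best[1]:
            best = (float(thr), res.p)
    if best is None:
        med = median_split(s, variable=variable)
        return GroupAssignment(
            variable=variable, method="iterative", threshold=med.threshold,
            labels=med.labels, n_low=med.n_low, n_high=med.n_high,
            fallback=True, note="no admissible cutpoint; median fallback",
        )
    thr, p = best
    labels = _labels_from_threshold(s, thr)
    return GroupAssignment(
        variable=variable, method="iterative", threshold=thr, labels=labels,
        n_low=int((labels == "low").sum()), n_high=int((labels == "high").sum()),
        selected_p=p,
        note="selected p is a minimum over cutpoints and is optimistically biased",
    )


@dataclass(frozen=True)
class AssociationTestResult:
    test: str
    statistic: float
    p: float
    detail: object = None


def kruskal_wallis(values, group_labels) -> AssociationTestResult:
    """Kruskal-Wallis rank test of a continuous variable across groups."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    groups = [v[g == lab] for lab in pd.unique(g)]
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    for arr in groups:
        if len(arr) < 2:
            raise ValidationError("every group needs >= 2 values")
    res = stats.kruskal(*groups)
    return AssociationTestResult(
        test="kruskal_wallis", statistic=float(res.statistic), p=float(res.pvalue),
        detail={str(lab): int((g == lab).sum()) for lab in pd.unique(g)},
    )


def fisher_exact(table) -> AssociationTestResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The two-sided p sums hypergeometric probabilities of tables (fixed
    margins) no more likely than the observed one.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (tab < 0).any() or not np.all(tab == np.floor(tab)):
        raise ValidationError("counts must be non-negative integers")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValidationError("both margins must be positive")
    odds, p = stats.fisher_exact(tab.astype(int), alternative="two-sided")
    return AssociationTestResult(test="fisher_exact", statistic=float(odds), p=float(p),
                                 detail=tab.astype(int).tolist())


def skewness(scores) -> float:
    """Adjusted Fisher-Pearson sample skewness."""
    s = np.asarray(pd.Series(scores).dropna(), dtype=float)
    if len(s) < 3:
        raise ValidationError("need >= 3 values")
    if np.ptp(s) == 0:
        raise DegenerateDataError("constant input; skewness undefined")
    return float(stats.skew(s, bias=False))
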