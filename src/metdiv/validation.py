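"""Classifier-agreement metrics against expert annotations.

Two complementary checks of an automated cell classifier:

* single-cell concordance — per-class one-vs-rest sensitivity,
  specificity and their mean (the "balanced average"), optionally
  stratified by anatomical site;
* field-of-view agreement — correlation between automated and expert
  per-class proportion scores over fields of view (Pearson by default,
  Spearman available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .io import CELL_CLASSES


def _metrics_one(df: pd.DataFrame, site: str) -> list[dict]:
    rows = []
    expert = df["expert_class"].to_numpy()
    pred = df["predicted_class"].to_numpy()
    for cls in CELL_CLASSES:
        is_cls = expert == cls
        pred_cls = pred == cls
        support = int(is_cls.sum())
        if support == 0:
            sens = np.nan
        else:
            sens = float((pred_cls & is_cls).sum() / support)
        n_neg = int((~is_cls).sum())
        spec = float((~pred_cls & ~is_cls).sum() / n_neg) if n_neg else np.nan
        rows.append({
            "site": site, "cell_class": cls,
            "sensitivity": sens, "specificity": spec,
            "balanced": (sens + spec) / 2 if np.isfinite(sens) and np.isfinite(spec) else np.nan,
            "support": support, "n": len(df),
        })
    return rows


def confusion_metrics(annotations: pd.DataFrame, by_site: bool = False) -> pd.DataFrame:
    """Per-class sensitivity, specificity and balanced average.

    One-vs-rest binarization per cell class. With ``by_site=True`` a block
    of rows per site is emitted in addition to the pooled ``"all"`` block.
    A class absent from the expert labels gets NaN sensitivity (flagged by
    support 0).
    """
    if len(annotations) == 0:
        raise ValidationError("no annotation pairs")
    rows = _metrics_one(annotations, "all")
    if by_site:
        for site, sub in annotations.groupby("site", sort=False):
            rows.extend(_metrics_one(sub, str(site)))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ProportionAgreement:
    cell_class: str
    r: float
    p: float
    method: str
    n_fov: int
    undefined: bool = False


def proportion_agreement(automated: pd.DataFrame, expert: pd.DataFrame,
                         method: str = "pearson") -> list[ProportionAgreement]:
    """Correlation of automated vs expert proportion scores per cell class.

    ``automated`` and ``expert`` are aligned frames with one row per field
    of view and one column per cell class. Zero variance in either vector
    yields a result flagged undefined rather than an error.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError("method must be 'pearson' or 'spearman'")
    if len(automated) != len(expert):
        raise ValidationError("automated and expert frames must align row-wise")
    if len(automated) < 3:
        raise ValidationError("need >= 3 fields of view")
    out = []
    for cls in CELL_CLASSES:
        a = automated[cls].to_numpy(dtype=float)
        e = expert[cls].to_numpy(dtype=float)
        if np.ptp(a) == 0 or np.ptp(e) == 0:
            out.append(ProportionAgreement(cls, np.nan, np.nan, method, len(a), undefined=True))
            continue
        res = stats.pearsonr(a, e) if method == "pearson" else stats.spearmanr(a, e)
        out.append(ProportionAgreement(cls, float(res.statistic), float(res.pvalue),
                                       method, len(a)))
    return out


def agreement_table(automated: pd.DataFrame, expert: pd.DataFrame) -> pd.DataFrame:
    """Both Pearson and Spearman agreement per class, as one table."""
    rows = []
    for method in ("pearson", "spearman"):
        for res in proportion_agreement(automated, expert, method=method):
            rows.append(vars(res))
    return pd.DataFrame(rows)
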