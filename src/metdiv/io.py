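"""Tabular I/O for cell maps, clinical records and annotation pairs.

All artifacts are plain UTF-8 text tables with a mandatory header. TSV is
the canonical dialect; CSV is accepted on read (the delimiter is sniffed
from the header line) and selected on write by the ``.csv`` extension.

Vocabularies are closed: seven anatomical sites and three cell classes.
``allow_extra_sites=True`` relaxes the site vocabulary for cohorts with
additional lesion locations; the cell-class vocabulary is always closed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

#: Anatomical sites of the lesions (ovary plus the six local metastasis sites).
SITES = ("ovary", "omentum", "peritoneum", "appendix", "lymph_node", "spleen", "umbilicus")

#: The three-class cell vocabulary produced by H&E nucleus classification.
CELL_CLASSES = ("cancer", "lymphocyte", "stromal")

CELL_COLUMNS = ["patient_id", "section_id", "site", "x", "y", "cell_class"]
CLINICAL_COLUMNS = [
    "patient_id", "age", "figo_stage", "debulking", "chemo_regimen",
    "os_months", "os_event", "pfs_months", "pfs_event",
]
ANNOTATION_COLUMNS = ["cell_id", "site", "expert_class", "predicted_class"]


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_raw(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"patient_id": str, "section_id": str, "cell_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    return df


def _check_vocab(series: pd.Series, vocab: tuple[str, ...], what: str, path) -> None:
    bad = ~series.isin(vocab)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1  # 1-based data row
        raise ValidationError(
            f"{path}: unknown {what} {series[bad].iloc[0]!r} at data row {row}; allowed: {vocab}"
        )


def _out_sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_cell_table(path, allow_extra_sites: bool = False) -> pd.DataFrame:
    """Read a per-cell table (one classified nucleus per row).

    Returns a :class:`pandas.DataFrame` with columns
    ``patient_id, section_id, site, x, y, cell_class``; input row order is
    preserved, so grouping by ``section_id`` keeps cells in file order.
    Coordinates are in μm, image convention (origin top-left, y downward).
    """
    df = _read_raw(path, CELL_COLUMNS)
    _check_vocab(df["cell_class"], CELL_CLASSES, "cell_class", path)
    if not allow_extra_sites:
        _check_vocab(df["site"], SITES, "site", path)
    xy = df[["x", "y"]].to_numpy(dtype=float)
    bad = ~np.isfinite(xy).all(axis=1) | (xy < 0).any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValidationError(f"{path}: non-finite or negative coordinate at data row {row}")
    return df[CELL_COLUMNS]


def write_cell_table(df: pd.DataFrame, path) -> None:
    df[CELL_COLUMNS].to_csv(path, sep=_out_sep(path), index=False)


def iter_sections(cells: pd.DataFrame):
    """Yield ``(section_id, sub-frame)`` pairs in order of first appearance."""
    for sid, sub in cells.groupby("section_id", sort=False):
        yield sid, sub


def read_clinical(path) -> pd.DataFrame:
    """Read the per-patient clinical table, keyed uniquely by ``patient_id``."""
    df = _read_raw(path, CLINICAL_COLUMNS)
    dup = df["patient_id"].duplicated()
    if dup.any():
        raise ValidationError(f"{path}: duplicate patient_id {df['patient_id'][dup].iloc[0]!r}")
    for col in ("os_months", "pfs_months"):
        vals = df[col].to_numpy(dtype=float)
        if (vals <= 0).any() or not np.isfinite(vals).all():
            row = int(np.flatnonzero((vals <= 0) | ~np.isfinite(vals))[0]) + 1
            raise ValidationError(f"{path}: non-positive {col} at data row {row}")
    for col in ("os_event", "pfs_event"):
        if not df[col].isin([0, 1]).all():
            raise ValidationError(f"{path}: {col} must be 0/1")
    # PFS should not exceed OS when the PFS event is death; recorded data can
    # legitimately disagree by follow-up quirks, so this is a warning only.
    late = df["pfs_months"] > df["os_months"]
    if late.any():
        warnings.warn(
            f"{path}: pfs_months > os_months for {int(late.sum())} patient(s)",
            stacklevel=2,
        )
    return df[CLINICAL_COLUMNS]


def write_clinical(df: pd.DataFrame, path) -> None:
    df[CLINICAL_COLUMNS].to_csv(path, sep=_out_sep(path), index=False)


def read_annotations(path, allow_extra_sites: bool = False) -> pd.DataFrame:
    """Read expert-vs-automated single-cell annotation pairs."""
    df = _read_raw(path, ANNOTATION_COLUMNS)
    _check_vocab(df["expert_class"], CELL_CLASSES, "expert_class", path)
    _check_vocab(df["predicted_class"], CELL_CLASSES, "predicted_class", path)
    if not allow_extra_sites:
        _check_vocab(df["site"], SITES, "site", path)
    return df[ANNOTATION_COLUMNS]


def write_annotations(df: pd.DataFrame, path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep=_out_sep(path), index=False)
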