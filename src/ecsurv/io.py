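"""Cohort CSV round-tripping with validation.

The cohort interchange format is a UTF-8 comma-separated table with a header
row and one row per patient; ``recurrence_sites`` is serialised as a
semicolon-joined label list.  Unknown columns survive a round trip
untouched.  Leading ``#`` comment lines (run manifest / config hash) are
ignored on read.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "neoadjuvant",
    "pT",
    "pN",
    "lvi",
    "pni",
    "nodes_examined",
    "nodes_positive",
    "lnr",
    "dfs_months",
    "event",
    "recurrence_type",
    "recurrence_sites",
)

_BOOL_COLUMNS = ("neoadjuvant", "lvi", "pni", "event")


class CohortValidationError(ValueError):
    """Raised when a cohort file violates a structural invariant."""


def write_cohort(cohort: pd.DataFrame, path, header_comment: Optional[str] = None) -> None:
    """Write a cohort table as CSV; sites become semicolon-joined strings."""
    frame = cohort.copy()
    frame["recurrence_sites"] = frame["recurrence_sites"].map(
        lambda row: ";".join(row) if not isinstance(row, str) else row
    )
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Missing required columns and node-count violations are rejected; an
    ``lnr`` inconsistent with the node counts by more than 1e-6 is repaired
    with a warning.  Unknown columns are preserved.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise CohortValidationError(f"{path}: file is empty") from exc
    if frame.empty:
        raise CohortValidationError(f"{path}: no data rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing required columns {missing}")
    for col in _BOOL_COLUMNS:
        frame[col] = frame[col].astype(bool)
    bad = frame["nodes_positive"] > frame["nodes_examined"]
    if bad.any():
        ids = frame.loc[bad, "patient_id"].tolist()
        raise CohortValidationError(
            f"{path}: nodes_positive exceeds nodes_examined for rows {ids}"
        )
    lnr_true = frame["nodes_positive"] / frame["nodes_examined"]
    drift = (frame["lnr"] - lnr_true).abs() > 1e-6
    if drift.any():
        warnings.warn(
            f"{path}: lnr inconsistent with node counts for "
            f"{int(drift.sum())} rows; recomputed",
            stacklevel=2,
        )
        frame["lnr"] = lnr_true
    frame["recurrence_sites"] = frame["recurrence_sites"].map(
        lambda v: tuple(sorted(str(v).split(";"))) if isinstance(v, str) and v else ()
    )
    if "true_group" in frame.columns:
        frame["true_group"] = frame["true_group"].where(
            frame["true_group"].notna(), None
        )
    return frame
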