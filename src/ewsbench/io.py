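"""Cohort CSV reading and writing.

One row per encounter, columns as documented in
:data:`ewsbench.records.COHORT_COLUMNS`; an empty cell means missing.
Writing uses fixed formatting so identical cohorts produce byte-identical
files.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyCohortError, InvalidRecordError, SchemaError
from .records import COHORT_COLUMNS, validate_cohort_frame

_BOOL_COLS = ("on_oxygen", "t2rf_risk", "outcome24h")
_REQUIRED = tuple(c for c in COHORT_COLUMNS if c not in ("patient_id", "map"))


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; raises on schema or domain problems."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyCohortError(f"{path}: empty file") from None
    if len(df) == 0:
        raise EmptyCohortError(f"{path}: no records")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown column(s) {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    if "patient_id" not in df.columns:
        df.insert(0, "patient_id", np.arange(len(df)))
    if "map" not in df.columns:
        df["map"] = np.nan
    for col in _BOOL_COLS:
        df[col] = df[col].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
        )
    problems = validate_cohort_frame(df)
    if problems:
        raise InvalidRecordError(
            "domain validation failed: " + "; ".join(problems[:10])
        )
    return df[list(COHORT_COLUMNS)]


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort with deterministic formatting (round-trips cleanly)."""
    out = df.copy()
    cols = [c for c in COHORT_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False, float_format="%.10g")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Deterministically formatted CSV for report tables."""
    df.to_csv(path, index=index, float_format="%.10g")
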