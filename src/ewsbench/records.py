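"""Patient-encounter record model and physiologic domains.

A cohort is represented as a :class:`pandas.DataFrame` with one row per
encounter and the columns listed in :data:`COHORT_COLUMNS`.  Missing values
are encoded as empty CSV cells / ``NaN``.  :class:`VitalsRecord` is a light
single-record view used by the scoring engine and in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidRecordError

#: numeric vital-sign parameters required for score calculation; these are the
#: variables eligible for missingness injection, the >2-missing exclusion rule
#: and imputation.
SCORE_PARAMS = ("hr", "rr", "sbp", "dbp", "temp", "spo2", "gcs")

AVPU_LEVELS = ("A", "V", "P", "U")

#: documented cohort CSV header (one row per encounter, empty cell = missing)
COHORT_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "hr",
    "rr",
    "sbp",
    "dbp",
    "map",
    "temp",
    "spo2",
    "gcs",
    "avpu",
    "on_oxygen",
    "t2rf_risk",
    "outcome24h",
)

#: plausible physiologic domains used for input validation and imputation clamps
DOMAINS = {
    "age": (80.0, 120.0),
    "hr": (10.0, 300.0),
    "rr": (0.0, 80.0),
    "sbp": (30.0, 300.0),
    "dbp": (10.0, 200.0),
    "map": (20.0, 250.0),
    "temp": (25.0, 45.0),
    "spo2": (0.0, 100.0),
    "gcs": (3.0, 15.0),
}


def avpu_from_gcs(gcs: float) -> str:
    """Deterministic GCS -> AVPU map: 15->A, 12-14->V, 9-11->P, <=8->U."""
    g = int(round(gcs))
    if g >= 15:
        return "A"
    if g >= 12:
        return "V"
    if g >= 9:
        return "P"
    return "U"


@dataclass
class VitalsRecord:
    """One ED encounter with demographics, vitals, flags and outcome."""

    age: int
    sex: str  # {"female", "male"}
    hr: float
    rr: float
    sbp: float
    dbp: float
    temp: float
    spo2: float
    gcs: int
    avpu: str  # {"A", "V", "P", "U"}
    on_oxygen: bool
    t2rf_risk: bool
    outcome24h: bool = False
    map: float | None = None
    missing_mask: set = field(default_factory=set)

    def validate(self) -> None:
        """Raise :class:`InvalidRecordError` on domain-invariant violations."""
        if self.age < 80:
            raise InvalidRecordError(f"age {self.age} < 80")
        if not (0 <= self.spo2 <= 100):
            raise InvalidRecordError(f"spo2 {self.spo2} outside [0, 100]")
        if not (3 <= self.gcs <= 15):
            raise InvalidRecordError(f"gcs {self.gcs} outside [3, 15]")
        if self.avpu not in AVPU_LEVELS:
            raise InvalidRecordError(f"avpu {self.avpu!r} not in {AVPU_LEVELS}")
        if self.sex not in ("female", "male"):
            raise InvalidRecordError(f"sex {self.sex!r} invalid")
        if self.map is not None and not math.isnan(self.map):
            lo = min(self.sbp, self.dbp)
            if not (lo - 0.51 <= self.map <= self.sbp + 0.51):
                raise InvalidRecordError(
                    f"map {self.map} inconsistent with sbp {self.sbp}/dbp {self.dbp}"
                )


def record_field(rec, name):
    """Fetch a field from a VitalsRecord, mapping, Series or namedtuple."""
    if isinstance(rec, dict):
        return rec.get(name, None)
    if isinstance(rec, pd.Series):
        return rec.get(name, None)
    return getattr(rec, name, None)


def is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


def validate_cohort_frame(df: pd.DataFrame) -> list[str]:
    """Return a list of domain violations for non-missing values in a cohort."""
    problems: list[str] = []
    for col, (lo, hi) in DOMAINS.items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[(vals.notna()) & ((vals < lo) | (vals > hi))]
        for idx in bad:
            problems.append(f"row {idx}: {col}={df.loc[idx, col]} outside [{lo}, {hi}]")
    if "avpu" in df.columns:
        bad = df.index[df["avpu"].notna() & ~df["avpu"].isin(AVPU_LEVELS)]
        for idx in bad:
            problems.append(f"row {idx}: avpu={df.loc[idx, 'avpu']!r} invalid")
    if "sex" in df.columns:
        bad = df.index[df["sex"].notna() & ~df["sex"].isin(["female", "male"])]
        for idx in bad:
            problems.append(f"row {idx}: sex={df.loc[idx, 'sex']!r} invalid")
    return problems


def missing_score_params(df: pd.DataFrame) -> pd.Series:
    """Number of missing score parameters per row."""
    cols = [c for c in SCORE_PARAMS if c in df.columns]
    return df[cols].isna().sum(axis=1)


def record_from_row(row: pd.Series) -> VitalsRecord:
    """Build a VitalsRecord from a cohort DataFrame row."""
    mask = {c for c in SCORE_PARAMS if is_missing(row.get(c))}
    return VitalsRecord(
        age=int(row["age"]),
        sex=str(row["sex"]),
        hr=row["hr"],
        rr=row["rr"],
        sbp=row["sbp"],
        dbp=row["dbp"],
        temp=row["temp"],
        spo2=row["spo2"],
        gcs=row["gcs"],
        avpu=row["avpu"],
        on_oxygen=bool(row["on_oxygen"]),
        t2rf_risk=bool(row["t2rf_risk"]),
        outcome24h=bool(row.get("outcome24h", False)),
        map=row.get("map", np.nan),
        missing_mask=mask,
    )
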