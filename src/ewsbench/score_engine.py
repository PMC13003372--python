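"""Generic band-table scoring engine for early warning scores.

A :class:`ScoreDefinition` is a declarative table loaded from JSON: each
component maps one record field to an ordered list of closed point bands (or a
categorical point map).  Bands are stated on the recorded value at the
component's resolution (1 for integer-valued vitals, 0.1 for temperature);
matching uses the rightmost band whose lower bound does not exceed the value,
so fractional values (e.g. a derived MAP of 109.33) fall into the band whose
stated range they extend.

The NEWS2-style alternate SpO2 scale for patients at risk of hypercapnic
respiratory failure is expressed as a named special rule carrying separate
band lists for breathing air vs. receiving supplemental oxygen.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidRecordError, MissingDataError
from .records import is_missing, record_field

SCORE_NAMES = ("NEWS", "NEWS2", "MEWS", "REMS", "IEWS")

_NEG_INF = float("-inf")
_POS_INF = float("inf")


@dataclass(frozen=True)
class ComponentBand:
    """One closed scoring interval; ``None`` bounds mean unbounded."""

    lower: float | None
    upper: float | None
    points: int

    @property
    def lo(self) -> float:
        return _NEG_INF if self.lower is None else float(self.lower)

    @property
    def hi(self) -> float:
        return _POS_INF if self.upper is None else float(self.upper)


@dataclass
class ScoreComponent:
    variable: str
    bands: list[ComponentBand] | None = None
    categorical_points: dict[str, int] | None = None
    resolution: float = 1.0

    def __post_init__(self):
        if (self.bands is None) == (self.categorical_points is None):
            raise ConfigurationError(
                f"component {self.variable!r}: exactly one of bands / "
                "categorical_points must be given"
            )


@dataclass
class ScoreDefinition:
    name: str
    components: list[ScoreComponent]
    special_rules: dict = field(default_factory=dict)
    theoretical_range: tuple[int, int] = (0, 0)


@dataclass
class ScoreResult:
    name: str
    total: int
    breakdown: dict[str, int]


# ---------------------------------------------------------------------------
# loading

def _parse_component(obj: dict) -> ScoreComponent:
    bands = None
    if "bands" in obj:
        bands = [ComponentBand(b[0], b[1], int(b[2])) for b in obj["bands"]]
    return ScoreComponent(
        variable=obj["variable"],
        bands=bands,
        categorical_points=obj.get("categorical_points"),
        resolution=float(obj.get("resolution", 1.0)),
    )


def load_definition(source) -> ScoreDefinition:
    """Load a score definition from a JSON file path or parsed dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            obj = json.load(fh)
    else:
        obj = source
    defn = ScoreDefinition(
        name=obj["name"],
        components=[_parse_component(c) for c in obj["components"]],
        special_rules=obj.get("special_rules", {}),
        theoretical_range=tuple(obj.get("theoretical_range", (0, 0))),
    )
    violations = validate_definition(defn)
    if violations:
        raise ConfigurationError(
            f"definition {defn.name!r} invalid: " + "; ".join(violations)
        )
    return defn


def load_default_definitions(directory: str | Path | None = None) -> dict[str, ScoreDefinition]:
    """Load the five bundled score definitions (or all ``*.json`` in a dir)."""
    defs: dict[str, ScoreDefinition] = {}
    if directory is not None:
        for p in sorted(Path(directory).glob("*.json")):
            d = load_definition(p)
            defs[d.name] = d
    else:
        pkg = resources.files("ewsbench") / "definitions"
        for p in sorted(pkg.iterdir()):
            if p.name.endswith(".json"):
                d = load_definition(json.loads(p.read_text()))
                defs[d.name] = d
    return {name: defs[name] for name in SCORE_NAMES if name in defs} | {
        k: v for k, v in defs.items() if k not in SCORE_NAMES
    }


# ---------------------------------------------------------------------------
# validation

def _check_band_list(name: str, variable: str, bands: list[ComponentBand],
                     resolution: float) -> list[str]:
    out: list[str] = []
    if not bands:
        return [f"{name}.{variable}: empty band list"]
    if bands[0].lower is not None:
        out.append(f"{name}.{variable}: coverage gap below {bands[0].lower}")
    if bands[-1].upper is not None:
        out.append(f"{name}.{variable}: coverage gap above {bands[-1].upper}")
    for prev, nxt in zip(bands, bands[1:]):
        if prev.upper is None or nxt.lower is None:
            out.append(f"{name}.{variable}: interior unbounded band")
            continue
        gap = nxt.lo - prev.hi
        if gap > resolution * 1.5:
            out.append(
                f"{name}.{variable}: coverage gap between {prev.upper} and {nxt.lower}"
            )
        elif gap < resolution * 0.5:
            out.append(
                f"{name}.{variable}: overlap between bands ending {prev.upper} "
                f"and starting {nxt.lower}"
            )
    for b in bands:
        if b.lo > b.hi:
            out.append(f"{name}.{variable}: band lower {b.lower} > upper {b.upper}")
        if b.points < 0:
            out.append(f"{name}.{variable}: negative points {b.points}")
    return out


def validate_definition(defn: ScoreDefinition) -> list[str]:
    """Return all structural violations (empty list means valid)."""
    out: list[str] = []
    max_total = 0
    min_total = 0
    for comp in defn.components:
        if comp.bands is not None:
            out.extend(_check_band_list(defn.name, comp.variable, comp.bands,
                                        comp.resolution))
            pts = [b.points for b in comp.bands]
        else:
            pts = list(comp.categorical_points.values())
            if any(p < 0 for p in pts):
                out.append(f"{defn.name}.{comp.variable}: negative categorical points")
        max_total += max(pts)
        min_total += min(pts)
    for rule, payload in defn.special_rules.items():
        if rule == "spo2_scale2":
            for arm in ("air", "oxygen"):
                if arm not in payload:
                    out.append(f"{defn.name}: spo2_scale2 missing arm {arm!r}")
                    continue
                bands = [ComponentBand(b[0], b[1], int(b[2])) for b in payload[arm]]
                out.extend(_check_band_list(defn.name, f"spo2_scale2.{arm}", bands, 1.0))
        else:
            out.append(f"{defn.name}: unknown special rule {rule!r}")
    lo, hi = defn.theoretical_range
    if min_total < lo or max_total > hi:
        out.append(
            f"{defn.name}: attainable totals [{min_total}, {max_total}] exceed "
            f"theoretical_range [{lo}, {hi}]"
        )
    return out


# ---------------------------------------------------------------------------
# scoring

def derive_map(sbp: float, dbp: float) -> float:
    """Mean arterial pressure: dbp + (sbp - dbp) / 3."""
    if is_missing(sbp) or is_missing(dbp):
        raise MissingDataError("sbp/dbp required to derive MAP")
    if sbp < dbp:
        raise InvalidRecordError(f"sbp {sbp} < dbp {dbp}")
    return dbp + (sbp - dbp) / 3.0


def _categorical_key(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    return str(value)


def _match_band(value: float, bands: list[ComponentBand], label: str) -> int:
    chosen = None
    for b in bands:
        if value >= b.lo:
            chosen = b
        else:
            break
    if chosen is None or value > bands[-1].hi:
        raise ConfigurationError(f"no band in {label} matches value {value}")
    return chosen.points


def score_component(value, comp: ScoreComponent) -> int:
    """Points of the unique band / category that matches ``value``."""
    if is_missing(value):
        raise MissingDataError(f"missing value for component {comp.variable!r}")
    if comp.categorical_points is not None:
        key = _categorical_key(value)
        if key not in comp.categorical_points:
            raise ConfigurationError(
                f"component {comp.variable!r}: no category for value {value!r}"
            )
        return int(comp.categorical_points[key])
    return _match_band(float(value), comp.bands, comp.variable)


def _effective_spo2_points(rec, defn: ScoreDefinition, comp: ScoreComponent) -> int:
    """SpO2 points honouring the alternate hypercapnic-risk scale if active."""
    rule = defn.special_rules.get("spo2_scale2")
    t2rf = record_field(rec, "t2rf_risk")
    if rule is None or not bool(t2rf):
        return score_component(record_field(rec, "spo2"), comp)
    on_o2 = bool(record_field(rec, "on_oxygen"))
    arm = "oxygen" if on_o2 else "air"
    bands = [ComponentBand(b[0], b[1], int(b[2])) for b in rule[arm]]
    value = record_field(rec, "spo2")
    if is_missing(value):
        raise MissingDataError("missing value for component 'spo2'")
    return _match_band(float(value), bands, f"{defn.name}.spo2_scale2.{arm}")


def compute_score(rec, defn: ScoreDefinition) -> ScoreResult:
    """Score one complete record against one definition.

    Missing required fields raise :class:`MissingDataError`; a recorded MAP is
    used when present, otherwise it is derived from SBP/DBP.
    """
    breakdown: dict[str, int] = {}
    for comp in defn.components:
        if comp.variable == "spo2" and "spo2_scale2" in defn.special_rules:
            pts = _effective_spo2_points(rec, defn, comp)
        elif comp.variable == "map":
            value = record_field(rec, "map")
            if is_missing(value):
                value = derive_map(record_field(rec, "sbp"), record_field(rec, "dbp"))
            pts = score_component(value, comp)
        else:
            pts = score_component(record_field(rec, comp.variable), comp)
        breakdown[comp.variable] = pts
    total = int(sum(breakdown.values()))
    lo, hi = defn.theoretical_range
    if not (lo <= total <= hi):
        raise ConfigurationError(
            f"{defn.name}: total {total} outside theoretical range [{lo}, {hi}]"
        )
    return ScoreResult(name=defn.name, total=total, breakdown=breakdown)


# ---------------------------------------------------------------------------
# vectorised cohort scoring

def _vector_band_points(values: np.ndarray, bands: list[ComponentBand],
                        label: str) -> np.ndarray:
    lowers = np.array([b.lo for b in bands])
    pts = np.array([b.points for b in bands], dtype=np.int64)
    idx = np.searchsorted(lowers, values, side="right") - 1
    if np.any(idx < 0):
        bad = values[idx < 0][0]
        raise ConfigurationError(f"no band in {label} matches value {bad}")
    return pts[idx]


def _score_frame(df: pd.DataFrame, defn: ScoreDefinition) -> np.ndarray:
    n = len(df)
    total = np.zeros(n, dtype=np.int64)
    for comp in defn.components:
        if comp.variable == "map":
            vals = df["map"].to_numpy(dtype=float)
            need = np.isnan(vals)
            if need.any():
                sbp = df["sbp"].to_numpy(dtype=float)[need]
                dbp = df["dbp"].to_numpy(dtype=float)[need]
                if np.any(np.isnan(sbp)) or np.any(np.isnan(dbp)):
                    raise MissingDataError("sbp/dbp required to derive MAP")
                vals = vals.copy()
                vals[need] = dbp + (sbp - dbp) / 3.0
        elif comp.categorical_points is not None:
            col = df[comp.variable]
            if col.isna().any():
                raise MissingDataError(
                    f"missing {comp.variable!r} at rows "
                    f"{list(df.index[col.isna()][:5])}"
                )
            keys = col.map(_categorical_key)
            unknown = ~keys.isin(comp.categorical_points)
            if unknown.any():
                raise ConfigurationError(
                    f"component {comp.variable!r}: no category for "
                    f"{keys[unknown].iloc[0]!r}"
                )
            total += keys.map(comp.categorical_points).to_numpy(dtype=np.int64)
            continue
        else:
            vals = df[comp.variable].to_numpy(dtype=float)
        if np.any(np.isnan(vals)):
            rows = list(df.index[np.isnan(vals)][:5])
            raise MissingDataError(f"missing {comp.variable!r} at rows {rows}")
        if comp.variable == "spo2" and "spo2_scale2" in defn.special_rules:
            rule = defn.special_rules["spo2_scale2"]
            t2rf = df["t2rf_risk"].astype(bool).to_numpy()
            on_o2 = df["on_oxygen"].astype(bool).to_numpy()
            pts = _vector_band_points(vals, comp.bands, f"{defn.name}.spo2")
            for arm, mask in (("air", t2rf & ~on_o2), ("oxygen", t2rf & on_o2)):
                if mask.any():
                    bands = [ComponentBand(b[0], b[1], int(b[2])) for b in rule[arm]]
                    pts[mask] = _vector_band_points(
                        vals[mask], bands, f"{defn.name}.spo2_scale2.{arm}"
                    )
            total += pts
        else:
            total += _vector_band_points(vals, comp.bands,
                                         f"{defn.name}.{comp.variable}")
    return total


def compute_all_scores(cohort: pd.DataFrame,
                       definitions: dict[str, ScoreDefinition] | None = None
                       ) -> pd.DataFrame:
    """Score a complete cohort; returns one column per score definition."""
    if definitions is None:
        definitions = load_default_definitions()
    if len(cohort) == 0:
        return pd.DataFrame(columns=list(definitions), dtype=np.int64)
    df = cohort.copy()
    if "map" not in df.columns:
        df["map"] = np.nan
    out = {}
    for name, defn in definitions.items():
        out[name] = _score_frame(df, defn)
    return pd.DataFrame(out, index=cohort.index)
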