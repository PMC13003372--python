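"""Synthetic ED cohort generator.

Emulates the statistical structure of the study population: two outcome
classes at configurable prevalence (default 2.4%), class-conditional vital
marginals matched on median and IQR, an age distribution with median 85 and
IQR 82-88 truncated at 80, class-conditional flag rates, and MCAR
missingness below 5% per variable.

Continuous vitals are drawn by pushing a Gaussian copula variate through a
split-normal quantile function matched to the target median and quartiles;
joint dependence comes from a single latent severity factor per patient, so
sicker patients are coherently deranged across vitals.  GCS is drawn from an
explicit per-class probability mass function and AVPU is derived from GCS via
a fixed map, keeping the two consciousness measures consistent.

Two generator knobs support constructed experiments:

``severity_shift``
    scales how far case marginals sit from control marginals (1 = defaults,
    0 = cases indistinguishable from controls), so downstream discrimination
    can be tuned.
``age_fade``
    linearly attenuates that separation with age (per year above 80), giving
    cohorts whose score discrimination genuinely declines with age.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError
from .records import COHORT_COLUMNS, SCORE_PARAMS, avpu_from_gcs

_Z75 = norm.ppf(0.75)  # 0.6744897...

#: class-conditional (median, q25, q75) targets for continuous vitals,
#: the copula loading on the latent severity factor, the direction in which
#: derangement moves the value, and output rounding.
VITALS_SPEC: dict[str, dict] = {
    "hr": {"control": (80.0, 69.0, 90.0), "case": (86.0, 75.0, 97.0),
           "direction": +1, "rho": 0.90, "tail": 0.5, "decimals": 0},
    "rr": {"control": (19.0, 16.0, 23.0), "case": (20.0, 17.0, 23.0),
           "direction": +1, "rho": 0.85, "tail": 0.5, "decimals": 0},
    "sbp": {"control": (139.0, 120.0, 158.0), "case": (120.0, 93.0, 143.0),
            "direction": -1, "rho": 0.90, "tail": 0.5, "decimals": 0},
    "dbp": {"control": (75.0, 65.0, 86.0), "case": (70.0, 55.0, 81.0),
            "direction": -1, "rho": 0.90, "tail": 0.5, "decimals": 0},
    "temp": {"control": (36.5, 36.0, 37.1), "case": (36.5, 36.0, 37.3),
             "direction": +1, "rho": 0.40, "tail": 0.5, "decimals": 1},
    "spo2": {"control": (96.0, 94.0, 98.0), "case": (92.0, 85.0, 96.0),
             "direction": -1, "rho": 0.80, "tail": 0.5, "decimals": 0},
}

#: explicit GCS probability mass functions (support 3..15) per outcome class.
GCS_SUPPORT = np.arange(3, 16)
GCS_PMF = {
    "control": np.array([0.0005, 0.0005, 0.001, 0.002, 0.002, 0.003, 0.004,
                         0.005, 0.007, 0.008, 0.012, 0.035, 0.92]),
    "case": np.array([0.003, 0.004, 0.005, 0.008, 0.01, 0.02, 0.04,
                      0.05, 0.06, 0.07, 0.08, 0.17, 0.48]),
}

#: class-conditional Bernoulli rates for binary flags.
FLAG_RATES = {
    "on_oxygen": {"control": 0.088, "case": 0.338},
    "t2rf_risk": {"control": 0.064, "case": 0.110},
}

FEMALE_FRACTION = 0.546

#: (median, q25, q75) of years above 80, truncated to [0, 25].
AGE_OFFSET_QUANTILES = (5.0, 2.0, 8.0)


@dataclass
class CohortConfig:
    """Parameters of the synthetic generator."""

    n: int
    prevalence: float = 0.024
    seed: int = 0
    severity_shift: float = 1.0
    age_fade: float = 0.0
    missing_rate: float = 0.0
    vitals: dict = field(default_factory=lambda: dict(VITALS_SPEC))
    gcs_pmf: dict = field(default_factory=lambda: {k: v.copy() for k, v in GCS_PMF.items()})
    flag_rates: dict = field(default_factory=lambda: {k: dict(v) for k, v in FLAG_RATES.items()})

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigurationError("n must be non-negative")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError("prevalence must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 0.05):
            raise ConfigurationError("per-variable missing rate must be < 0.05")
        if self.severity_shift < 0:
            raise ConfigurationError("severity_shift must be >= 0")
        for cls, pmf in self.gcs_pmf.items():
            pmf = np.asarray(pmf, dtype=float)
            if pmf.shape != GCS_SUPPORT.shape or np.any(pmf < 0):
                raise ConfigurationError(f"invalid GCS pmf for class {cls!r}")
            if abs(pmf.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"GCS pmf for class {cls!r} does not sum to 1")


@dataclass
class SyntheticCohort:
    records: pd.DataFrame
    config: CohortConfig
    truth: np.ndarray  # latent per-patient event probability
    severity: np.ndarray  # latent severity factor


def _split_normal_ppf(u: np.ndarray, med, q25, q75, tail: float = 1.0) -> np.ndarray:
    """Quantile function matching a given median and quartiles.

    Uses two half-normal scales below/above the median so the stated median
    and IQR are reproduced exactly in distribution; ``tail`` < 1 compresses
    the distribution beyond the quartiles (quartiles are unchanged), which
    mimics the clumpy charted vitals of real cohorts.  ``med``/``q25``/
    ``q75`` may be scalars or per-element arrays.
    """
    z = norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    scale_lo = (np.asarray(med) - np.asarray(q25)) / _Z75
    scale_hi = (np.asarray(q75) - np.asarray(med)) / _Z75
    inner = np.where(z < 0, med + z * scale_lo, med + z * scale_hi)
    low = np.asarray(q25) + (z + _Z75) * scale_lo * tail
    high = np.asarray(q75) + (z - _Z75) * scale_hi * tail
    return np.where(z < -_Z75, low, np.where(z > _Z75, high, inner))


def _interp_triplet(control, case, shift):
    """Per-patient (median, q25, q75) interpolated between class targets."""
    c = np.asarray(control, dtype=float)
    k = np.asarray(case, dtype=float)
    return tuple(c[i] + shift * (k[i] - c[i]) for i in range(3))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a reproducible synthetic cohort for a validated config."""
    config.validate()
    n = config.n
    rng = np.random.default_rng(config.seed)
    if n == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=object) for c in COHORT_COLUMNS})
        return SyntheticCohort(empty, config, np.zeros(0), np.zeros(0))

    y = rng.random(n) < config.prevalence
    z = rng.standard_normal(n)  # latent severity
    sex = np.where(rng.random(n) < FEMALE_FRACTION, "female", "male")

    m, q25, q75 = AGE_OFFSET_QUANTILES
    age_off = _split_normal_ppf(rng.random(n), m, q25, q75)
    age = 80 + np.clip(np.rint(age_off), 0, 25).astype(int)

    # per-patient interpolation weight between control and case marginals
    shift = np.zeros(n)
    fade = np.maximum(0.0, 1.0 - config.age_fade * (age - 80))
    shift[y] = (config.severity_shift * fade)[y]

    df = pd.DataFrame({"patient_id": np.arange(n), "age": age, "sex": sex})

    eps_sbp = None
    for var, spec in config.vitals.items():
        med_i, lo_i, hi_i = _interp_triplet(spec["control"], spec["case"], shift)
        if var == "dbp" and eps_sbp is not None:
            # diastolic tracks systolic closely so dbp < sbp holds
            eps = 0.9 * eps_sbp + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        else:
            eps = rng.standard_normal(n)
        if var == "sbp":
            eps_sbp = eps
        rho = spec["rho"]
        w = spec["direction"] * rho * z + np.sqrt(1 - rho**2) * eps
        vals = _split_normal_ppf(norm.cdf(w), med_i, lo_i, hi_i,
                                 tail=spec.get("tail", 1.0))
        df[var] = np.round(vals, spec["decimals"])

    df["hr"] = df["hr"].clip(20, 250)
    df["rr"] = df["rr"].clip(4, 70)
    df["sbp"] = df["sbp"].clip(40, 280)
    df["dbp"] = np.minimum(df["dbp"].clip(20, 180), df["sbp"] - 5)
    df["temp"] = df["temp"].clip(30.0, 43.0)
    df["spo2"] = df["spo2"].clip(40, 100)

    # GCS from per-patient interpolated pmf, linked to severity via the copula
    cdf_c = np.cumsum(config.gcs_pmf["control"])
    cdf_k = np.cumsum(config.gcs_pmf["case"])
    cdf = cdf_c[None, :] + shift[:, None] * (cdf_k[None, :] - cdf_c[None, :])
    cdf = np.maximum.accumulate(np.clip(cdf, 0.0, 1.0), axis=1)
    rho_g = 0.6
    w = -rho_g * z + np.sqrt(1 - rho_g**2) * rng.standard_normal(n)
    u = norm.cdf(w)
    # low u -> low GCS: invert the CDF
    idx = (u[:, None] > cdf).sum(axis=1)
    df["gcs"] = GCS_SUPPORT[np.minimum(idx, len(GCS_SUPPORT) - 1)]
    df["avpu"] = [avpu_from_gcs(g) for g in df["gcs"]]

    for flag, rates in config.flag_rates.items():
        p = rates["control"] + shift * (rates["case"] - rates["control"])
        df[flag] = rng.random(n) < np.clip(p, 0.0, 1.0)

    mapv = df["dbp"] + (df["sbp"] - df["dbp"]) / 3.0
    df["map"] = np.clip(np.round(mapv, 1), df["dbp"], df["sbp"])
    df["outcome24h"] = y
    df = df[list(COHORT_COLUMNS)]

    cohort = SyntheticCohort(df, config, np.full(n, config.prevalence), z)
    if config.missing_rate > 0:
        cohort = replace(
            cohort,
            records=inject_missingness(df, config.missing_rate,
                                       seed=rng.integers(2**31)),
        )
    return cohort


def inject_missingness(cohort: pd.DataFrame, missing_rate, seed: int,
                       variables=SCORE_PARAMS) -> pd.DataFrame:
    """Mask values MCAR, per variable, at rates below the 5% regime bound.

    ``missing_rate`` may be a scalar or a per-variable mapping.  When GCS is
    masked the derived AVPU level is masked with it, so the pair stays
    consistent.
    """
    if np.isscalar(missing_rate):
        rates = {v: float(missing_rate) for v in variables}
    else:
        rates = {v: float(missing_rate.get(v, 0.0)) for v in variables}
    for var, rate in rates.items():
        if not (0.0 <= rate < 0.05):
            raise ConfigurationError(
                f"missing rate {rate} for {var!r} violates the <5% regime"
            )
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)
    for var in variables:
        mask = rng.random(n) < rates[var]
        out.loc[mask, var] = np.nan
        if var == "gcs":
            out.loc[mask, "avpu"] = np.nan
        if var in ("sbp", "dbp"):
            out.loc[mask, "map"] = np.nan
    return out


def class_medians(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric per-class medians of the continuous vitals (testing aid)."""
    rows = {}
    ctrl = cohort[~cohort["outcome24h"].astype(bool)]
    case = cohort[cohort["outcome24h"].astype(bool)]
    for var in list(VITALS_SPEC) + ["gcs", "age"]:
        rows[var] = {
            "all": cohort[var].median(),
            "controls": ctrl[var].median() if len(ctrl) else np.nan,
            "cases": case[var].median() if len(case) else np.nan,
        }
    return pd.DataFrame(rows).T


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Table-1-style summary: median (IQR) per class, n (%) for flags."""
    classes = {
        "all": cohort,
        "controls": cohort[~cohort["outcome24h"].astype(bool)] if len(cohort) else cohort,
        "cases": cohort[cohort["outcome24h"].astype(bool)] if len(cohort) else cohort,
    }
    rows = []
    cont_vars = ["age"] + list(VITALS_SPEC) + ["map", "gcs"]
    for var in cont_vars:
        row = {"variable": var, "kind": "median (IQR)"}
        for cls, sub in classes.items():
            if len(sub) == 0:
                row[cls] = "absent"
            else:
                med = sub[var].median()
                lo, hi = sub[var].quantile([0.25, 0.75])
                row[cls] = f"{med:g} ({lo:g}-{hi:g})"
        rows.append(row)
    flag_vars = [("sex", lambda s: s == "female", "female"),
                 ("on_oxygen", lambda s: s.astype(bool), "on_oxygen"),
                 ("t2rf_risk", lambda s: s.astype(bool), "t2rf_risk"),
                 ("avpu", lambda s: s != "A", "not alert (AVPU != A)")]
    for col, pred, label in flag_vars:
        row = {"variable": label, "kind": "n (%)"}
        for cls, sub in classes.items():
            if len(sub) == 0:
                row[cls] = "absent"
            else:
                k = int(pred(sub[col]).sum())
                row[cls] = f"{k} ({100.0 * k / len(sub):.1f})"
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
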