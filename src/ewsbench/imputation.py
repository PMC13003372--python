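"""Missing-data handling: exclusion rule and multiple imputation.

Records with more than two missing score parameters are excluded.  The rest
are completed by chained equations with Monte-Carlo posterior draws
(BayesianRidge conditionals over the other vitals, age and sex); the ``m``
draws are collapsed to a single completed dataset by averaging, because
downstream scoring consumes one completed cohort.  Observed values are never
altered, imputed values are clamped to the observed range of each variable,
and the outcome is excluded from the predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .errors import ConfigurationError
from .records import SCORE_PARAMS, avpu_from_gcs

#: variables rounded to integers after imputation
_INT_VARS = ("hr", "rr", "sbp", "dbp", "spo2", "gcs")


@dataclass
class ImputationConfig:
    m: int = 20
    seed: int = 0
    max_missing_per_record: int = 2
    max_iter: int = 10

    def validate(self) -> None:
        if self.m < 2:
            raise ConfigurationError("number of imputations m must be >= 2")
        if self.max_missing_per_record != 2:
            raise ConfigurationError("max_missing_per_record is fixed at 2")


def apply_exclusions(cohort: pd.DataFrame, max_missing: int = 2
                     ) -> tuple[pd.DataFrame, dict]:
    """Drop records with more than ``max_missing`` missing score parameters."""
    cols = [c for c in SCORE_PARAMS if c in cohort.columns]
    n_missing = cohort[cols].isna().sum(axis=1)
    keep = n_missing <= max_missing
    log = {
        "n_input": int(len(cohort)),
        "n_retained": int(keep.sum()),
        "n_excluded": int((~keep).sum()),
        "reasons": {"missing>2": int((~keep).sum())},
    }
    return cohort[keep].copy(), log


def impute(cohort: pd.DataFrame, config: ImputationConfig | None = None
           ) -> pd.DataFrame:
    """Return a completed copy of ``cohort`` (no missing score parameters)."""
    if config is None:
        config = ImputationConfig()
    config.validate()
    out = cohort.copy()
    cols = [c for c in SCORE_PARAMS if c in out.columns]
    miss = out[cols].isna()
    if not miss.any().any():
        return out

    frac = miss.mean()
    high = frac[frac >= 0.05]
    for var, f in high.items():
        warnings.warn(
            f"variable {var!r} has {100 * f:.1f}% missing, outside the <5% "
            "regime the method was designed for",
            stacklevel=2,
        )

    predictors = pd.DataFrame(index=out.index)
    predictors["age"] = out["age"].astype(float)
    predictors["sex_male"] = (out["sex"] == "male").astype(float)
    X = pd.concat([predictors, out[cols].astype(float)], axis=1)

    rng = np.random.default_rng(config.seed)
    draws = np.zeros((config.m, len(out), len(cols)))
    for k in range(config.m):
        imp = IterativeImputer(
            sample_posterior=True,
            max_iter=config.max_iter,
            random_state=int(rng.integers(2**31)),
            keep_empty_features=True,
        )
        completed = imp.fit_transform(X.to_numpy())
        draws[k] = completed[:, len(predictors.columns):]

    pooled = draws.mean(axis=0)
    for j, var in enumerate(cols):
        observed = out[var].dropna()
        vals = pooled[:, j]
        if len(observed):
            vals = np.clip(vals, observed.min(), observed.max())
        if var in _INT_VARS:
            vals = np.rint(vals)
        else:
            vals = np.round(vals, 1)
        filled = out[var].to_numpy(dtype=float)
        mask = miss[var].to_numpy()
        filled[mask] = vals[mask]
        out[var] = filled

    out["gcs"] = out["gcs"].clip(3, 15)
    if "avpu" in out.columns:
        need = out["avpu"].isna()
        out.loc[need, "avpu"] = [avpu_from_gcs(g) for g in out.loc[need, "gcs"]]
    if "map" in out.columns:
        need = out["map"].isna()
        mapv = out["dbp"] + (out["sbp"] - out["dbp"]) / 3.0
        out.loc[need, "map"] = np.clip(
            np.round(mapv[need], 1), out.loc[need, "dbp"], out.loc[need, "sbp"]
        )
    return out


def median_fill(cohort: pd.DataFrame) -> pd.DataFrame:
    """Unconditional per-variable median imputation (comparison baseline)."""
    out = cohort.copy()
    for var in SCORE_PARAMS:
        if var in out.columns:
            out[var] = out[var].fillna(out[var].median())
    return out
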