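"""Component-contribution analysis via gradient boosting and Shapley values.

Fits a gradient-boosted tree classifier over the core variables of all five
scores, quantifies feature contributions as raw and normalised (divided by
the maximum) mean absolute Shapley values, and contrasts the normalised
contributions between two age strata (below vs. at/above a cut, default 87)
with two-sided nonparametric bootstrap tests on the per-feature differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier

from .errors import ConfigurationError, FitError
from .treeshap import shap_values

#: union of the inputs of all five scores (AVPU enters as an ordinal level)
DEFAULT_FEATURES = (
    "age", "sex", "hr", "rr", "sbp", "map", "temp", "spo2", "gcs",
    "avpu", "on_oxygen", "t2rf_risk",
)

#: fixed, config-declared defaults: shallow trees, moderate number of rounds,
#: learning rate 0.1; class imbalance handled by balanced sample weights.
DEFAULT_HYPERPARAMS = {
    "n_estimators": 150,
    "max_depth": 3,
    "learning_rate": 0.1,
    "subsample": 1.0,
}

_AVPU_ORDINAL = {"A": 0, "V": 1, "P": 2, "U": 3}


@dataclass
class ContributionResult:
    features: list[str]
    mean_abs_shap: pd.Series      # raw scale
    normalized: pd.Series         # divided by the maximum; max is exactly 1
    n: int


@dataclass
class ContributionReport:
    age_cut: int
    younger: ContributionResult
    older: ContributionResult
    shap_difference: pd.Series    # older minus younger, normalised scale
    p_boot: pd.Series
    B: int
    hyperparams: dict = field(default_factory=dict)


def encode_features(cohort: pd.DataFrame,
                    features=DEFAULT_FEATURES) -> pd.DataFrame:
    """Numeric design matrix: binary flags as 0/1, AVPU as ordinal 0-3."""
    X = pd.DataFrame(index=cohort.index)
    for f in features:
        if f == "sex":
            X[f] = (cohort["sex"] == "male").astype(float)
        elif f == "avpu":
            X[f] = cohort["avpu"].map(_AVPU_ORDINAL).astype(float)
        elif f in ("on_oxygen", "t2rf_risk"):
            X[f] = cohort[f].astype(bool).astype(float)
        else:
            X[f] = pd.to_numeric(cohort[f]).astype(float)
    return X


def fit_outcome_model(X: pd.DataFrame, y, hyperparams: dict | None = None,
                      seed: int = 0) -> GradientBoostingClassifier:
    """Deterministic gradient-boosted classifier with balanced class weights."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise FitError("cannot fit outcome model: only one class present")
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    model = GradientBoostingClassifier(random_state=seed, init="zero", **hp)
    w = np.where(y == 1, 0.5 / max(y.mean(), 1e-12),
                 0.5 / max(1 - y.mean(), 1e-12))
    model.fit(np.asarray(X, dtype=float), y, sample_weight=w)
    return model


def shap_contributions(model, X) -> ContributionResult:
    """Raw and normalised mean |SHAP| per feature on the raw margin scale."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(Xv.shape[1])]
    phi, _base = shap_values(model, Xv)
    raw = pd.Series(np.abs(phi).mean(axis=0), index=names)
    peak = raw.max()
    normalized = raw / peak if peak > 0 else raw * 0.0
    return ContributionResult(names, raw, normalized, n=len(Xv))


def _normalized_from_rows(abs_phi: np.ndarray) -> np.ndarray:
    raw = abs_phi.mean(axis=0)
    peak = raw.max()
    return raw / peak if peak > 0 else raw * 0.0


def stratum_contrast(cohort: pd.DataFrame, age_cut: int = 87, B: int = 1000,
                     seed: int = 0, features=DEFAULT_FEATURES,
                     hyperparams: dict | None = None,
                     max_shap_samples: int = 1000) -> ContributionReport:
    """Contrast normalised contributions between age strata at ``age_cut``.

    Identical modelling procedure per stratum.  The bootstrap resamples
    patients (rows of |SHAP|) within each stratum, recomputing the
    normalisation on every resample; p values are two-sided percentile tests
    of the normalised difference against zero.
    """
    ages = cohort["age"].to_numpy()
    if not (ages.min() < age_cut <= ages.max()):
        raise ConfigurationError(
            f"age cut {age_cut} outside observed range [{ages.min()}, {ages.max()}]"
        )
    y = cohort["outcome24h"].astype(int).to_numpy()
    rng = np.random.default_rng(seed)
    results: dict[str, ContributionResult] = {}
    abs_rows: dict[str, np.ndarray] = {}
    for label, mask in (("younger", ages < age_cut), ("older", ages >= age_cut)):
        sub = cohort[mask]
        ysub = y[mask]
        if len(np.unique(ysub)) < 2:
            raise FitError(f"stratum {label!r} lacks an outcome class")
        X = encode_features(sub, features)
        model = fit_outcome_model(X, ysub, hyperparams, seed=seed)
        if len(X) > max_shap_samples:
            take = rng.choice(len(X), size=max_shap_samples, replace=False)
            Xs = X.iloc[np.sort(take)]
        else:
            Xs = X
        phi, _ = shap_values(model, Xs.to_numpy(dtype=float))
        abs_phi = np.abs(phi)
        abs_rows[label] = abs_phi
        raw = pd.Series(abs_phi.mean(axis=0), index=list(X.columns))
        peak = raw.max()
        results[label] = ContributionResult(
            list(X.columns), raw, raw / peak if peak > 0 else raw * 0.0,
            n=len(Xs),
        )

    feat_names = results["older"].features
    diff = results["older"].normalized - results["younger"].normalized

    n_y = len(abs_rows["younger"])
    n_o = len(abs_rows["older"])
    diffs = np.empty((B, len(feat_names)))
    for b in range(B):
        iy = rng.integers(0, n_y, n_y)
        io = rng.integers(0, n_o, n_o)
        diffs[b] = (_normalized_from_rows(abs_rows["older"][io])
                    - _normalized_from_rows(abs_rows["younger"][iy]))
    p = np.empty(len(feat_names))
    for j in range(len(feat_names)):
        lo = (1 + np.sum(diffs[:, j] <= 0)) / (B + 1)
        hi = (1 + np.sum(diffs[:, j] >= 0)) / (B + 1)
        p[j] = min(1.0, 2 * min(lo, hi))

    return ContributionReport(
        age_cut=age_cut,
        younger=results["younger"],
        older=results["older"],
        shap_difference=diff,
        p_boot=pd.Series(p, index=feat_names),
        B=B,
        hyperparams=dict(DEFAULT_HYPERPARAMS) | (hyperparams or {}),
    )
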