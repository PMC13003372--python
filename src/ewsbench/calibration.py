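"""Calibration and threshold classification metrics.

Covers single-predictor logistic risk models, Brier scores with seeded
patient-level bootstrap CIs and paired comparison p values, logit
recalibration slopes, equal-count calibration bins, PPV-margin threshold
selection with Wilson CIs, and precision-recall curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, precision_recall_curve
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import FitError, UndefinedMetricError


@dataclass
class RiskModel:
    intercept: float
    coef: float
    probabilities: np.ndarray
    separation: bool


@dataclass
class BrierResult:
    brier: float
    ci95: tuple[float, float]
    p_vs_null: float | None
    p_vs_ref: float | None


@dataclass
class ThresholdMetrics:
    margin: float
    attainable: bool
    threshold: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    sens: float | None = None
    spec: float | None = None
    ppv: float | None = None
    npv: float | None = None
    sens_ci: tuple | None = None
    spec_ci: tuple | None = None
    ppv_ci: tuple | None = None
    npv_ci: tuple | None = None


@dataclass
class PRResult:
    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    auprc: float


def _check_binary(outcomes) -> np.ndarray:
    y = np.asarray(outcomes).astype(int)
    if y.min() == y.max():
        raise UndefinedMetricError("both outcome classes must be present")
    return y


def fit_risk_model(scores, outcomes) -> RiskModel:
    """Univariable logistic regression of outcome on one score.

    Perfect separation is flagged and a ridge-penalised fit is substituted.
    For a converged MLE fit the mean predicted probability equals the
    observed prevalence.
    """
    y = _check_binary(outcomes)
    x = np.asarray(scores, dtype=float)
    X = sm.add_constant(x)
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0)
        params = np.asarray(res.params)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
            raise PerfectSeparationError("diverging coefficients")
        probs = np.asarray(res.predict(X))
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        separation = True
        lr = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
        lr.fit(x[:, None], y)
        params = np.r_[lr.intercept_[0], lr.coef_[0][0]]
        probs = lr.predict_proba(x[:, None])[:, 1]
    return RiskModel(float(params[0]), float(params[1]), probs, separation)


def brier_score(pred, outcomes) -> float:
    """Mean squared error between probabilities and the binary outcome."""
    y = np.asarray(outcomes, dtype=float)
    p = np.asarray(pred, dtype=float)
    return float(np.mean((p - y) ** 2))


def _boot_p(diffs: np.ndarray) -> float:
    B = len(diffs)
    lo = (1 + np.sum(diffs <= 0)) / (B + 1)
    hi = (1 + np.sum(diffs >= 0)) / (B + 1)
    return float(min(1.0, 2 * min(lo, hi)))


def brier(pred, outcomes, B: int = 2000, seed: int = 0,
          ref_pred=None) -> BrierResult:
    """Brier score with bootstrap CI, plus paired bootstrap comparisons.

    ``p_vs_null`` tests against a constant predictor refitted to each
    resample's prevalence; ``p_vs_ref`` (if ``ref_pred`` is given) tests
    against another prediction vector on the same patients.
    """
    y = np.asarray(outcomes, dtype=float)
    p = np.asarray(pred, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise UndefinedMetricError("predictions must lie in [0, 1]")
    point = brier_score(p, y)
    rng = np.random.default_rng(seed)
    n = len(y)
    boots = np.empty(B)
    d_null = np.empty(B)
    d_ref = np.empty(B) if ref_pred is not None else None
    r = np.asarray(ref_pred, dtype=float) if ref_pred is not None else None
    for b in range(B):
        idx = rng.integers(0, n, n)
        yb, pb = y[idx], p[idx]
        bb = np.mean((pb - yb) ** 2)
        boots[b] = bb
        prev = yb.mean()
        d_null[b] = bb - prev * (1 - prev)
        if r is not None:
            d_ref[b] = bb - np.mean((r[idx] - yb) ** 2)
    ci = tuple(np.percentile(boots, [2.5, 97.5]))
    return BrierResult(
        brier=point,
        ci95=(float(ci[0]), float(ci[1])),
        p_vs_null=_boot_p(d_null),
        p_vs_ref=_boot_p(d_ref) if d_ref is not None else None,
    )


def calibration_slope(pred, outcomes) -> tuple[float, float]:
    """Slope and intercept of the logistic recalibration regression.

    Regresses the outcome on logit(pred); slope 1 / intercept 0 indicates
    perfect calibration, slope < 1 predictions that are too extreme.
    """
    y = _check_binary(outcomes)
    p = np.asarray(pred, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise UndefinedMetricError("predictions must lie strictly in (0, 1)")
    lp = logit(p)
    if np.ptp(lp) < 1e-12:
        raise UndefinedMetricError("degenerate predictions: slope undefined")
    res = sm.Logit(y, sm.add_constant(lp)).fit(disp=0)
    return float(res.params[1]), float(res.params[0])


def calibration_bins(pred, outcomes, n_bins: int = 10) -> pd.DataFrame:
    """Equal-count bins with mean predicted and observed event fraction."""
    p = np.asarray(pred, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(p) < n_bins:
        warnings.warn(
            f"only {len(p)} observations for {n_bins} bins; bins collapse",
            stacklevel=2,
        )
        n_bins = max(1, len(p))
    bins = pd.qcut(p, q=n_bins, duplicates="drop", labels=False)
    df = pd.DataFrame({"bin": bins, "pred": p, "obs": y})
    out = df.groupby("bin").agg(
        n=("obs", "size"), mean_pred=("pred", "mean"), obs_rate=("obs", "mean")
    ).reset_index()
    return out


def _wilson(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return (float(lo), float(hi))


def select_threshold_for_ppv(scores, outcomes, margin: float) -> ThresholdMetrics:
    """Smallest cut-off t (positive iff score >= t) with empirical PPV >= margin.

    Confusion-matrix metrics carry Wilson 95% CIs.  If no cut-off attains the
    margin an explicit not-attainable result is returned.
    """
    y = _check_binary(outcomes)
    s = np.asarray(scores, dtype=float)
    n = len(y)
    for t in np.unique(s):
        pos = s >= t
        tp = int(np.sum(pos & (y == 1)))
        fp = int(np.sum(pos & (y == 0)))
        if tp + fp == 0:
            continue
        if tp / (tp + fp) >= margin:
            fn = int(np.sum(~pos & (y == 1)))
            tn = int(np.sum(~pos & (y == 0)))
            return ThresholdMetrics(
                margin=margin,
                attainable=True,
                threshold=float(t),
                tp=tp, fp=fp, tn=tn, fn=fn,
                sens=tp / (tp + fn),
                spec=tn / (tn + fp),
                ppv=tp / (tp + fp),
                npv=tn / (tn + fn) if (tn + fn) else float("nan"),
                sens_ci=_wilson(tp, tp + fn),
                spec_ci=_wilson(tn, tn + fp),
                ppv_ci=_wilson(tp, tp + fp),
                npv_ci=_wilson(tn, tn + fn),
            )
    return ThresholdMetrics(margin=margin, attainable=False, threshold=None,
                            tp=0, fp=0, tn=int((y == 0).sum()),
                            fn=int((y == 1).sum()))


def precision_recall(scores, outcomes) -> PRResult:
    """Precision-recall curve and step-integrated AUPRC (average precision)."""
    y = _check_binary(outcomes)
    s = np.asarray(scores, dtype=float)
    precision, recall, thresholds = precision_recall_curve(y, s)
    auprc = float(average_precision_score(y, s))
    return PRResult(precision=precision, recall=recall,
                    thresholds=thresholds, auprc=auprc)
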