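"""Discrimination analysis: ROC/AUROC, DeLong comparisons, AUROC-by-age.

The AUROC is the tie-corrected Mann-Whitney concordance probability; its
variance and the covariance between paired AUROCs come from the DeLong
structural-components estimator.  The age analysis computes AUROC in closed
5-year windows advancing by 1 year and models the window series with a
restricted cubic spline fitted by OLS, compared against an intercept-only
model with an F test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

from .errors import FitError, PairingError, UndefinedMetricError


@dataclass
class RocResult:
    auroc: float
    ci95: tuple[float, float]
    variance: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int


@dataclass
class DelongComparison:
    auroc_a: float
    auroc_b: float
    delta_auroc: float
    z: float
    p: float


@dataclass
class AgeWindowSeries:
    window_centers: np.ndarray
    window_auroc: np.ndarray
    window_n: np.ndarray
    window_events: np.ndarray
    width: int
    step: int
    skipped: list = field(default_factory=list)


@dataclass
class SplineFit:
    knots: np.ndarray
    params: np.ndarray
    predicted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    f_stat: float
    p_value: float
    df: int


def _as_binary(outcomes) -> np.ndarray:
    y = np.asarray(outcomes).astype(int)
    if not np.isin(y, (0, 1)).all():
        raise UndefinedMetricError("outcomes must be binary 0/1")
    return y


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components (V10, V01) and AUROC for one score vector."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    tz = stats.rankdata(allv)
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n          # per-positive components
    v01 = 1.0 - (tz[m:] - ty) / m    # per-negative components
    return auc, v10, v01


def delong_covariance(score_matrix, outcomes):
    """AUROCs and DeLong covariance matrix for k paired score vectors."""
    y = _as_binary(outcomes)
    S = np.atleast_2d(np.asarray(score_matrix, dtype=float))
    if S.shape[1] != len(y):
        raise PairingError("score vectors and outcomes must have equal length")
    m = int(y.sum())
    n = int(len(y) - m)
    if m == 0 or n == 0:
        raise UndefinedMetricError("AUROC undefined: only one outcome class present")
    k = S.shape[0]
    aucs = np.zeros(k)
    V10 = np.zeros((k, m))
    V01 = np.zeros((k, n))
    for r in range(k):
        aucs[r], V10[r], V01[r] = _delong_components(S[r], y)
    s10 = np.cov(V10) if k > 1 else np.atleast_2d(np.var(V10, ddof=1))
    s01 = np.cov(V01) if k > 1 else np.atleast_2d(np.var(V01, ddof=1))
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return aucs, cov


def auroc(scores, outcomes) -> RocResult:
    """Tie-corrected concordance AUROC with a DeLong-variance 95% CI."""
    y = _as_binary(outcomes)
    s = np.asarray(scores, dtype=float)
    aucs, cov = delong_covariance(s[None, :], y)
    var = float(cov[0, 0])
    se = np.sqrt(max(var, 0.0))
    lo, hi = np.clip([aucs[0] - 1.959963985 * se, aucs[0] + 1.959963985 * se], 0, 1)
    fpr, tpr, thr = roc_curve(y, s)
    return RocResult(
        auroc=float(aucs[0]),
        ci95=(float(lo), float(hi)),
        variance=var,
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
    )


def delong_compare(scores_a, scores_b, outcomes) -> DelongComparison:
    """Two-sided DeLong test for a difference between paired AUROCs."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise PairingError("paired score vectors must have identical shape")
    aucs, cov = delong_covariance(np.vstack([a, b]), outcomes)
    delta = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var <= 1e-16:
        z = 0.0 if abs(delta) < 1e-12 else np.sign(delta) * np.inf
    else:
        z = delta / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if z == 0.0:
        p = 1.0
    return DelongComparison(float(aucs[0]), float(aucs[1]), delta, float(z), p)


def auroc_vs_chance(scores, outcomes) -> tuple[float, float]:
    """z and two-sided p for AUROC != 0.5 using the DeLong variance."""
    res = auroc(scores, outcomes)
    if res.variance <= 0:
        return np.inf, 0.0
    z = (res.auroc - 0.5) / np.sqrt(res.variance)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def bootstrap_auroc_summary(scores, outcomes, B: int = 1000, seed: int = 0):
    """Bootstrap median and IQR of the AUROC (descriptive convenience)."""
    y = _as_binary(outcomes)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    vals = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.sum() in (0, n):
            vals[b] = np.nan
            continue
        aucs, _ = delong_covariance(s[idx][None, :], yb)
        vals[b] = aucs[0]
    vals = vals[~np.isnan(vals)]
    med, lo, hi = np.percentile(vals, [50, 25, 75])
    return {"median": float(med), "iqr": (float(lo), float(hi))}


# ---------------------------------------------------------------------------
# AUROC by age

def sliding_window_auroc(ages, scores, outcomes, width: int = 5, step: int = 1,
                         min_events: int = 10) -> AgeWindowSeries:
    """AUROC in closed integer-age windows [a, a+width-1], step 1 year.

    Windows with fewer than ``min_events`` events (or no controls) are
    reported as absent, not zero.
    """
    ages = np.asarray(ages)
    s = np.asarray(scores, dtype=float)
    y = _as_binary(outcomes)
    lo, hi = int(np.min(ages)), int(np.max(ages))
    centers, aurocs, ns, events, skipped = [], [], [], [], []
    for a in range(lo, hi - width + 2, step):
        mask = (ages >= a) & (ages <= a + width - 1)
        ye = y[mask]
        n_ev = int(ye.sum())
        center = a + (width - 1) / 2.0
        if n_ev < min_events or n_ev == len(ye):
            skipped.append({"window": (a, a + width - 1), "n": int(mask.sum()),
                            "events": n_ev})
            continue
        aucs, _ = delong_covariance(s[mask][None, :], ye)
        centers.append(center)
        aurocs.append(float(aucs[0]))
        ns.append(int(mask.sum()))
        events.append(n_ev)
    return AgeWindowSeries(
        window_centers=np.array(centers),
        window_auroc=np.array(aurocs),
        window_n=np.array(ns),
        window_events=np.array(events),
        width=width,
        step=step,
        skipped=skipped,
    )


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis, linear beyond boundary knots.

    With k knots the basis has k-1 columns (x plus k-2 truncated-cubic terms,
    normalised by the squared knot span), i.e. k-1 regression df.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise FitError("restricted cubic spline needs at least 3 knots")

    def cube(v):
        return np.maximum(v, 0.0) ** 3

    cols = [x]
    denom = (t[-1] - t[0]) ** 2
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / denom)
    return np.column_stack(cols)


def default_knots(x, df: int = 3) -> np.ndarray:
    """Knots at quantiles of x; {0.05, 0.35, 0.65, 0.95} for df=3."""
    if df == 3:
        qs = [0.05, 0.35, 0.65, 0.95]
    else:
        qs = list(np.linspace(0.05, 0.95, df + 1))
    knots = np.quantile(np.asarray(x, dtype=float), qs)
    if len(np.unique(knots)) != len(knots):
        raise FitError("degenerate knot placement: duplicate knots")
    return knots


def fit_age_spline(series: AgeWindowSeries, df: int = 3) -> SplineFit:
    """OLS restricted-cubic-spline fit of window AUROC on window-centre age.

    Returns the fitted curve with a 95% band and the F test of the spline
    model against the intercept-only (fixed-age) model.
    """
    x = np.asarray(series.window_centers, dtype=float)
    yv = np.asarray(series.window_auroc, dtype=float)
    n = len(x)
    if n < df + 2:
        raise FitError(f"need at least {df + 2} windows for a {df}-df spline fit")
    knots = default_knots(x, df=df)
    X = sm.add_constant(rcs_basis(x, knots))
    if np.ptp(yv) < 1e-12:
        return SplineFit(knots, np.r_[yv[0], np.zeros(df)], yv.copy(),
                         yv.copy(), yv.copy(), 0.0, 1.0, df)
    res = sm.OLS(yv, X).fit()
    pred = res.get_prediction(X)
    ci = pred.conf_int(alpha=0.05)
    fstat = float(res.fvalue)
    pval = float(res.f_pvalue)
    return SplineFit(
        knots=knots,
        params=np.asarray(res.params),
        predicted=np.asarray(pred.predicted_mean),
        ci_low=ci[:, 0],
        ci_high=ci[:, 1],
        f_stat=fstat,
        p_value=pval,
        df=df,
    )
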