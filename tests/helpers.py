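"""Independent oracle implementations used only by the test suite."""

import itertools
import math

import numpy as np


def oracle_band_points(value, bands):
    """Linear scan over [lower, upper] bands; gap values (fractional inputs
    between two integer-resolution bands) belong to the band they extend."""
    lowers = [(-math.inf if b[0] is None else b[0]) for b in bands]
    uppers = [(math.inf if b[1] is None else b[1]) for b in bands]
    for i, b in enumerate(bands):
        if lowers[i] <= value <= uppers[i]:
            return b[2]
    for i in reversed(range(len(bands))):
        if value >= lowers[i]:
            return bands[i][2]
    raise AssertionError(f"oracle: no band for {value}")


def oracle_score(row, defn_json):
    """Brute-force scoring straight off the JSON fixture dict."""
    total = 0
    for comp in defn_json["components"]:
        var = comp["variable"]
        if "categorical_points" in comp:
            val = row[var]
            if isinstance(val, (bool, np.bool_)):
                val = "true" if val else "false"
            total += comp["categorical_points"][str(val)]
            continue
        if var == "map":
            val = row.get("map")
            if val is None or (isinstance(val, float) and math.isnan(val)):
                val = row["dbp"] + (row["sbp"] - row["dbp"]) / 3.0
        else:
            val = row[var]
        if (var == "spo2" and "spo2_scale2" in defn_json.get("special_rules", {})
                and bool(row["t2rf_risk"])):
            arm = "oxygen" if bool(row["on_oxygen"]) else "air"
            total += oracle_band_points(val, defn_json["special_rules"]["spo2_scale2"][arm])
        else:
            total += oracle_band_points(val, comp["bands"])
    return total


def oracle_auroc(scores, outcomes):
    """Exhaustive pair counting: (concordant + ties/2) / (n_pos * n_neg)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    num = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                num += 1.0
            elif p == q:
                num += 0.5
    return num / (len(pos) * len(neg))


def oracle_auprc(scores, outcomes):
    """Brute-force average precision over all distinct cut-offs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(int)
    n_pos = y.sum()
    cuts = np.sort(np.unique(s))[::-1]
    ap = 0.0
    prev_recall = 0.0
    for t in cuts:
        pos = s >= t
        tp = int(np.sum(pos & (y == 1)))
        fp = int(np.sum(pos & (y == 0)))
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def oracle_tree_expvalue(sk_tree, x, subset):
    """Path-dependent conditional expectation of one sklearn tree."""
    t = sk_tree.tree_

    def rec(j):
        if t.children_left[j] < 0:
            return t.value[j, 0, 0]
        d = t.feature[j]
        left, right = t.children_left[j], t.children_right[j]
        if d in subset:
            return rec(left if x[d] <= t.threshold[j] else right)
        wl = t.weighted_n_node_samples[left]
        wr = t.weighted_n_node_samples[right]
        return (wl * rec(left) + wr * rec(right)) / (wl + wr)

    return rec(0)


def oracle_tree_shap(sk_tree, x, n_features):
    """Exact Shapley values by exponential subset enumeration."""
    phi = np.zeros(n_features)
    feats = list(range(n_features))
    for i in feats:
        rest = [f for f in feats if f != i]
        for k in range(len(rest) + 1):
            for S in itertools.combinations(rest, k):
                w = (math.factorial(k) * math.factorial(n_features - k - 1)
                     / math.factorial(n_features))
                phi[i] += w * (oracle_tree_expvalue(sk_tree, x, set(S) | {i})
                               - oracle_tree_expvalue(sk_tree, x, set(S)))
    return phi


def oracle_rcs_predictions(x, y, knots):
    """OLS predictions from an independently constructed natural-spline basis.

    Uses the unnormalised truncated-power construction (different scaling and
    column arrangement than the implementation, same column space).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)

    def pp(v):
        return np.where(v > 0, v, 0.0) ** 3

    cols = [np.ones_like(x), x]
    for j in range(len(t) - 2):
        term = (pp(x - t[j])
                - pp(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
                + pp(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2]))
        cols.append(term)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, np.asarray(y, dtype=float), rcond=None)
    return X @ beta
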