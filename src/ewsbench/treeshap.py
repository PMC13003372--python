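"""Path-dependent Shapley attributions for tree ensembles.

Implements the polynomial-time path-dependent algorithm for exact Shapley
values of a decision tree under the conditional-expectation-by-training-
cover value function, and sums per-tree attributions across the stages of a
:class:`sklearn.ensemble.GradientBoostingClassifier` on the raw (log-odds)
margin scale.  Local accuracy holds: per sample, base value plus the sum of
attributions equals the model's decision function.

The ensembles used here are fitted with ``init="zero"`` so the raw margin is
exactly ``learning_rate`` times the sum of tree outputs.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError


class _Tree:
    """Flat view of one sklearn regression tree."""

    __slots__ = ("left", "right", "feature", "threshold", "value", "cover")

    def __init__(self, sk_tree):
        t = sk_tree.tree_
        self.left = t.children_left
        self.right = t.children_right
        self.feature = t.feature
        self.threshold = t.threshold
        self.value = t.value[:, 0, 0]
        self.cover = t.weighted_n_node_samples


def _extend(m: list, pz: float, po: float, pi: int) -> list:
    m = [e[:] for e in m]
    l = len(m)
    m.append([pi, pz, po, 1.0 if l == 0 else 0.0])
    for i in range(l - 1, -1, -1):
        m[i + 1][3] += po * m[i][3] * (i + 1) / (l + 1)
        m[i][3] = pz * m[i][3] * (l - i) / (l + 1)
    return m


def _unwind(m: list, i: int) -> list:
    L = len(m)
    o_i, z_i = m[i][2], m[i][1]
    n = m[L - 1][3]
    out = [e[:] for e in m[: L - 1]]
    for j in range(L - 2, -1, -1):
        if o_i != 0:
            t = out[j][3]
            out[j][3] = n * L / ((j + 1) * o_i)
            n = t - out[j][3] * z_i * (L - 1 - j) / L
        else:
            out[j][3] = out[j][3] * L / (z_i * (L - 1 - j))
    for j in range(i, L - 1):
        src = m[j + 1]
        out[j][0], out[j][1], out[j][2] = src[0], src[1], src[2]
    return out


def _unwound_sum(m: list, i: int) -> float:
    return sum(e[3] for e in _unwind(m, i))


def _recurse(tree: _Tree, x: np.ndarray, phi: np.ndarray, j: int,
             m: list, pz: float, po: float, pi: int) -> None:
    m = _extend(m, pz, po, pi)
    if tree.left[j] < 0:  # leaf
        v = tree.value[j]
        for i in range(1, len(m)):
            w = _unwound_sum(m, i)
            phi[m[i][0]] += w * (m[i][2] - m[i][1]) * v
        return
    d = int(tree.feature[j])
    lft, rgt = int(tree.left[j]), int(tree.right[j])
    if x[d] <= tree.threshold[j]:
        hot, cold = lft, rgt
    else:
        hot, cold = rgt, lft
    iz = io = 1.0
    k = next((idx for idx in range(1, len(m)) if m[idx][0] == d), None)
    if k is not None:
        iz, io = m[k][1], m[k][2]
        m = _unwind(m, k)
    rj = tree.cover[j]
    _recurse(tree, x, phi, hot, m, iz * tree.cover[hot] / rj, io, d)
    _recurse(tree, x, phi, cold, m, iz * tree.cover[cold] / rj, 0.0, d)


def tree_shap_single(sk_tree, x, n_features: int) -> np.ndarray:
    """Shapley attributions of one fitted sklearn tree for one sample."""
    tree = _Tree(sk_tree)
    phi = np.zeros(n_features)
    _recurse(tree, np.asarray(x, dtype=float), phi, 0, [], 1.0, 1.0, -1)
    return phi


def tree_expected_value(sk_tree) -> float:
    """Training-cover-weighted mean prediction of a fitted sklearn tree."""
    t = sk_tree.tree_
    leaves = t.children_left < 0
    w = t.weighted_n_node_samples[leaves]
    v = t.value[leaves, 0, 0]
    return float(np.sum(w * v) / np.sum(w))


def shap_values(model, X) -> tuple[np.ndarray, float]:
    """Per-sample, per-feature attributions of a gradient-boosted classifier.

    Returns ``(phi, base)`` on the raw margin scale with
    ``phi.sum(axis=1) + base == model.decision_function(X)``.
    """
    if getattr(model, "init", None) != "zero":
        raise ConfigurationError(
            "shap_values requires an ensemble fitted with init='zero'"
        )
    X = np.asarray(X, dtype=float)
    n, M = X.shape
    if M != model.n_features_in_:
        raise ConfigurationError(
            f"feature mismatch: model expects {model.n_features_in_}, got {M}"
        )
    lr = model.learning_rate
    trees = [_Tree(stage[0]) for stage in model.estimators_]
    phi = np.zeros((n, M))
    base = 0.0
    for tr in trees:
        leaves = tr.left < 0
        base += lr * float(
            np.sum(tr.cover[leaves] * tr.value[leaves]) / tr.cover[0]
        )
        for i in range(n):
            p = np.zeros(M)
            _recurse(tr, X[i], p, 0, [], 1.0, 1.0, -1)
            phi[i] += lr * p
    return phi, base
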