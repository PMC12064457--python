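"""Exact path-dependent Shapley values for decision-tree ensembles.

For a single decision tree, the value of a feature coalition S at input x
is the path-dependent conditional expectation: the tree is traversed from
the root, following x at splits on features in S and averaging the two
children weighted by their training cover otherwise.  The Shapley value of
feature j is the cover-weighted average of its marginal contributions over
all coalitions; for trees it can be computed in polynomial time by keeping,
along each root-to-leaf path, the proportion of coalitions of every size in
which the path is followed (the EXTEND / UNWIND bookkeeping of the
path-dependent TreeSHAP algorithm).

For a random forest the explained output is the class-1 probability, which
is the plain average of the per-tree leaf class frequencies, so forest
attributions are the average of per-tree attributions and additivity

    base_value + sum_j phi_j(x) = P(class 1 | x)

holds per sample to numerical precision.

Only the structure arrays of fitted scikit-learn trees are used
(children, features, thresholds, weighted covers, leaf class counts).
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import ShapeError

__all__ = ["tree_shap_values", "forest_shap_values", "tree_expected_value"]


class _Tree:
    """Flat view of one fitted sklearn tree with class-1 leaf probabilities."""

    def __init__(self, sk_tree, class_index: int):
        t = sk_tree.tree_
        self.left = t.children_left
        self.right = t.children_right
        self.feature = t.feature
        self.threshold = t.threshold
        self.cover = t.weighted_n_node_samples
        value = t.value[:, 0, :]  # (nodes, classes) class frequencies
        with np.errstate(invalid="ignore"):
            norm = value / value.sum(axis=1, keepdims=True)
        self.leaf_value = norm[:, class_index]

    def is_leaf(self, node: int) -> bool:
        return self.left[node] < 0


def tree_expected_value(tree: _Tree, node: int = 0) -> float:
    """Cover-weighted mean leaf value — the empty-coalition value."""
    if tree.is_leaf(node):
        return float(tree.leaf_value[node])
    l, r = tree.left[node], tree.right[node]
    wl, wr = tree.cover[l], tree.cover[r]
    return float(
        (wl * tree_expected_value(tree, l) + wr * tree_expected_value(tree, r))
        / (wl + wr)
    )


# A path is a list of [feature, zero_fraction, one_fraction, weight] entries;
# entry 0 is a sentinel for the root.

def _extend(path: list[list[float]], pz: float, po: float, pi: int) -> list[list[float]]:
    path = [e[:] for e in path]
    path.append([pi, pz, po, 1.0 if not path else 0.0])
    l = len(path) - 1
    for i in range(l - 1, -1, -1):
        path[i + 1][3] += po * path[i][3] * (i + 1) / (l + 1)
        path[i][3] = pz * path[i][3] * (l - i) / (l + 1)
    return path


def _unwind(path: list[list[float]], i: int) -> list[list[float]]:
    path = [e[:] for e in path]
    l = len(path) - 1
    z_i, o_i = path[i][1], path[i][2]
    n = path[l][3]
    for j in range(l - 1, -1, -1):
        if o_i != 0.0:
            t = path[j][3]
            path[j][3] = n * (l + 1) / ((j + 1) * o_i)
            n = t - path[j][3] * z_i * (l - j) / (l + 1)
        else:
            path[j][3] = path[j][3] * (l + 1) / (z_i * (l - j))
    for j in range(i, l):
        path[j][0], path[j][1], path[j][2] = path[j + 1][0], path[j + 1][1], path[j + 1][2]
    return path[:-1]


def _unwound_sum(path: list[list[float]], i: int) -> float:
    return float(sum(e[3] for e in _unwind(path, i)))


def _tree_shap_single(tree: _Tree, x: np.ndarray, phi: np.ndarray) -> None:
    def recurse(node: int, path: list[list[float]], pz: float, po: float, pi: int) -> None:
        path = _extend(path, pz, po, pi)
        if tree.is_leaf(node):
            v = tree.leaf_value[node]
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                phi[int(path[i][0])] += w * (path[i][2] - path[i][1]) * v
            return
        f = int(tree.feature[node])
        if x[f] <= tree.threshold[node]:
            hot, cold = tree.left[node], tree.right[node]
        else:
            hot, cold = tree.right[node], tree.left[node]
        iz, io = 1.0, 1.0
        k = next((i for i in range(1, len(path)) if int(path[i][0]) == f), None)
        if k is not None:
            iz, io = path[k][1], path[k][2]
            path = _unwind(path, k)
        cov = tree.cover[node]
        recurse(int(hot), path, iz * tree.cover[hot] / cov, io, f)
        recurse(int(cold), path, iz * tree.cover[cold] / cov, 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)


def tree_shap_values(sk_tree, X: np.ndarray, class_index: int = 1
                     ) -> tuple[np.ndarray, float]:
    """Shapley attribution matrix and base value for one fitted tree."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    tree = _Tree(sk_tree, class_index)
    phi = np.zeros_like(X)
    for row in range(X.shape[0]):
        _tree_shap_single(tree, X[row], phi[row])
    return phi, tree_expected_value(tree)


def forest_shap_values(clf: RandomForestClassifier, X: np.ndarray
                       ) -> tuple[np.ndarray, float]:
    """Per-sample per-feature Shapley values for the class-1 probability.

    Returns ``(phi, base)`` with ``phi`` of shape (samples, features);
    ``base + phi.sum(axis=1)`` equals ``predict_proba(X)[:, class 1]``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != clf.n_features_in_:
        raise ShapeError(
            f"X has {X.shape[1]} columns; forest was fitted on {clf.n_features_in_}"
        )
    class_index = int(np.flatnonzero(clf.classes_ == 1)[0])
    phi = np.zeros_like(X, dtype=float)
    base = 0.0
    for est in clf.estimators_:
        p, b = tree_shap_values(est, X, class_index)
        phi += p
        base += b
    n = len(clf.estimators_)
    return phi / n, base / n
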