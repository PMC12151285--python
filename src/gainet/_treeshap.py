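"""Path-dependent Shapley values for sklearn decision-tree ensembles.

Implements the polynomial-time tree-traversal algorithm that attributes a
tree's prediction for one sample to its input features as exact Shapley
values of the game v(S) = E[f(x) | x_S], where the conditional expectation
follows the tree's own training cover: at a split on a feature outside S the
walk descends both children weighted by their training-sample coverage.

The recursion maintains, per path from the root, the fraction of "zero"
(feature-hidden) and "one" (feature-followed) subsets flowing down, together
with permutation weights, so every feature's marginal contribution over all
subset orderings is accumulated in a single descent.  Verified in the test
suite against a brute-force subset-enumeration Shapley oracle on small trees.
"""

from __future__ import annotations

import numpy as np


class _Path:
    """Parallel arrays of (feature, zero_fraction, one_fraction, pweight)."""

    __slots__ = ("feature", "zero", "one", "weight")

    def __init__(self, capacity: int):
        self.feature = np.empty(capacity, dtype=np.int64)
        self.zero = np.empty(capacity, dtype=float)
        self.one = np.empty(capacity, dtype=float)
        self.weight = np.empty(capacity, dtype=float)

    def copy_to_depth(self, depth: int) -> "_Path":
        p = _Path(self.feature.size)
        p.feature[: depth + 1] = self.feature[: depth + 1]
        p.zero[: depth + 1] = self.zero[: depth + 1]
        p.one[: depth + 1] = self.one[: depth + 1]
        p.weight[: depth + 1] = self.weight[: depth + 1]
        return p


def _extend(p: _Path, depth: int, zero: float, one: float, feat: int) -> None:
    p.feature[depth] = feat
    p.zero[depth] = zero
    p.one[depth] = one
    p.weight[depth] = 1.0 if depth == 0 else 0.0
    for i in range(depth - 1, -1, -1):
        p.weight[i + 1] += one * p.weight[i] * (i + 1) / (depth + 1)
        p.weight[i] = zero * p.weight[i] * (depth - i) / (depth + 1)


def _unwind(p: _Path, depth: int, index: int) -> None:
    one = p.one[index]
    zero = p.zero[index]
    next_one = p.weight[depth]
    for i in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = p.weight[i]
            p.weight[i] = next_one * (depth + 1) / ((i + 1) * one)
            next_one = tmp - p.weight[i] * zero * (depth - i) / (depth + 1)
        else:
            p.weight[i] = p.weight[i] * (depth + 1) / (zero * (depth - i))
    for i in range(index, depth):
        p.feature[i] = p.feature[i + 1]
        p.zero[i] = p.zero[i + 1]
        p.one[i] = p.one[i + 1]


def _unwound_sum(p: _Path, depth: int, index: int) -> float:
    one = p.one[index]
    zero = p.zero[index]
    next_one = p.weight[depth]
    total = 0.0
    for i in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = next_one * (depth + 1) / ((i + 1) * one)
            total += tmp
            next_one = p.weight[i] - tmp * zero * (depth - i) / (depth + 1)
        else:
            total += p.weight[i] / (zero * (depth - i) / (depth + 1))
    return total


class _TreeArrays:
    def __init__(self, tree):
        self.left = tree.children_left
        self.right = tree.children_right
        self.feature = tree.feature
        self.threshold = tree.threshold
        self.cover = tree.weighted_n_node_samples
        values = tree.value  # (n_nodes, 1, n_outputs)
        v = values[:, 0, :].astype(float)
        sums = v.sum(axis=1, keepdims=True)
        # classifiers may store counts (older sklearn) or proportions; use proportions
        if v.shape[1] > 1:
            v = np.divide(v, sums, out=np.zeros_like(v), where=sums > 0)
        self.value = v
        self.max_depth = tree.max_depth


def _recurse(
    t: _TreeArrays,
    x: np.ndarray,
    phi: np.ndarray,
    node: int,
    depth: int,
    parent_path: _Path,
    parent_zero: float,
    parent_one: float,
    parent_feat: int,
) -> None:
    path = parent_path.copy_to_depth(depth - 1) if depth > 0 else parent_path
    _extend(path, depth, parent_zero, parent_one, parent_feat)
    if t.left[node] < 0:  # leaf
        leaf_value = t.value[node]
        for i in range(1, depth + 1):
            w = _unwound_sum(path, depth, i)
            phi[path.feature[i]] += w * (path.one[i] - path.zero[i]) * leaf_value
        return

    split = t.feature[node]
    if x[split] <= t.threshold[node]:
        hot, cold = t.left[node], t.right[node]
    else:
        hot, cold = t.right[node], t.left[node]
    w = t.cover[node]
    hot_zero = t.cover[hot] / w
    cold_zero = t.cover[cold] / w
    incoming_zero = 1.0
    incoming_one = 1.0
    k = -1
    for i in range(1, depth + 1):
        if path.feature[i] == split:
            k = i
            break
    if k >= 0:
        incoming_zero = path.zero[k]
        incoming_one = path.one[k]
        _unwind(path, depth, k)
        depth -= 1
    _recurse(t, x, phi, hot, depth + 1, path, hot_zero * incoming_zero, incoming_one, split)
    _recurse(t, x, phi, cold, depth + 1, path, cold_zero * incoming_zero, 0.0, split)


def tree_shap_values(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shapley values for every sample under a fitted tree model or forest.

    Parameters
    ----------
    model
        A fitted ``DecisionTreeClassifier``/``Regressor`` or a forest with an
        ``estimators_`` list (e.g. ``RandomForestClassifier``); forests
        average per-tree attributions, matching their averaged prediction.
    X
        Samples to explain, shape (n_samples, n_features).

    Returns
    -------
    phi : ndarray, shape (n_samples, n_features, n_outputs)
        Per-feature attributions; for classifiers n_outputs = n_classes and
        ``phi.sum(axis=1) + expected == predict_proba(X)`` (local accuracy).
    expected : ndarray, shape (n_outputs,)
        The cover-weighted mean leaf value of the ensemble (the baseline).
    """
    X = np.asarray(X, dtype=float)
    if hasattr(model, "estimators_"):
        trees = [est.tree_ for est in np.ravel(model.estimators_)]
    elif hasattr(model, "tree_"):
        trees = [model.tree_]
    else:
        raise TypeError(
            f"{type(model).__name__} is not a decision tree or tree ensemble"
        )

    arrays = [_TreeArrays(t) for t in trees]
    n_outputs = arrays[0].value.shape[1]
    phi = np.zeros((X.shape[0], X.shape[1], n_outputs))
    expected = np.zeros(n_outputs)
    for t in arrays:
        leaves = t.left < 0
        w = t.cover[leaves] / t.cover[0]
        expected += w @ t.value[leaves]
        capacity = t.max_depth + 2
        for si in range(X.shape[0]):
            _recurse(t, X[si], phi[si], 0, 0, _Path(capacity), 1.0, 1.0, -1)
    phi /= len(arrays)
    expected /= len(arrays)
    return phi, expected
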