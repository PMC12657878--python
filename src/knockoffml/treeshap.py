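"""Additive attributions for decision-tree ensembles.

Two routes are provided for the same quantity:

* :func:`tree_shap_values` — the polynomial-time path algorithm. For every
  decision path it maintains the fractions of feature subsets that flow down
  each branch (weighted by training-cover proportions at splits on absent
  features) and recovers each feature's Shapley value exactly.
* :func:`exhaustive_shap_values` — the defining sum over all feature
  coalitions, where the value of a coalition S is the cover-weighted
  conditional expectation of the tree output given the features in S. Only
  feasible for models with at most ~12 features; used as the testing oracle.

Both attribute the model's raw output: the decision-function margin for
gradient-boosted classifiers, the predicted class-1 probability for random
forests, and the response for regressors.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from sklearn.ensemble import (
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

__all__ = [
    "TreeData",
    "trees_from_sklearn",
    "tree_shap_values",
    "exhaustive_shap_values",
    "tree_expected_value",
]


@dataclass
class TreeData:
    """Flat arrays for one regression tree (classification trees are stored
    through their leaf scores)."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray  # scalar leaf score per node
    cover: np.ndarray  # training sample weight reaching each node


def _tree_from_sklearn_tree(tree, class_probability: bool) -> TreeData:
    t = tree.tree_
    if class_probability:
        v = t.value[:, 0, :]
        totals = v.sum(axis=1)
        value = np.where(totals > 0, v[:, -1] / np.where(totals > 0, totals, 1), 0.0)
    else:
        value = t.value[:, 0, 0].astype(float)
    return TreeData(
        children_left=t.children_left.copy(),
        children_right=t.children_right.copy(),
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        value=np.asarray(value, dtype=float),
        cover=t.weighted_n_node_samples.astype(float),
    )


def trees_from_sklearn(model) -> tuple[list[TreeData], list[float], float]:
    """Decompose a sklearn tree model into (trees, per-tree scales, offset)
    such that raw_output(x) = offset + sum_t scale_t * tree_t(x)."""
    if isinstance(model, (DecisionTreeRegressor,)):
        return [_tree_from_sklearn_tree(model, False)], [1.0], 0.0
    if isinstance(model, (DecisionTreeClassifier,)):
        return [_tree_from_sklearn_tree(model, True)], [1.0], 0.0
    if isinstance(model, (RandomForestRegressor, ExtraTreesRegressor)):
        trees = [_tree_from_sklearn_tree(e, False) for e in model.estimators_]
        return trees, [1.0 / len(trees)] * len(trees), 0.0
    if isinstance(model, (RandomForestClassifier, ExtraTreesClassifier)):
        if list(model.classes_) != [0, 1] and len(model.classes_) != 2:
            raise ValueError("only binary classifiers are supported")
        trees = [_tree_from_sklearn_tree(e, True) for e in model.estimators_]
        return trees, [1.0 / len(trees)] * len(trees), 0.0
    if isinstance(model, (GradientBoostingRegressor, GradientBoostingClassifier)):
        dummy = np.zeros((1, model.n_features_in_))
        offset = float(model._raw_predict_init(dummy)[0, 0])
        trees = [
            _tree_from_sklearn_tree(e, False) for e in model.estimators_[:, 0]
        ]
        lr = float(model.learning_rate)
        return trees, [lr] * len(trees), offset
    raise TypeError(f"unsupported model type {type(model).__name__}")


# ---------------------------------------------------------------------------
# exhaustive oracle


def tree_expected_value(tree: TreeData, x: np.ndarray, subset: frozenset) -> float:
    """Cover-weighted conditional expectation of the tree output given the
    feature values of ``x`` restricted to ``subset``."""

    def rec(node: int) -> float:
        if tree.children_left[node] < 0:
            return float(tree.value[node])
        d = int(tree.feature[node])
        left, right = int(tree.children_left[node]), int(tree.children_right[node])
        if d in subset:
            child = left if x[d] <= tree.threshold[node] else right
            return rec(child)
        wl, wr = tree.cover[left], tree.cover[right]
        return (wl * rec(left) + wr * rec(right)) / (wl + wr)

    return rec(0)


def exhaustive_shap_values(
    trees: list[TreeData],
    scales: list[float],
    offset: float,
    X: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Shapley values by direct enumeration of all coalitions.

    Complexity is O(2^p) in the number of model features; refuses p > 14.
    Returns (phi, base) with phi of shape (n_rows, p).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if p > 14:
        raise ValueError("exhaustive enumeration is limited to <= 14 features")
    feats = list(range(p))
    phi = np.zeros((n, p))
    base = offset + sum(
        s * tree_expected_value(t, np.zeros(p), frozenset())
        for t, s in zip(trees, scales)
    )

    def value(x: np.ndarray, S: frozenset) -> float:
        return sum(
            s * tree_expected_value(t, x, S) for t, s in zip(trees, scales)
        )

    fact = [factorial(k) for k in range(p + 1)]
    subsets = [
        frozenset(f for f in feats if mask >> f & 1) for mask in range(1 << p)
    ]
    for i in range(n):
        x = X[i]
        vals = {S: value(x, S) for S in subsets}
        for j in feats:
            total = 0.0
            for S in subsets:
                if j in S:
                    continue
                w = fact[len(S)] * fact[p - len(S) - 1] / fact[p]
                total += w * (vals[S | {j}] - vals[S])
            phi[i, j] = total
    return phi, float(base)


# ---------------------------------------------------------------------------
# polynomial path algorithm


class _Path:
    __slots__ = ("d", "z", "o", "w")

    def __init__(self) -> None:
        self.d: list[int] = []
        self.z: list[float] = []
        self.o: list[float] = []
        self.w: list[float] = []

    def copy(self) -> "_Path":
        p = _Path.__new__(_Path)
        p.d = self.d.copy()
        p.z = self.z.copy()
        p.o = self.o.copy()
        p.w = self.w.copy()
        return p


def _extend(p: _Path, pz: float, po: float, pi: int) -> None:
    l = len(p.w)
    p.d.append(pi)
    p.z.append(pz)
    p.o.append(po)
    p.w.append(1.0 if l == 0 else 0.0)
    for i in range(l - 1, -1, -1):
        p.w[i + 1] += po * p.w[i] * (i + 1) / (l + 1)
        p.w[i] = pz * p.w[i] * (l - i) / (l + 1)


def _unwind(p: _Path, i: int) -> None:
    l = len(p.w) - 1
    o, z = p.o[i], p.z[i]
    n = p.w[l]
    for j in range(l - 1, -1, -1):
        if o != 0:
            t = p.w[j]
            p.w[j] = n * (l + 1) / ((j + 1) * o)
            n = t - p.w[j] * z * (l - j) / (l + 1)
        else:
            p.w[j] = p.w[j] * (l + 1) / (z * (l - j))
    for j in range(i, l):
        p.d[j] = p.d[j + 1]
        p.z[j] = p.z[j + 1]
        p.o[j] = p.o[j + 1]
    p.d.pop()
    p.z.pop()
    p.o.pop()
    p.w.pop()


def _unwound_sum(p: _Path, i: int) -> float:
    l = len(p.w) - 1
    o, z = p.o[i], p.z[i]
    total = 0.0
    if o != 0:
        n = p.w[l]
        for j in range(l - 1, -1, -1):
            t = n / ((j + 1) * o)
            total += t
            n = p.w[j] - t * z * (l - j)
    else:
        for j in range(l - 1, -1, -1):
            total += p.w[j] / (z * (l - j))
    return total * (l + 1)


def _tree_shap_single(tree: TreeData, x: np.ndarray, phi: np.ndarray) -> None:
    def recurse(node: int, parent: _Path, pz: float, po: float, pi: int) -> None:
        p = parent.copy()
        _extend(p, pz, po, pi)
        if tree.children_left[node] < 0:
            leaf = float(tree.value[node])
            for i in range(1, len(p.w)):
                w = _unwound_sum(p, i)
                phi[p.d[i]] += w * (p.o[i] - p.z[i]) * leaf
            return
        d = int(tree.feature[node])
        left, right = int(tree.children_left[node]), int(tree.children_right[node])
        hot, cold = (left, right) if x[d] <= tree.threshold[node] else (right, left)
        iz = io = 1.0
        k = None
        for i in range(1, len(p.d)):
            if p.d[i] == d:
                k = i
                break
        if k is not None:
            iz, io = p.z[k], p.o[k]
            _unwind(p, k)
        total = tree.cover[node]
        recurse(hot, p, iz * tree.cover[hot] / total, io, d)
        recurse(cold, p, iz * tree.cover[cold] / total, 0.0, d)

    recurse(0, _Path(), 1.0, 1.0, -1)


def tree_shap_values(
    trees: list[TreeData],
    scales: list[float],
    offset: float,
    X: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Path-algorithm attributions for an ensemble; returns (phi, base) with
    base + phi.sum(axis=1) equal to the raw model output for each row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    phi = np.zeros((n, p))
    base = offset
    for tree, scale in zip(trees, scales):
        base += scale * tree_expected_value(tree, np.zeros(p), frozenset())
        tree_phi = np.zeros(p)
        for i in range(n):
            tree_phi[:] = 0.0
            _tree_shap_single(tree, X[i], tree_phi)
            phi[i] += scale * tree_phi
    return phi, float(base)
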