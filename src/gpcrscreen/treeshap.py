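"""Exact Shapley attributions for decision-tree ensembles.

Implements the path-dependent polynomial-time Tree SHAP recursion for
scikit-learn decision trees and random forests.  The value function for
a feature coalition S is the tree's expected output when features in S
are fixed to the explained sample and features outside S are marginalized
along the tree structure, weighting each branch by its training cover.
The algorithm returns the exact Shapley values of that function, so the
local-accuracy identity

    base_value + sum_i phi_i = f(x)

holds to floating-point precision for every sample; this is asserted by
the test suite against exhaustive coalition enumeration on small trees.

For a forest, attributions and base values are averaged over trees,
matching the forest's averaged probability output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor


@dataclass
class TreeArrays:
    """Flat array view of one decision tree."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    cover: np.ndarray   # weighted training samples reaching each node
    value: np.ndarray   # scalar output per node (leaf values are used)

    @classmethod
    def from_sklearn(cls, tree, class_index: int | None) -> "TreeArrays":
        t = tree.tree_
        raw = t.value  # (n_nodes, 1, n_outputs) — probabilities or means
        if class_index is not None:
            val = raw[:, 0, :]
            totals = val.sum(axis=1)
            out = np.where(totals > 0, val[:, class_index] / np.maximum(totals, 1e-300), 0.0)
            # newer sklearn stores normalized probabilities already; the
            # division above is then a no-op
        else:
            out = raw[:, 0, 0]
        return cls(t.children_left.copy(), t.children_right.copy(),
                   t.feature.copy(), t.threshold.copy(),
                   t.weighted_n_node_samples.copy(), np.asarray(out, float))

    def expected_value(self) -> float:
        """Cover-weighted mean leaf output (the empty-coalition value)."""
        total = 0.0
        root_cover = self.cover[0]
        stack = [0]
        while stack:
            j = stack.pop()
            if self.children_left[j] < 0:
                total += self.value[j] * self.cover[j] / root_cover
            else:
                stack.extend((self.children_left[j], self.children_right[j]))
        return total


def _tree_shap(tree: TreeArrays, x: np.ndarray, phi: np.ndarray) -> None:
    """Path-dependent Tree SHAP for one sample, accumulated into ``phi``."""

    def extend(m, pz, po, pi):
        l = len(m)
        m = [row.copy() for row in m]
        m.append([pi, pz, po, 1.0 if l == 0 else 0.0])
        for i in range(l - 1, -1, -1):
            m[i + 1][3] += po * m[i][3] * (i + 1) / (l + 1)
            m[i][3] = pz * m[i][3] * (l - i) / (l + 1)
        return m

    def unwind(m, i):
        l = len(m) - 1
        o_i, z_i = m[i][2], m[i][1]
        out = [row.copy() for row in m]
        n = out[l][3]
        for j in range(l - 1, -1, -1):
            if o_i != 0:
                t = out[j][3]
                out[j][3] = n * (l + 1) / ((j + 1) * o_i)
                n = t - out[j][3] * z_i * (l - j) / (l + 1)
            else:
                out[j][3] = out[j][3] * (l + 1) / (z_i * (l - j))
        for j in range(i, l):
            out[j][0], out[j][1], out[j][2] = out[j + 1][0], out[j + 1][1], out[j + 1][2]
        return out[:-1]

    def unwound_sum(m, i):
        l = len(m) - 1
        o_i, z_i = m[i][2], m[i][1]
        total, n = 0.0, m[l][3]
        for j in range(l - 1, -1, -1):
            if o_i != 0:
                t = n * (l + 1) / ((j + 1) * o_i)
                total += t
                n = m[j][3] - t * z_i * (l - j) / (l + 1)
            else:
                total += m[j][3] * (l + 1) / (z_i * (l - j))
        return total

    def recurse(j, m, pz, po, pi):
        m = extend(m, pz, po, pi)
        if tree.children_left[j] < 0:  # leaf
            for i in range(1, len(m)):
                w = unwound_sum(m, i)
                phi[m[i][0]] += w * (m[i][2] - m[i][1]) * tree.value[j]
            return
        f = int(tree.feature[j])
        left, right = int(tree.children_left[j]), int(tree.children_right[j])
        hot, cold = (left, right) if x[f] <= tree.threshold[j] else (right, left)
        iz, io = 1.0, 1.0
        k = next((idx for idx in range(1, len(m)) if m[idx][0] == f), None)
        if k is not None:
            iz, io = m[k][1], m[k][2]
            m = unwind(m, k)
        rj = tree.cover[j]
        recurse(hot, m, iz * tree.cover[hot] / rj, io, f)
        recurse(cold, m, iz * tree.cover[cold] / rj, 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)


@dataclass
class AttributionReport:
    """Additive per-feature attributions for each explained sample.

    ``values[s, f]`` is the signed contribution of feature ``f`` to
    sample ``s``'s predicted probability; ``base_value`` is the
    cover-weighted expected model output, shared by all samples.
    """

    values: np.ndarray          # (n_samples, n_features)
    base_value: float
    feature_names: list[str]
    predictions: np.ndarray     # model output the attributions reconstruct

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)

    def ranking(self) -> list[tuple[str, float]]:
        """Features sorted by global importance (mean |attribution|)."""
        ma = self.mean_abs()
        order = np.argsort(-ma)
        return [(self.feature_names[i], float(ma[i])) for i in order]


def shap_values(model, X: np.ndarray,
                feature_names: Sequence[str] | None = None,
                class_index: int | None = None) -> AttributionReport:
    """Exact path-dependent Shapley attributions for a tree ensemble.

    ``model`` may be a fitted sklearn decision tree or random forest.
    For classifiers, attributions explain the predicted probability of
    ``class_index`` (default: the last class).  Raises ``TypeError`` for
    unsupported model families.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if isinstance(model, (RandomForestClassifier, RandomForestRegressor)):
        estimators = list(model.estimators_)
    elif isinstance(model, (DecisionTreeClassifier, DecisionTreeRegressor)):
        estimators = [model]
    else:
        raise TypeError(
            f"unsupported model type {type(model).__name__}: "
            "Shapley attributions require a tree or tree ensemble")
    is_classifier = isinstance(model, (RandomForestClassifier,
                                       DecisionTreeClassifier))
    if is_classifier:
        if class_index is None:
            class_index = len(model.classes_) - 1
        trees = [TreeArrays.from_sklearn(e, class_index) for e in estimators]
        preds = model.predict_proba(X)[:, class_index]
    else:
        trees = [TreeArrays.from_sklearn(e, None) for e in estimators]
        preds = model.predict(X)

    n_features = X.shape[1]
    phi = np.zeros((X.shape[0], n_features))
    for tree in trees:
        for s in range(X.shape[0]):
            row = np.zeros(n_features + 1)  # slot -1 absorbs the root dummy
            _tree_shap(tree, X[s], row)
            phi[s] += row[:n_features]
    phi /= len(trees)
    base = float(np.mean([t.expected_value() for t in trees]))
    names = (list(feature_names) if feature_names is not None
             else [f"f{i}" for i in range(n_features)])
    return AttributionReport(values=phi, base_value=base,
                             feature_names=names, predictions=preds)
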