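"""Shapley-value explanations for the encounter-based forest.

Per-feature contributions φ_j are computed with the polynomial-time
path-dependent tree Shapley algorithm: the value function is the
conditional expectation of the tree output obtained by descending the tree
and, for features outside the coalition, averaging the children weighted by
their background cover.  Each tree is explained against its own training
sub-sample (whose cover weights the fitted tree already carries), and the
ensemble explanation is the plain average of the per-tree explanations —
valid because the ensemble prediction is itself the average of tree
outputs, so local accuracy (φ_0 + Σ_j φ_j = f(x)) carries over by
linearity.

An exhaustive 2^M subset-enumeration implementation of the same value
function (`exhaustive_shapley`) is provided as an independent reference for
validating the polynomial algorithm on small trees.

Contributions are in probability units, so a φ of +0.1 reads directly as
"+10 percentage points of red-flag risk from this feature".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .forest import EFModel, predict_proba


# ---------------------------------------------------------------------------
# tree plumbing


@dataclass
class _TreeArrays:
    """Flat arrays of a fitted sklearn tree plus background cover weights."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    missing_go_to_left: np.ndarray
    leaf_p1: np.ndarray  # positive-class probability per node
    weights: np.ndarray  # background cover per node


def _positive_index(tree: DecisionTreeClassifier) -> int | None:
    classes = list(tree.classes_)
    return classes.index(1) if 1 in classes else None


def _node_p1(tree: DecisionTreeClassifier) -> np.ndarray:
    value = tree.tree_.value[:, 0, :]
    # sklearn >= 1.4 stores class fractions; normalise defensively
    totals = value.sum(axis=1)
    frac = np.divide(value.T, np.where(totals == 0, 1.0, totals)).T
    pi = _positive_index(tree)
    return frac[:, pi] if pi is not None else np.zeros(len(frac))


def _background_weights(tree: DecisionTreeClassifier, background: np.ndarray) -> np.ndarray:
    """Cover of each node under a background sample, honouring NaN routing."""
    t = tree.tree_
    weights = np.zeros(t.node_count)
    paths = tree.decision_path(background)  # sklearn applies missing routing
    weights += np.asarray(paths.sum(axis=0)).ravel()
    return weights


def _tree_arrays(
    tree: DecisionTreeClassifier, background: np.ndarray | None = None
) -> _TreeArrays:
    t = tree.tree_
    if background is None:
        weights = t.weighted_n_node_samples.copy()
    else:
        weights = _background_weights(tree, background)
    return _TreeArrays(
        children_left=t.children_left,
        children_right=t.children_right,
        feature=t.feature,
        threshold=t.threshold,
        missing_go_to_left=getattr(t, "missing_go_to_left", np.zeros(t.node_count)),
        leaf_p1=_node_p1(tree),
        weights=weights,
    )


def _goes_left(x_val: float, threshold: float, missing_left: bool) -> bool:
    if np.isnan(x_val):
        return missing_left
    return x_val <= threshold


def tree_predict_p1(tree: DecisionTreeClassifier, x: np.ndarray) -> float:
    """Single-row positive probability via explicit traversal (NaN-aware)."""
    a = _tree_arrays(tree)
    node = 0
    while a.children_left[node] != -1:
        if _goes_left(x[a.feature[node]], a.threshold[node], bool(a.missing_go_to_left[node])):
            node = a.children_left[node]
        else:
            node = a.children_right[node]
    return float(a.leaf_p1[node])


# ---------------------------------------------------------------------------
# path-dependent tree Shapley (polynomial algorithm)


def _extend(m: list[list[float]], pz: float, po: float, pi: int) -> list[list[float]]:
    l = len(m)
    m = [e.copy() for e in m]
    m.append([pi, pz, po, 1.0 if l == 0 else 0.0])
    for i in range(l - 1, -1, -1):
        m[i + 1][3] += po * m[i][3] * (i + 1) / (l + 1)
        m[i][3] = pz * m[i][3] * (l - i) / (l + 1)
    return m


def _unwind(m: list[list[float]], i: int) -> list[list[float]]:
    L = len(m)
    n = m[L - 1][3]
    zi, oi = m[i][1], m[i][2]
    out = [e.copy() for e in m[: L - 1]]
    for j in range(L - 2, -1, -1):
        if oi != 0:
            t = out[j][3]
            out[j][3] = n * L / ((j + 1) * oi)
            n = t - out[j][3] * zi * (L - 1 - j) / L
        else:
            out[j][3] = out[j][3] * L / (zi * (L - 1 - j))
    for j in range(i, L - 1):
        out[j][0], out[j][1], out[j][2] = m[j + 1][0], m[j + 1][1], m[j + 1][2]
    return out


def _unwound_sum(m: list[list[float]], i: int) -> float:
    """Sum of path weights after unwinding entry i, without materialising it."""
    L = len(m)
    n = m[L - 1][3]
    zi, oi = m[i][1], m[i][2]
    total = 0.0
    if oi != 0:
        for j in range(L - 2, -1, -1):
            w = n * L / ((j + 1) * oi)
            total += w
            n = m[j][3] - w * zi * (L - 1 - j) / L
    else:
        for j in range(L - 2, -1, -1):
            total += m[j][3] * L / (zi * (L - 1 - j))
    return total


def _shap_recurse(
    a: _TreeArrays,
    x: np.ndarray,
    phi: np.ndarray,
    node: int,
    m: list[list[float]],
    pz: float,
    po: float,
    pi: int,
) -> None:
    if pz == 0.0 and po == 0.0:
        return  # zero-cover excluded branch: the whole subtree contributes 0
    m = _extend(m, pz, po, pi)
    left, right = a.children_left[node], a.children_right[node]
    if left == -1:
        leaf = a.leaf_p1[node]
        for i in range(1, len(m)):
            w = _unwound_sum(m, i)
            phi[int(m[i][0])] += w * (m[i][2] - m[i][1]) * leaf
        return
    d = int(a.feature[node])
    if _goes_left(x[d], a.threshold[node], bool(a.missing_go_to_left[node])):
        hot, cold = left, right
    else:
        hot, cold = right, left
    w_node = a.weights[node]
    r_hot = a.weights[hot] / w_node if w_node > 0 else 0.0
    r_cold = a.weights[cold] / w_node if w_node > 0 else 0.0
    iz, io = 1.0, 1.0
    k = next((i for i in range(1, len(m)) if int(m[i][0]) == d), None)
    if k is not None:
        iz, io = m[k][1], m[k][2]
        m = _unwind(m, k)
    _shap_recurse(a, x, phi, hot, m, iz * r_hot, io, d)
    _shap_recurse(a, x, phi, cold, m, iz * r_cold, 0.0, d)


def _base_value(a: _TreeArrays) -> float:
    leaves = a.children_left == -1
    total = a.weights[leaves].sum()
    if total == 0:
        return 0.0
    return float(np.dot(a.weights[leaves], a.leaf_p1[leaves]) / total)


def tree_shapley(
    tree: DecisionTreeClassifier,
    x: np.ndarray,
    background: np.ndarray | None = None,
    n_features: int | None = None,
) -> tuple[np.ndarray, float]:
    """Path-dependent Shapley contributions of one tree for one row.

    Returns ``(phi, phi0)`` where ``phi0`` is the cover-weighted mean leaf
    value under the background (the expected model output) and local
    accuracy ``phi0 + phi.sum() == f(x)`` holds.  With ``background=None``
    the tree's own training cover is used — for EF members this is exactly
    the bootstrap sub-sample the tree was fitted on.
    """
    x = np.asarray(x, dtype=float)
    M = n_features if n_features is not None else tree.n_features_in_
    if len(x) < M:
        raise ValueError(f"row has {len(x)} features; tree schema expects {M}")
    a = _tree_arrays(tree, background)
    phi = np.zeros(M)
    if a.children_left[0] == -1:  # single-leaf tree: constant game
        return phi, float(a.leaf_p1[0])
    _shap_recurse(a, x, phi, 0, [], 1.0, 1.0, -1)
    return phi, _base_value(a)


# ---------------------------------------------------------------------------
# exhaustive reference implementation


def _expvalue(a: _TreeArrays, x: np.ndarray, S: frozenset, node: int = 0) -> float:
    """Conditional expectation: follow x on S, cover-average otherwise."""
    left, right = a.children_left[node], a.children_right[node]
    if left == -1:
        return float(a.leaf_p1[node])
    d = int(a.feature[node])
    if d in S:
        child = (
            left
            if _goes_left(x[d], a.threshold[node], bool(a.missing_go_to_left[node]))
            else right
        )
        return _expvalue(a, x, S, child)
    w = a.weights
    if w[node] == 0:
        return 0.0
    return (
        w[left] * _expvalue(a, x, S, left) + w[right] * _expvalue(a, x, S, right)
    ) / w[node]


def exhaustive_shapley(
    tree: DecisionTreeClassifier,
    x: np.ndarray,
    background: np.ndarray | None = None,
    n_features: int | None = None,
) -> tuple[np.ndarray, float]:
    """Brute-force Shapley values by full 2^M coalition enumeration.

    Exponential in the number of features the tree actually splits on; meant
    as an independent correctness reference for `tree_shapley` on small
    trees, never for production explanation.
    """
    x = np.asarray(x, dtype=float)
    M = n_features if n_features is not None else tree.n_features_in_
    a = _tree_arrays(tree, background)
    used = sorted({int(f) for f in a.feature if f >= 0})
    phi = np.zeros(M)
    Mu = len(used)
    cache: dict[frozenset, float] = {}

    def v(S: frozenset) -> float:
        if S not in cache:
            cache[S] = _expvalue(a, x, S)
        return cache[S]

    for j in used:
        others = [f for f in used if f != j]
        for k in range(Mu):
            coef = factorial(k) * factorial(Mu - k - 1) / factorial(Mu)
            for S in combinations(others, k):
                S = frozenset(S)
                phi[j] += coef * (v(S | {j}) - v(S))
    return phi, v(frozenset())


# ---------------------------------------------------------------------------
# ensemble-level API


@dataclass
class Explanation:
    """Per-feature contributions for one prediction.

    ``base_value + contributions.sum()`` equals the model output (local
    accuracy).  ``feature_values`` carries the raw inputs so reports can
    colour-code high/low values.
    """

    feature_names: list[str]
    contributions: np.ndarray
    base_value: float
    model_output: float
    feature_values: np.ndarray

    def top_contributors(self, k: int = 10) -> list[tuple[str, float, float]]:
        return top_contributors(self, k)


def ensemble_explain(model: EFModel, row: pd.Series | pd.DataFrame) -> Explanation:
    """Average the per-tree Shapley explanations across the ensemble."""
    if isinstance(row, pd.DataFrame):
        if len(row) != 1:
            raise ValueError("ensemble_explain expects exactly one row")
        row = row.iloc[0]
    x = row[model.feature_names].to_numpy(dtype=float)
    M = len(model.feature_names)
    phi = np.zeros(M)
    phi0 = 0.0
    for tree in model.trees:
        p, p0 = tree_shapley(tree, x, n_features=M)
        phi += p
        phi0 += p0
    phi /= model.n_trees
    phi0 /= model.n_trees
    fx = float(predict_proba(model, row.to_frame().T)[0])
    return Explanation(
        feature_names=list(model.feature_names),
        contributions=phi,
        base_value=phi0,
        model_output=fx,
        feature_values=x,
    )


def top_contributors(expl: Explanation, k: int = 10) -> list[tuple[str, float, float]]:
    """Features sorted by |φ| descending; ties break by schema order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(
        range(len(expl.feature_names)), key=lambda j: (-abs(expl.contributions[j]), j)
    )
    return [
        (expl.feature_names[j], float(expl.contributions[j]), float(expl.feature_values[j]))
        for j in order[:k]
    ]


def global_importance(model: EFModel, population: pd.DataFrame) -> pd.Series:
    """Mean |φ| per feature over a population, descending."""
    if len(population) == 0:
        raise ValueError("population is empty")
    X = population[model.feature_names].to_numpy(dtype=float)
    return _global_importance_exact(model, X)


def _global_importance_exact(model: EFModel, X: np.ndarray) -> pd.Series:
    M = len(model.feature_names)
    arrays = [_tree_arrays(t) for t in model.trees]
    total = np.zeros(M)
    for i in range(len(X)):
        phi = np.zeros(M)
        for a in arrays:
            if a.children_left[0] == -1:
                continue
            _shap_recurse(a, X[i], phi, 0, [], 1.0, 1.0, -1)
        total += np.abs(phi / len(arrays))
    imp = pd.Series(total / len(X), index=model.feature_names)
    return imp.sort_values(ascending=False)


def explanation_table(expl: Explanation) -> pd.DataFrame:
    """Long-format explanation (feature, value, phi) for CSV output."""
    return pd.DataFrame(
        {
            "feature": expl.feature_names,
            "value": expl.feature_values,
            "phi": expl.contributions,
        }
    )
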