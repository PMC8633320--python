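"""Exact path-dependent TreeSHAP for sklearn decision-tree ensembles.

Computes Shapley-value feature attributions for tree regressors under the
path-dependent conditional expectation: when a feature is "absent" from a
coalition, the tree is descended through *both* children weighted by their
training-sample cover.  The polynomial-time algorithm tracks, along each
root-to-leaf path, the proportion of feature subsets of every size that flow
to the leaf, extending the path at each split and unwinding duplicate splits
on the same feature.

The per-sample attribution satisfies additivity exactly:
``baseline + sum(phi) == model.predict(x)`` (baseline is the cover-weighted
mean leaf value, i.e. the root value of each tree).
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_shap_values", "expected_value"]


def _extend(path: list[list[float]], pz: float, po: float, pi: int) -> None:
    """Append a split to the path and update subset-permutation weights in place.

    Each element is ``[feature_index, zero_fraction, one_fraction, pweight]``.
    """
    depth = len(path)
    path.append([pi, pz, po, 1.0 if depth == 0 else 0.0])
    for i in range(depth - 1, -1, -1):
        path[i + 1][3] += po * path[i][3] * (i + 1) / (depth + 1)
        path[i][3] = pz * path[i][3] * (depth - i) / (depth + 1)


def _unwound_sum(path: list[list[float]], index: int) -> float:
    """Total permutation weight the path would have if element ``index`` were removed."""
    depth = len(path) - 1
    one = path[index][2]
    zero = path[index][1]
    total = 0.0
    if one != 0:
        next_one = path[depth][3]
        for i in range(depth - 1, -1, -1):
            tmp = next_one * (depth + 1) / ((i + 1) * one)
            total += tmp
            next_one = path[i][3] - tmp * zero * (depth - i) / (depth + 1)
    else:
        for i in range(depth - 1, -1, -1):
            total += path[i][3] * (depth + 1) / (zero * (depth - i))
    return total


def _unwind(path: list[list[float]], index: int) -> None:
    """Remove element ``index`` from the path, restoring the weights, in place."""
    depth = len(path) - 1
    one = path[index][2]
    zero = path[index][1]
    next_one = path[depth][3]
    for i in range(depth - 1, -1, -1):
        if one != 0:
            tmp = path[i][3]
            path[i][3] = next_one * (depth + 1) / ((i + 1) * one)
            next_one = tmp - path[i][3] * zero * (depth - i) / (depth + 1)
        else:
            path[i][3] = path[i][3] * (depth + 1) / (zero * (depth - i))
    for i in range(index, depth):
        path[i][0] = path[i + 1][0]
        path[i][1] = path[i + 1][1]
        path[i][2] = path[i + 1][2]
    path.pop()


def _tree_shap_single(
    x: np.ndarray,
    phi: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    feature: np.ndarray,
    threshold: np.ndarray,
    value: np.ndarray,
    cover: np.ndarray,
) -> None:
    """Accumulate one tree's SHAP values for one sample into ``phi``."""

    def recurse(node: int, path: list[list[float]], pz: float, po: float, pi: int) -> None:
        path = [el.copy() for el in path]
        _extend(path, pz, po, pi)
        if left[node] < 0:  # leaf
            leaf = value[node]
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                phi[int(path[i][0])] += w * (path[i][2] - path[i][1]) * leaf
            return
        hot, cold = (
            (left[node], right[node])
            if x[feature[node]] <= threshold[node]
            else (right[node], left[node])
        )
        iz, io = 1.0, 1.0
        for k in range(1, len(path)):  # previous split on this feature?
            if path[k][0] == feature[node]:
                iz, io = path[k][1], path[k][2]
                _unwind(path, k)
                break
        recurse(hot, path, iz * cover[hot] / cover[node], io, feature[node])
        recurse(cold, path, iz * cover[cold] / cover[node], 0.0, feature[node])

    recurse(0, [], 1.0, 1.0, -1)


def _sklearn_trees(model):
    """Yield (tree arrays, weight) for a DecisionTreeRegressor or forest."""
    if hasattr(model, "estimators_"):  # forest: prediction is the mean over trees
        trees = [est.tree_ for est in model.estimators_]
        weight = 1.0 / len(trees)
    else:
        trees = [model.tree_]
        weight = 1.0
    for t in trees:
        yield (
            t.children_left,
            t.children_right,
            t.feature,
            t.threshold,
            t.value[:, 0, 0],
            t.weighted_n_node_samples,
        ), weight


def expected_value(model) -> float:
    """Cover-weighted mean prediction of the ensemble (the SHAP baseline)."""
    if hasattr(model, "get_booster"):  # xgboost: delegated in tree_shap_values
        raise TypeError("use tree_shap_values for xgboost models")
    return float(sum(arrays[4][0] * w for arrays, w in _sklearn_trees(model)))


def tree_shap_values(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """SHAP value matrix (n_samples x n_features) and baseline for a tree model.

    Supports sklearn DecisionTreeRegressor / RandomForestRegressor (own
    implementation) and xgboost XGBRegressor (native ``pred_contribs``).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")

    if hasattr(model, "get_booster"):
        import xgboost as xgb

        booster = model.get_booster()
        if booster.num_features() != X.shape[1]:
            raise ValueError(
                f"model was trained on {booster.num_features()} features, got {X.shape[1]}"
            )
        contribs = booster.predict(xgb.DMatrix(X), pred_contribs=True)
        return contribs[:, :-1], float(contribs[0, -1])

    n_features = getattr(model, "n_features_in_", X.shape[1])
    if n_features != X.shape[1]:
        raise ValueError(f"model was trained on {n_features} features, got {X.shape[1]}")
    phi = np.zeros_like(X)
    for arrays, weight in _sklearn_trees(model):
        left, right, feature, threshold, value, cover = arrays
        for row in range(X.shape[0]):
            tree_phi = np.zeros(X.shape[1])
            _tree_shap_single(X[row], tree_phi, left, right, feature, threshold, value, cover)
            phi[row] += weight * tree_phi
    return phi, expected_value(model)
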