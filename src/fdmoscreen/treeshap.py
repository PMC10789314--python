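"""Path-dependent TreeSHAP for scikit-learn decision trees and forests.

Computes exact Shapley values for tree ensembles under the
"tree-path-dependent" value function: the conditional expectation of the
tree output when a feature subset is withheld is estimated by splitting
flow according to the training cover (weighted node sample counts).  This
is the polynomial-time algorithm of Lundberg et al. for tree models; the
recursion keeps a path of unique features with their one/zero fractions
and Shapley permutation weights, extending on the way down and unwinding
at leaves.

Gradient-boosting backends (XGBoost, LightGBM) expose the same algorithm
natively through their ``pred_contribs`` predictors; this module covers
the random-forest leg of the model ensemble.  The kernels are numba-jitted;
correctness is guarded by additivity (contributions sum to the model
output) and, in the test suite, by a brute-force Shapley enumeration.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _extend(feat, zero, one, pw, off, unique_depth, pz, po, pi):
    feat[off + unique_depth] = pi
    zero[off + unique_depth] = pz
    one[off + unique_depth] = po
    pw[off + unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        pw[off + i + 1] += po * pw[off + i] * (i + 1.0) / (unique_depth + 1.0)
        pw[off + i] *= pz * (unique_depth - i) / (unique_depth + 1.0)


@njit(cache=False)
def _unwind(feat, zero, one, pw, off, unique_depth, path_index):
    one_fraction = one[off + path_index]
    zero_fraction = zero[off + path_index]
    next_one = pw[off + unique_depth]
    for i in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = pw[off + i]
            pw[off + i] = next_one * (unique_depth + 1.0) / ((i + 1.0) * one_fraction)
            next_one = tmp - pw[off + i] * zero_fraction * (unique_depth - i) / (unique_depth + 1.0)
        else:
            pw[off + i] = pw[off + i] * (unique_depth + 1.0) / (zero_fraction * (unique_depth - i))
    for i in range(path_index, unique_depth):
        feat[off + i] = feat[off + i + 1]
        zero[off + i] = zero[off + i + 1]
        one[off + i] = one[off + i + 1]


@njit(cache=False)
def _unwound_sum(zero, one, pw, off, unique_depth, path_index):
    one_fraction = one[off + path_index]
    zero_fraction = zero[off + path_index]
    next_one = pw[off + unique_depth]
    total = 0.0
    if one_fraction != 0.0:
        for i in range(unique_depth - 1, -1, -1):
            tmp = next_one / ((i + 1.0) * one_fraction)
            total += tmp
            next_one = pw[off + i] - tmp * zero_fraction * (unique_depth - i)
    else:
        for i in range(unique_depth - 1, -1, -1):
            total += pw[off + i] / (zero_fraction * (unique_depth - i))
    return total * (unique_depth + 1.0)


@njit(cache=False)
def _recurse(
    left,
    right,
    split_feature,
    threshold,
    cover,
    values,
    x,
    phi,
    node,
    unique_depth,
    parent_off,
    feat,
    zero,
    one,
    pw,
    parent_zero,
    parent_one,
    parent_feat,
):
    off = parent_off + unique_depth
    for i in range(unique_depth):
        feat[off + i] = feat[parent_off + i]
        zero[off + i] = zero[parent_off + i]
        one[off + i] = one[parent_off + i]
        pw[off + i] = pw[parent_off + i]
    _extend(feat, zero, one, pw, off, unique_depth, parent_zero, parent_one, parent_feat)

    if left[node] < 0:  # leaf
        for i in range(1, unique_depth + 1):
            w = _unwound_sum(zero, one, pw, off, unique_depth, i)
            f = feat[off + i]
            scale = w * (one[off + i] - zero[off + i])
            for j in range(values.shape[1]):
                phi[f, j] += scale * values[node, j]
        return

    d = split_feature[node]
    if x[d] <= threshold[node]:
        hot, cold = left[node], right[node]
    else:
        hot, cold = right[node], left[node]
    hot_zero = cover[hot] / cover[node]
    cold_zero = cover[cold] / cover[node]
    inc_zero = 1.0
    inc_one = 1.0

    path_index = 0
    while path_index <= unique_depth:
        if feat[off + path_index] == d:
            break
        path_index += 1
    if path_index != unique_depth + 1:
        inc_zero = zero[off + path_index]
        inc_one = one[off + path_index]
        _unwind(feat, zero, one, pw, off, unique_depth, path_index)
        unique_depth -= 1

    _recurse(
        left, right, split_feature, threshold, cover, values, x, phi,
        hot, unique_depth + 1, off, feat, zero, one, pw,
        hot_zero * inc_zero, inc_one, d,
    )
    _recurse(
        left, right, split_feature, threshold, cover, values, x, phi,
        cold, unique_depth + 1, off, feat, zero, one, pw,
        cold_zero * inc_zero, 0.0, d,
    )


@njit(cache=False)
def _tree_shap_matrix(left, right, split_feature, threshold, cover, values, X, n_features):
    n_samples = X.shape[0]
    n_out = values.shape[1]
    phi = np.zeros((n_samples, n_features, n_out))
    max_depth = _max_depth(left, right) + 2
    size = (max_depth + 1) * (max_depth + 2) // 2 + max_depth + 2
    feat = np.empty(size, dtype=np.int64)
    zero = np.empty(size)
    one = np.empty(size)
    pw = np.empty(size)
    for s in range(n_samples):
        _recurse(
            left, right, split_feature, threshold, cover, values, X[s], phi[s],
            0, 0, 0, feat, zero, one, pw, 1.0, 1.0, -1,
        )
    return phi


@njit(cache=False)
def _max_depth(left, right):
    n = left.shape[0]
    depth = np.zeros(n, dtype=np.int64)
    best = 0
    for node in range(n):
        if left[node] >= 0:
            depth[left[node]] = depth[node] + 1
            depth[right[node]] = depth[node] + 1
        if depth[node] > best:
            best = depth[node]
    return best


def _tree_arrays(tree, normalize_values: bool):
    """Extract flat arrays from a fitted sklearn ``Tree`` object."""
    values = tree.value[:, 0, :].astype(np.float64).copy()
    if normalize_values:
        sums = values.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        values = values / sums
    return (
        tree.children_left.astype(np.int64),
        tree.children_right.astype(np.int64),
        tree.feature.astype(np.int64),
        tree.threshold.astype(np.float64),
        tree.weighted_n_node_samples.astype(np.float64),
        values,
    )


def tree_shap_values(estimator, X, normalize_values: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """SHAP values for one fitted sklearn decision tree.

    Returns
    -------
    phi : (n_samples, n_features, n_outputs)
        Per-feature contributions to each output (class probability for
        classifiers).
    expected : (n_outputs,)
        The cover-weighted expected tree output (the SHAP base value);
        ``phi.sum(axis=1) + expected`` equals the tree's prediction.
    """
    left, right, feature, threshold, cover, values = _tree_arrays(
        estimator.tree_, normalize_values
    )
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = _tree_shap_matrix(left, right, feature, threshold, cover, values, X, X.shape[1])
    is_leaf = left < 0
    expected = (values[is_leaf] * cover[is_leaf, None]).sum(axis=0) / cover[0]
    return phi, expected


def forest_shap_values(forest, X) -> tuple[np.ndarray, np.ndarray]:
    """SHAP values for a fitted RandomForestClassifier/Regressor.

    The forest output is the mean over trees, so contributions and base
    values are tree averages.  For classifiers the explained output is the
    predicted class probability vector.
    """
    phis = None
    expected = None
    is_clf = hasattr(forest, "classes_")
    for est in forest.estimators_:
        p, e = tree_shap_values(est, X, normalize_values=is_clf)
        phis = p if phis is None else phis + p
        expected = e if expected is None else expected + e
    n = len(forest.estimators_)
    return phis / n, expected / n
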