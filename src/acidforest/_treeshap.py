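"""Exact Shapley attributions for scikit-learn tree ensembles.

Implements the polynomial-time "tree-path-dependent" Shapley value algorithm
for decision trees: coalition expectations are taken by following the tree and
splitting weight between children in proportion to their training cover when a
coalition does not fix the split feature.  The per-tree recursion keeps, for
every root-to-node path, the proportion of feature subsets of each size that
flow along it, extending and unwinding those proportions as features enter and
leave the path.

For a forest the attributions of the member trees are averaged, matching the
forest prediction being the mean of tree predictions, so for every row

    base_value + sum_j phi[j] == prediction

holds to numerical precision (this additivity is asserted in the test suite).

The recursion is JIT-compiled with numba when available; a pure-Python fallback
runs the identical code.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


def _extend_impl(f, z, o, pw, off, unique_depth, pzf, pof, pfi):
    f[off + unique_depth] = pfi
    z[off + unique_depth] = pzf
    o[off + unique_depth] = pof
    pw[off + unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        pw[off + i + 1] += pof * pw[off + i] * (i + 1.0) / (unique_depth + 1.0)
        pw[off + i] = pzf * pw[off + i] * (unique_depth - i) / (unique_depth + 1.0)


def _unwind_impl(f, z, o, pw, off, unique_depth, path_index):
    one = o[off + path_index]
    zero = z[off + path_index]
    nxt = pw[off + unique_depth]
    for i in range(unique_depth - 1, -1, -1):
        if one != 0.0:
            tmp = pw[off + i]
            pw[off + i] = nxt * (unique_depth + 1.0) / ((i + 1.0) * one)
            nxt = tmp - pw[off + i] * zero * (unique_depth - i) / (unique_depth + 1.0)
        else:
            pw[off + i] = pw[off + i] * (unique_depth + 1.0) / (zero * (unique_depth - i))
    for i in range(path_index, unique_depth):
        f[off + i] = f[off + i + 1]
        z[off + i] = z[off + i + 1]
        o[off + i] = o[off + i + 1]


def _unwound_sum_impl(z, o, pw, off, unique_depth, path_index):
    one = o[off + path_index]
    zero = z[off + path_index]
    total = 0.0
    if one != 0.0:
        nxt = pw[off + unique_depth]
        for i in range(unique_depth - 1, -1, -1):
            tmp = nxt / ((i + 1.0) * one)
            total += tmp
            nxt = pw[off + i] - tmp * zero * (unique_depth - i)
    else:
        for i in range(unique_depth - 1, -1, -1):
            total += pw[off + i] / (zero * (unique_depth - i))
    return total * (unique_depth + 1.0)


def _traverse_impl(
    cl, cr, feat, thr, val, wt, x, phi, f, z, o, pw,
    st_node, st_depth, st_off, st_pzf, st_pof, st_pfi,
):
    """Depth-first traversal replacing the recursion of the path algorithm.

    Each stack frame carries (node, unique_depth, parent path offset,
    zero/one fractions and feature of the incoming split); on expansion it
    copies the parent's unique path into its own slot of the shared buffer,
    so descendants never clobber an ancestor's path state.
    """
    top = 0
    st_node[0] = 0
    st_depth[0] = 0
    st_off[0] = 0
    st_pzf[0] = 1.0
    st_pof[0] = 1.0
    st_pfi[0] = -1
    while top >= 0:
        node = st_node[top]
        unique_depth = st_depth[top]
        off = st_off[top]
        pzf = st_pzf[top]
        pof = st_pof[top]
        pfi = st_pfi[top]
        top -= 1

        new_off = off + unique_depth + 1
        for i in range(unique_depth + 1):
            f[new_off + i] = f[off + i]
            z[new_off + i] = z[off + i]
            o[new_off + i] = o[off + i]
            pw[new_off + i] = pw[off + i]
        _extend(f, z, o, pw, new_off, unique_depth, pzf, pof, pfi)

        if cl[node] < 0:  # leaf
            for i in range(1, unique_depth + 1):
                w = _unwound_sum(z, o, pw, new_off, unique_depth, i)
                phi[f[new_off + i]] += w * (o[new_off + i] - z[new_off + i]) * val[node]
            continue

        split = feat[node]
        if x[split] <= thr[node]:
            hot, cold = cl[node], cr[node]
        else:
            hot, cold = cr[node], cl[node]
        w_node = wt[node]
        hot_zero = wt[hot] / w_node
        cold_zero = wt[cold] / w_node
        iz = 1.0
        io = 1.0
        path_index = 0
        while path_index <= unique_depth:
            if f[new_off + path_index] == split:
                break
            path_index += 1
        if path_index != unique_depth + 1:
            iz = z[new_off + path_index]
            io = o[new_off + path_index]
            _unwind(f, z, o, pw, new_off, unique_depth, path_index)
            unique_depth -= 1
        # push cold then hot (pop order is irrelevant to correctness)
        top += 1
        st_node[top] = cold
        st_depth[top] = unique_depth + 1
        st_off[top] = new_off
        st_pzf[top] = cold_zero * iz
        st_pof[top] = 0.0
        st_pfi[top] = split
        top += 1
        st_node[top] = hot
        st_depth[top] = unique_depth + 1
        st_off[top] = new_off
        st_pzf[top] = hot_zero * iz
        st_pof[top] = io
        st_pfi[top] = split


if _HAVE_NUMBA:
    _extend = _njit(cache=False)(_extend_impl)
    _unwind = _njit(cache=False)(_unwind_impl)
    _unwound_sum = _njit(cache=False)(_unwound_sum_impl)
    _traverse = _njit(cache=False)(_traverse_impl)
else:  # pragma: no cover
    _extend = _extend_impl
    _unwind = _unwind_impl
    _unwound_sum = _unwound_sum_impl
    _traverse = _traverse_impl


def _tree_arrays(tree) -> tuple:
    """Flat node arrays of a fitted sklearn tree (regression, one output)."""
    t = tree.tree_
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        t.value[:, 0, 0].astype(np.float64),
        t.weighted_n_node_samples.astype(np.float64),
        int(t.max_depth),
    )


def tree_shap_values(tree, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley attributions for every row of ``X`` under a single tree.

    Returns ``(phi, base)`` where ``phi`` has shape (n_rows, n_features) and
    ``base`` is the tree's training-cover-weighted mean prediction (the root
    node value), so ``base + phi.sum(1) == tree.predict(X)``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    cl, cr, feat, thr, val, wt, maxd = _tree_arrays(tree)
    n_rows, n_feat = X.shape
    phi = np.zeros((n_rows, n_feat), dtype=np.float64)
    size = (maxd + 2) * (maxd + 3)
    f = np.zeros(size, dtype=np.int64)
    z = np.zeros(size, dtype=np.float64)
    o = np.zeros(size, dtype=np.float64)
    pw = np.zeros(size, dtype=np.float64)
    stack_size = 2 * (maxd + 2)
    st_node = np.zeros(stack_size, dtype=np.int64)
    st_depth = np.zeros(stack_size, dtype=np.int64)
    st_off = np.zeros(stack_size, dtype=np.int64)
    st_pzf = np.zeros(stack_size, dtype=np.float64)
    st_pof = np.zeros(stack_size, dtype=np.float64)
    st_pfi = np.zeros(stack_size, dtype=np.int64)
    for r in range(n_rows):
        _traverse(
            cl, cr, feat, thr, val, wt, X[r], phi[r], f, z, o, pw,
            st_node, st_depth, st_off, st_pzf, st_pof, st_pfi,
        )
    return phi, float(val[0])


def forest_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley attributions for a RandomForestRegressor (mean over trees)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros(X.shape, dtype=np.float64)
    base = 0.0
    for est in forest.estimators_:
        p, b = tree_shap_values(est, X)
        phi += p
        base += b
    n = len(forest.estimators_)
    return phi / n, base / n
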