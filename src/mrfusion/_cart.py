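"""Compiled CART kernels: greedy binary Gini splitting on a feature subset.

Trees are grown depth-first with explicit stacks. Candidate thresholds are
midpoints between consecutive distinct sorted values of each feature; the
best split minimizes the weighted Gini impurity of the children, with ties
broken deterministically toward the lower feature index and lower threshold
(first strictly-better candidate wins in scan order). Nodes become leaves
when pure, when no split reduces impurity, or at ``max_depth``; leaf labels
are the majority class with ties resolved to -1.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# node array layout: feature < 0 marks a leaf, its label stored in `value`
_EPS = 1e-12


@njit(cache=True)
def build_tree(X, y, max_depth, min_samples_leaf):
    """Grow a binary classification tree on labels in {-1, +1}.

    Returns (feature, threshold, left, right, value) arrays of length
    n_nodes. ``max_depth < 0`` means unlimited.
    """
    n, m = X.shape
    max_nodes = 2 * n + 1
    feature = np.full(max_nodes, -1, np.int32)
    threshold = np.zeros(max_nodes, np.float64)
    left = np.full(max_nodes, -1, np.int32)
    right = np.full(max_nodes, -1, np.int32)
    value = np.zeros(max_nodes, np.int8)

    idx = np.arange(n)
    # stack rows: start, end, depth, parent, is_left
    stack = np.empty((max_nodes, 5), np.int64)
    stack[0] = (0, n, 0, -1, 0)
    top = 1
    n_nodes = 0

    order = np.empty(n, np.int64)
    vals = np.empty(n, np.float64)

    while top > 0:
        top -= 1
        start, end, depth, parent, is_left = stack[top]
        node = n_nodes
        n_nodes += 1
        if parent >= 0:
            if is_left == 1:
                left[parent] = node
            else:
                right[parent] = node

        size = end - start
        n_neg = 0
        for i in range(start, end):
            if y[idx[i]] < 0:
                n_neg += 1
        n_pos = size - n_neg

        p = n_neg / size
        parent_gini = 2.0 * p * (1.0 - p)
        grown_out = max_depth >= 0 and depth >= max_depth
        if n_neg == 0 or n_pos == 0 or grown_out or size < 2 * min_samples_leaf:
            value[node] = -1 if n_neg >= n_pos else 1
            continue

        best_score = parent_gini - _EPS
        best_feat = -1
        best_thr = 0.0
        best_nl = 0

        for j in range(m):
            for i in range(size):
                vals[i] = X[idx[start + i], j]
            order[:size] = np.argsort(vals[:size], kind="mergesort")
            neg_left = 0
            for i in range(1, size):
                prev = vals[order[i - 1]]
                if y[idx[start + order[i - 1]]] < 0:
                    neg_left += 1
                cur = vals[order[i]]
                if cur <= prev:
                    continue
                nl = i
                nr = size - i
                if nl < min_samples_leaf or nr < min_samples_leaf:
                    continue
                pl = neg_left / nl
                pr = (n_neg - neg_left) / nr
                score = (
                    nl * 2.0 * pl * (1.0 - pl) + nr * 2.0 * pr * (1.0 - pr)
                ) / size
                if score < best_score - _EPS:
                    best_score = score
                    best_feat = j
                    best_thr = 0.5 * (prev + cur)
                    best_nl = nl

        if best_feat < 0:
            value[node] = -1 if n_neg >= n_pos else 1
            continue

        # partition idx[start:end] around the threshold (stable)
        buf = np.empty(size, np.int64)
        k = 0
        for i in range(start, end):
            if X[idx[i], best_feat] <= best_thr:
                buf[k] = idx[i]
                k += 1
        kk = k
        for i in range(start, end):
            if X[idx[i], best_feat] > best_thr:
                buf[kk] = idx[i]
                kk += 1
        for i in range(size):
            idx[start + i] = buf[i]

        feature[node] = best_feat
        threshold[node] = best_thr
        # push right first so the left child is processed (and numbered) first
        stack[top] = (start + best_nl, end, depth + 1, node, 0)
        top += 1
        stack[top] = (start, start + best_nl, depth + 1, node, 1)
        top += 1

    return (
        feature[:n_nodes].copy(),
        threshold[:n_nodes].copy(),
        left[:n_nodes].copy(),
        right[:n_nodes].copy(),
        value[:n_nodes].copy(),
    )


@njit(cache=True)
def predict_tree(feature, threshold, left, right, value, X):
    n = X.shape[0]
    out = np.empty(n, np.int8)
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = value[node]
    return out
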