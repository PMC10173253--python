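"""Numba kernels: biased random walks and skip-gram negative sampling.

Single-threaded by design — every kernel is exactly reproducible from its
seed, which the pipeline's determinism contract relies on.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Sigmoid lookup table, word2vec-style: sigmoid(x) for x in [-MAX_EXP, MAX_EXP].
_EXP_TABLE_SIZE = 1024
_MAX_EXP = 6.0
EXP_TABLE = (
    1.0
    / (1.0 + np.exp(-(np.arange(_EXP_TABLE_SIZE) / _EXP_TABLE_SIZE * 2.0 - 1.0) * _MAX_EXP))
).astype(np.float32)


@njit(cache=True)
def _weighted_pick(cumw, lo, hi, r):
    """Index in [lo, hi) with probability proportional to the weight slice;
    cumw holds the within-row cumulative weights."""
    total = cumw[hi - 1]
    target = r * total
    a, b = lo, hi - 1
    while a < b:
        mid = (a + b) // 2
        if cumw[mid] < target:
            a = mid + 1
        else:
            b = mid
    return a


@njit(cache=True)
def first_order_walks(indptr, indices, cumw, weighted, n_nodes,
                      walks_per_node, walk_length, seed):
    """Simple random walks; next node ~ edge weight (uniform if unweighted)."""
    np.random.seed(seed)
    walks = np.empty((n_nodes * walks_per_node, walk_length), dtype=np.int32)
    w = 0
    for _ in range(walks_per_node):
        for start in range(n_nodes):
            cur = start
            walks[w, 0] = cur
            for t in range(1, walk_length):
                lo, hi = indptr[cur], indptr[cur + 1]
                if weighted:
                    j = _weighted_pick(cumw, lo, hi, np.random.rand())
                else:
                    j = lo + np.random.randint(hi - lo)
                cur = indices[j]
                walks[w, t] = cur
            w += 1
    return walks


@njit(cache=True)
def _is_neighbor(indptr, indices, u, v):
    lo, hi = indptr[u], indptr[u + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        if indices[mid] < v:
            lo = mid + 1
        else:
            hi = mid
    return lo < indptr[u + 1] and indices[lo] == v


@njit(cache=True)
def second_order_walks(indptr, indices, weights, n_nodes, walks_per_node,
                       walk_length, p, q, seed):
    """p/q-biased walks: from v (arrived from t), candidate x gets weight
    w(v,x)/p if x == t, w(v,x) if x is adjacent to t, w(v,x)/q otherwise."""
    np.random.seed(seed)
    walks = np.empty((n_nodes * walks_per_node, walk_length), dtype=np.int32)
    max_deg = 0
    for v in range(n_nodes):
        d = indptr[v + 1] - indptr[v]
        if d > max_deg:
            max_deg = d
    probs = np.empty(max_deg, dtype=np.float64)
    w = 0
    for _ in range(walks_per_node):
        for start in range(n_nodes):
            cur = start
            walks[w, 0] = cur
            prev = -1
            for t in range(1, walk_length):
                lo, hi = indptr[cur], indptr[cur + 1]
                deg = hi - lo
                if prev < 0:
                    # first step: plain weight-proportional transition
                    total = 0.0
                    for idx in range(deg):
                        probs[idx] = weights[lo + idx]
                        total += probs[idx]
                else:
                    total = 0.0
                    for idx in range(deg):
                        x = indices[lo + idx]
                        bias = 1.0 / q
                        if x == prev:
                            bias = 1.0 / p
                        elif _is_neighbor(indptr, indices, prev, x):
                            bias = 1.0
                        probs[idx] = weights[lo + idx] * bias
                        total += probs[idx]
                r = np.random.rand() * total
                acc = 0.0
                pick = deg - 1
                for idx in range(deg):
                    acc += probs[idx]
                    if r < acc:
                        pick = idx
                        break
                prev = cur
                cur = indices[lo + pick]
                walks[w, t] = cur
            w += 1
    return walks


@njit(cache=True, fastmath=True)
def train_skipgram(walks, n_nodes, dim, window, epochs, n_negative,
                   alpha0, alpha_min, neg_cum, exp_table, seed):
    """Skip-gram with negative sampling over walks-as-sentences.

    Linear learning-rate decay, per-position window subsampling and a
    unigram^0.75 negative table (via cumulative weights in ``neg_cum``),
    following the reference word2vec training scheme. Returns the input
    (center-word) vectors, one row per node.
    """
    np.random.seed(seed)
    syn0 = ((np.random.rand(n_nodes, dim) - 0.5) / dim).astype(np.float32)
    syn1 = np.zeros((n_nodes, dim), dtype=np.float32)
    neu1e = np.zeros(dim, dtype=np.float32)
    n_walks, walk_len = walks.shape
    total = epochs * n_walks
    done = 0
    table_size = exp_table.shape[0]
    max_exp = 6.0
    for _ in range(epochs):
        for wi in range(n_walks):
            alpha = np.float32(alpha0 + (alpha_min - alpha0) * (done / total))
            for pos in range(walk_len):
                center = walks[wi, pos]
                b = np.random.randint(window) + 1
                lo = pos - b
                if lo < 0:
                    lo = 0
                hi = pos + b + 1
                if hi > walk_len:
                    hi = walk_len
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    ctx = walks[wi, cpos]
                    v = syn0[center]
                    for j in range(dim):
                        neu1e[j] = 0.0
                    for neg in range(n_negative + 1):
                        if neg == 0:
                            target = ctx
                            label = np.float32(1.0)
                        else:
                            target = np.searchsorted(neg_cum, np.random.rand())
                            if target == ctx:
                                continue
                            label = np.float32(0.0)
                        u = syn1[target]
                        f = np.float32(0.0)
                        for j in range(dim):
                            f += v[j] * u[j]
                        if f >= max_exp:
                            g = (label - np.float32(1.0)) * alpha
                        elif f <= -max_exp:
                            g = label * alpha
                        else:
                            ti = int((f + max_exp) * (table_size / (2.0 * max_exp)))
                            g = (label - exp_table[ti]) * alpha
                        for j in range(dim):
                            neu1e[j] += g * u[j]
                        for j in range(dim):
                            u[j] += g * v[j]
                    for j in range(dim):
                        v[j] += neu1e[j]
            done += 1
    return syn0
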