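"""Numba kernel for the weighted cross-entropy graph layout.

Single-threaded, sequential stochastic gradient descent over the edges of
the joint neighborhood graph with uniform negative sampling, in the style
of the UMAP family of layout optimizers.  The kernel is resumable: it
advances the sampling state arrays in place between ``epoch_start`` and
``epoch_end`` so callers can interleave loss evaluation without touching
the random stream.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(inline="always", cache=True)
def _xorshift(state):
    s = state[0]
    s ^= s << np.uint64(13)
    s ^= s >> np.uint64(7)
    s ^= s << np.uint64(17)
    state[0] = s
    return s


@numba.njit(inline="always", cache=True)
def _clip(val):
    if val > 4.0:
        return 4.0
    if val < -4.0:
        return -4.0
    return val


@numba.njit(cache=True)
def optimize_epochs(
    emb,  # (N, d) float32, updated in place
    heads,  # (E,) int64, one entry per undirected edge
    tails,  # (E,) int64
    attract_w,  # (E,) float32 dataset weight on attractive updates
    repulse_w,  # (E,) float32 dataset weight on repulsive updates
    pool_start1,  # (E,) int64: first global index of the edge's first sampling pool
    pool_len1,  # (E,) int64
    pool_start2,  # (E,) int64: second pool (0-length when unused)
    pool_len2,  # (E,) int64
    epochs_per_sample,  # (E,) float64
    epoch_of_next_sample,  # (E,) float64, advanced in place
    epoch_of_next_negative,  # (E,) float64, advanced in place
    epoch_start,
    epoch_end,
    n_epochs_total,
    a,
    b,
    gamma,
    initial_alpha,
    negative_sample_rate,
    rng_state,  # (1,) uint64, advanced in place
):
    n_points, dim = emb.shape
    n_edges = heads.shape[0]
    for epoch in range(epoch_start, epoch_end):
        alpha = initial_alpha * (1.0 - epoch / n_epochs_total)
        for e in range(n_edges):
            if epoch_of_next_sample[e] > epoch:
                continue
            i = heads[e]
            j = tails[e]
            w_att = attract_w[e]
            dist2 = 0.0
            for d in range(dim):
                diff = emb[i, d] - emb[j, d]
                dist2 += diff * diff
            if dist2 > 0.0:
                coeff = (-2.0 * a * b * pow(dist2, b - 1.0)) / (
                    a * pow(dist2, b) + 1.0
                )
            else:
                coeff = 0.0
            for d in range(dim):
                grad = _clip(coeff * (emb[i, d] - emb[j, d]))
                emb[i, d] += w_att * alpha * grad
                emb[j, d] -= w_att * alpha * grad
            epoch_of_next_sample[e] += epochs_per_sample[e]

            eps_neg = epochs_per_sample[e] / negative_sample_rate
            n_neg = int((epoch - epoch_of_next_negative[e]) / eps_neg)
            w_rep = repulse_w[e]
            pool = pool_len1[e] + pool_len2[e]
            for _ in range(n_neg):
                r = int(_xorshift(rng_state) % np.uint64(pool))
                if r < pool_len1[e]:
                    k = pool_start1[e] + r
                else:
                    k = pool_start2[e] + (r - pool_len1[e])
                if k == i:
                    continue
                dist2 = 0.0
                for d in range(dim):
                    diff = emb[i, d] - emb[k, d]
                    dist2 += diff * diff
                if dist2 > 0.0:
                    coeff = (2.0 * gamma * b) / (
                        (0.001 + dist2) * (a * pow(dist2, b) + 1.0)
                    )
                    for d in range(dim):
                        grad = _clip(coeff * (emb[i, d] - emb[k, d]))
                        emb[i, d] += w_rep * alpha * grad
                else:
                    for d in range(dim):
                        emb[i, d] += w_rep * alpha * 4.0
            epoch_of_next_negative[e] += n_neg * eps_neg
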