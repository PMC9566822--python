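"""Numba kernels for the collapsed Gibbs LDA sampler.

The inner loop resamples one topic assignment per token per sweep from

    p(z_i = k | z_-i, w) ∝ (n_dk + α) (n_kw + β) / (n_k + V β)

with all counts excluding token i.  Randomness comes from an inline
xorshift64* generator whose state is threaded through the kernels, so runs
are bit-reproducible for a fixed seed regardless of threading or library
RNG state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MULT = np.uint64(2685821657736338717)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _next_u64(state):
    s = state[0]
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    state[0] = s
    return s * _MULT


@njit(cache=True, inline="always")
def _next_uniform(state):
    return float(_next_u64(state) >> np.uint64(11)) * _INV53


@njit(cache=True)
def seed_state(seed):
    state = np.empty(1, dtype=np.uint64)
    s = np.uint64(seed) * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
    if s == np.uint64(0):
        s = np.uint64(0x9E3779B97F4A7C15)
    state[0] = s
    # warm up to decorrelate nearby seeds
    for _ in range(8):
        _next_u64(state)
    return state


@njit(cache=True)
def init_assignments(doc_of, word_of, K, V, state):
    n = doc_of.size
    D = doc_of.max() + 1 if n > 0 else 0
    z = np.empty(n, dtype=np.int32)
    n_kw = np.zeros((K, V), dtype=np.int64)
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    for i in range(n):
        k = int(_next_uniform(state) * K)
        if k == K:
            k = K - 1
        z[i] = k
        n_kw[k, word_of[i]] += 1
        n_dk[doc_of[i], k] += 1
        n_k[k] += 1
    return z, n_kw, n_dk, n_k


@njit(cache=True)
def gibbs_sweep(doc_of, word_of, z, n_kw, n_dk, n_k, alpha, beta, state):
    """One full sweep over all tokens, updating counts in place."""
    K, V = n_kw.shape
    vbeta = V * beta
    p = np.empty(K, dtype=np.float64)
    for i in range(doc_of.size):
        d = doc_of[i]
        w = word_of[i]
        k = z[i]
        n_kw[k, w] -= 1
        n_dk[d, k] -= 1
        n_k[k] -= 1
        tot = 0.0
        for kk in range(K):
            tot += (n_dk[d, kk] + alpha) * (n_kw[kk, w] + beta) / (n_k[kk] + vbeta)
            p[kk] = tot
        u = _next_uniform(state) * tot
        knew = 0
        while p[knew] < u and knew < K - 1:
            knew += 1
        z[i] = knew
        n_kw[knew, w] += 1
        n_dk[d, knew] += 1
        n_k[knew] += 1


@njit(cache=True)
def fold_in_sweeps(doc_of, word_of, n_kw, n_k, K, alpha, beta, n_sweeps, state):
    """Estimate doc-topic counts for held-out docs with topic-word counts frozen."""
    V = n_kw.shape[1]
    vbeta = V * beta
    n = doc_of.size
    D = doc_of.max() + 1 if n > 0 else 0
    z = np.empty(n, dtype=np.int32)
    n_dk = np.zeros((D, K), dtype=np.int64)
    p = np.empty(K, dtype=np.float64)
    for i in range(n):
        k = int(_next_uniform(state) * K)
        if k == K:
            k = K - 1
        z[i] = k
        n_dk[doc_of[i], k] += 1
    for _ in range(n_sweeps):
        for i in range(n):
            d = doc_of[i]
            w = word_of[i]
            k = z[i]
            n_dk[d, k] -= 1
            tot = 0.0
            for kk in range(K):
                tot += (n_dk[d, kk] + alpha) * (n_kw[kk, w] + beta) / (n_k[kk] + vbeta)
                p[kk] = tot
            u = _next_uniform(state) * tot
            knew = 0
            while p[knew] < u and knew < K - 1:
                knew += 1
            z[i] = knew
            n_dk[d, knew] += 1
    return n_dk
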