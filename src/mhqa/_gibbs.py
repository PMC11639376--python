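"""Collapsed Gibbs sampling kernel for LDA, compiled with numba.

The kernel owns its RNG (numba's MT19937, seeded inside the jitted function)
so a (corpus, K, iters, seed) tuple is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def gibbs_sample(
    token_word: np.ndarray,  # (N,) int32 word id per token
    token_doc: np.ndarray,  # (N,) int32 doc id per token
    K: int,
    V: int,
    D: int,
    alpha: float,
    beta: float,
    n_iters: int,
    seed: int,
):
    """Run collapsed Gibbs for LDA; returns (z, n_wk, n_dk, n_k)."""
    np.random.seed(seed)
    N = token_word.shape[0]
    z = np.empty(N, dtype=np.int32)
    n_wk = np.zeros((V, K), dtype=np.int64)
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    # random initial assignment
    for i in range(N):
        k = np.int32(np.random.random() * K)
        if k >= K:
            k = np.int32(K - 1)
        z[i] = k
        n_wk[token_word[i], k] += 1
        n_dk[token_doc[i], k] += 1
        n_k[k] += 1
    cum = np.empty(K, dtype=np.float64)
    vbeta = V * beta
    for _ in range(n_iters):
        for i in range(N):
            w = token_word[i]
            d = token_doc[i]
            k = z[i]
            n_wk[w, k] -= 1
            n_dk[d, k] -= 1
            n_k[k] -= 1
            total = 0.0
            for kk in range(K):
                p = (n_wk[w, kk] + beta) * (n_dk[d, kk] + alpha) / (n_k[kk] + vbeta)
                total += p
                cum[kk] = total
            u = np.random.random() * total
            knew = 0
            while knew < K - 1 and cum[knew] < u:
                knew += 1
            z[i] = knew
            n_wk[w, knew] += 1
            n_dk[d, knew] += 1
            n_k[knew] += 1
    return z, n_wk, n_dk, n_k
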