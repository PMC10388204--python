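"""Numba-compiled inner loops for HMM inference.

The forward-backward and Viterbi recursions are O(T K^2) with a strict
sequential dependency over frames, so they are the hot loops of the whole
pipeline (hundreds of traces x several K values x restarts x EM
iterations).  Both accept *unnormalized* initial/transition weights: the
scaled recursion absorbs any constant, which is exactly what variational
EM needs (its "tilde" parameters are sub-normalized geometric means).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward_backward_core", "viterbi_core"]


@njit(cache=True)
def forward_backward_core(pi, A, logB):  # pragma: no cover - jitted
    """Scaled forward-backward.

    Parameters: pi (K,) initial weights, A (K, K) transition weights,
    logB (T, K) per-frame log emission densities.
    Returns (loglik, gamma, xi_sum): log normalizer, per-frame posterior
    state probabilities, and summed two-slice transition posteriors.
    """
    T, K = logB.shape
    offs = np.empty(T)
    B = np.empty((T, K))
    for t in range(T):
        m = logB[t, 0]
        for k in range(1, K):
            if logB[t, k] > m:
                m = logB[t, k]
        offs[t] = m
        for k in range(K):
            B[t, k] = np.exp(logB[t, k] - m)

    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[0, k]
        s += alpha[0, k]
    if s <= 0.0:
        s = 1e-300
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * A[j, k]
            alpha[t, k] = acc * B[t, k]
            s += alpha[t, k]
        if s <= 0.0:
            s = 1e-300
        c[t] = s
        for k in range(K):
            alpha[t, k] /= s

    beta = np.ones(K)
    beta_next = np.empty(K)
    gamma = np.empty((T, K))
    xi = np.zeros((K, K))
    for k in range(K):
        gamma[T - 1, k] = alpha[T - 1, k]
    for t in range(T - 2, -1, -1):
        ct1 = c[t + 1]
        for j in range(K):
            acc = 0.0
            for k in range(K):
                acc += A[j, k] * B[t + 1, k] * beta[k]
            beta_next[j] = acc / ct1
        for j in range(K):
            for k in range(K):
                xi[j, k] += alpha[t, j] * A[j, k] * B[t + 1, k] * beta[k] / ct1
        g = 0.0
        for k in range(K):
            gamma[t, k] = alpha[t, k] * beta_next[k]
            g += gamma[t, k]
        if g > 0.0:
            for k in range(K):
                gamma[t, k] /= g
        for k in range(K):
            beta[k] = beta_next[k]

    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t]) + offs[t]
    return loglik, gamma, xi


@njit(cache=True)
def viterbi_core(log_pi, log_A, logB):  # pragma: no cover - jitted
    """Max-probability state path; ties broken toward the lower index.

    Returns (path, best_log_prob).
    """
    T, K = logB.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_pi[k] + logB[0, k]
    for t in range(1, T):
        for k in range(K):
            best = delta[t - 1, 0] + log_A[0, k]
            arg = 0
            for j in range(1, K):
                v = delta[t - 1, j] + log_A[j, k]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = j
            delta[t, k] = best + logB[t, k]
            psi[t, k] = arg
    best = delta[T - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best
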