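"""Numba-jitted forward, forward-backward and Viterbi recursions.

These operate on a precomputed (T, K) per-step emission probability matrix;
scaling keeps the forward pass stable for arbitrarily long bursts. A
non-positive (or non-finite) column sum at any step signals an impossible
observation under the parameters; the step index is returned so callers can
report it.
"""
import numpy as np
from numba import njit


@njit(cache=True)
def forward_scaled(delta, tmat, B):
    """Scaled forward pass. Returns (log-likelihood, failing step or -1)."""
    T, K = B.shape
    alpha = np.empty(K)
    c = 0.0
    for k in range(K):
        alpha[k] = delta[k] * B[0, k]
        c += alpha[k]
    if not (c > 0.0 and np.isfinite(c)):
        return -np.inf, 0
    ll = np.log(c)
    for k in range(K):
        alpha[k] /= c
    for t in range(1, T):
        new = np.zeros(K)
        for j in range(K):
            s = 0.0
            for i in range(K):
                s += alpha[i] * tmat[i, j]
            new[j] = s * B[t, j]
        c = 0.0
        for j in range(K):
            c += new[j]
        if not (c > 0.0 and np.isfinite(c)):
            return -np.inf, t
        ll += np.log(c)
        for j in range(K):
            alpha[j] = new[j] / c
    return ll, -1


@njit(cache=True)
def forward_backward(delta, tmat, B):
    """Smoothed state probabilities (T, K); rows sum to 1.

    Returns (posteriors, failing step or -1).
    """
    T, K = B.shape
    alphas = np.empty((T, K))
    cs = np.empty(T)
    c = 0.0
    for k in range(K):
        alphas[0, k] = delta[k] * B[0, k]
        c += alphas[0, k]
    if not (c > 0.0 and np.isfinite(c)):
        return alphas, 0
    cs[0] = c
    for k in range(K):
        alphas[0, k] /= c
    for t in range(1, T):
        c = 0.0
        for j in range(K):
            s = 0.0
            for i in range(K):
                s += alphas[t - 1, i] * tmat[i, j]
            alphas[t, j] = s * B[t, j]
            c += alphas[t, j]
        if not (c > 0.0 and np.isfinite(c)):
            return alphas, t
        cs[t] = c
        for j in range(K):
            alphas[t, j] /= c

    post = np.empty((T, K))
    beta = np.ones(K)
    for k in range(K):
        post[T - 1, k] = alphas[T - 1, k]
    for t in range(T - 2, -1, -1):
        newb = np.empty(K)
        for i in range(K):
            s = 0.0
            for j in range(K):
                s += tmat[i, j] * B[t + 1, j] * beta[j]
            newb[i] = s / cs[t + 1]
        tot = 0.0
        for k in range(K):
            post[t, k] = alphas[t, k] * newb[k]
            tot += post[t, k]
        for k in range(K):
            post[t, k] /= tot
        beta = newb
    return post, -1


@njit(cache=True)
def viterbi_path(log_delta, log_tmat, logB):
    """Most likely state path in log space; ties resolve to the lower index."""
    T, K = logB.shape
    dp = np.empty(K)
    for k in range(K):
        dp[k] = log_delta[k] + logB[0, k]
    back = np.zeros((T, K), np.int64)
    for t in range(1, T):
        new = np.empty(K)
        for j in range(K):
            best = -np.inf
            arg = 0
            for i in range(K):
                v = dp[i] + log_tmat[i, j]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = i
            new[j] = best + logB[t, j]
            back[t, j] = arg
        dp = new
    path = np.empty(T, np.int64)
    best = -np.inf
    arg = 0
    for k in range(K):
        if dp[k] > best:
            best = dp[k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path
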