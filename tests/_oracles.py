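"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: emissions go through
scipy.stats, HMM quantities are computed by explicit enumeration over all
state paths, and geometry checks use direct O(n^2) re-implementations.
"""
import itertools

import numpy as np
from scipy import stats


def oracle_emissions(series, params):
    """(T, K) emission likelihoods via scipy.stats densities."""
    T, K = len(series), params.n_states
    B = np.empty((T, K))
    for k in range(K):
        shape = params.step_means[k] ** 2 / params.step_sds[k] ** 2
        scale = params.step_sds[k] ** 2 / params.step_means[k]
        z = params.zero_mass[k]
        step = np.where(
            series.lengths == 0,
            z,
            (1 - z) * stats.gamma.pdf(series.lengths, shape, scale=scale),
        )
        kappa = params.kappas[k]
        if kappa == 0:
            vm = np.full(T, 1.0 / (2 * np.pi))
        else:
            vm = stats.vonmises.pdf(
                np.nan_to_num(series.angles), kappa, loc=params.angle_means[k]
            )
        ang = np.where(np.isnan(series.angles), 1.0, vm)
        B[:, k] = step * ang
    return B


def _path_prob(path, delta, tmat, B):
    p = delta[path[0]] * B[0, path[0]]
    for t in range(1, len(path)):
        p *= tmat[path[t - 1], path[t]] * B[t, path[t]]
    return p


def enum_loglik(series, params, delta=None):
    """log sum over all K^T state paths of the joint likelihood."""
    delta = params.delta if delta is None else np.asarray(delta, float)
    B = oracle_emissions(series, params)
    T, K = B.shape
    total = sum(
        _path_prob(path, delta, params.tmat, B)
        for path in itertools.product(range(K), repeat=T)
    )
    return np.log(total)


def enum_viterbi(series, params, delta=None):
    """argmax path by enumeration; lexicographic order breaks ties low."""
    delta = params.delta if delta is None else np.asarray(delta, float)
    B = oracle_emissions(series, params)
    T, K = B.shape
    best, best_path = -1.0, None
    for path in itertools.product(range(K), repeat=T):
        p = _path_prob(path, delta, params.tmat, B)
        if p > best:  # strict: first (lexicographically lowest) path wins
            best, best_path = p, path
    return np.asarray(best_path) + 1


def enum_posteriors(series, params, delta=None):
    """Smoothed state probabilities by enumeration."""
    delta = params.delta if delta is None else np.asarray(delta, float)
    B = oracle_emissions(series, params)
    T, K = B.shape
    post = np.zeros((T, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = _path_prob(path, delta, params.tmat, B)
        total += p
        for t, s in enumerate(path):
            post[t, s] += p
    return post / total


def random_hmm_case(rng, T, K, with_zeros=True):
    """Random valid parameters plus a random observation series."""
    from movescape import HMMParams, StepSeries

    means = np.sort(rng.uniform(5, 500, K))
    sds = means * rng.uniform(0.5, 1.5, K)
    z = rng.uniform(0.05, 0.3, K) if with_zeros else np.zeros(K)
    m = rng.uniform(-np.pi, np.pi, K)
    kappas = rng.uniform(0.0, 3.0, K)
    tmat = rng.dirichlet(np.ones(K) * 2, size=K)
    params = HMMParams(means, sds, z, m, kappas, tmat)
    lengths = rng.gamma(1.0, means[rng.integers(0, K, T)])
    if with_zeros:
        lengths[rng.random(T) < 0.2] = 0.0
    angles = rng.uniform(-np.pi, np.pi, T)
    angles[0] = np.nan
    angles[rng.random(T) < 0.15] = np.nan
    return StepSeries(lengths, angles, "oracle"), params


def brute_force_max_distance(points):
    points = np.asarray(points, float)
    best = 0.0
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            d = float(np.hypot(*(points[i] - points[j])))
            best = max(best, d)
    return best


def brute_force_mcp_points(points, percent):
    """Indices an MCP should retain: percent% nearest the mean center."""
    points = np.asarray(points, float)
    center = points.mean(axis=0)
    d = np.sqrt(((points - center) ** 2).sum(axis=1))
    k = int(np.floor(len(points) * percent / 100.0 + 1e-9))
    return np.sort(np.argsort(d, kind="stable")[:k])
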