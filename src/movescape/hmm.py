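"""K-state Hidden Markov movement models.

Observations are per-step (step length, turning angle) pairs. Step lengths
follow a zero-inflated gamma distribution per state (point mass ``z_k`` at
zero, otherwise gamma with mean ``mu_k`` and SD ``sigma_k``); turning angles
follow a von Mises distribution with mean direction ``m_k`` and
concentration ``kappa_k``. Missing angles (series start, or next to a
zero-length step) are marginalized out and contribute likelihood factor 1.
The initial state distribution is tied to the stationary distribution of
the transition matrix throughout.

The fitting interface follows the model/results convention: build a
:class:`MovementHMM` from step series, call :meth:`MovementHMM.fit`, and
work with the returned :class:`MovementHMMResults` (parameters,
log-likelihood, AIC, decoding, predictive power, plausibility screening,
``summary()``). Module-level functions expose the individual algorithms.
"""
from __future__ import annotations

import dataclasses
import itertools
import json
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special

from ._recursions import forward_backward, forward_scaled, viterbi_path
from .tracks import StepSeries

STATE_LABELS = {
    1: ("all",),
    2: ("encamped", "moving"),
    3: ("encamped", "foraging", "traveling"),
    4: ("encamped", "foraging", "searching", "traveling"),
}
PREDICTIVE_POWER_THRESHOLD = 0.90


# ---------------------------------------------------------------------------
# parameters

@dataclasses.dataclass
class HMMParams:
    """Parameters of a K-state movement HMM (natural scale).

    ``step_means``/``step_sds`` in meters, ``zero_mass`` in [0, 1),
    ``angle_means`` in (-pi, pi], ``kappas`` >= 0, ``tmat`` row-stochastic.
    The initial distribution is always the stationary distribution of
    ``tmat`` (see :func:`stationary_distribution`).
    """

    step_means: np.ndarray
    step_sds: np.ndarray
    zero_mass: np.ndarray
    angle_means: np.ndarray
    kappas: np.ndarray
    tmat: np.ndarray

    def __post_init__(self) -> None:
        for name in ("step_means", "step_sds", "zero_mass", "angle_means", "kappas"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        K = self.step_means.size
        self.tmat = np.asarray(self.tmat, dtype=float).reshape(K, K)
        if np.any(self.step_means <= 0) or np.any(self.step_sds <= 0):
            raise ValueError("step means and SDs must be positive")
        if np.any(self.zero_mass < 0) or np.any(self.zero_mass >= 1):
            raise ValueError("zero_mass must lie in [0, 1)")
        if np.any(self.kappas < 0):
            raise ValueError("kappas must be non-negative")
        if np.any(self.tmat < 0) or np.any(np.abs(self.tmat.sum(axis=1) - 1) > 1e-9):
            raise ValueError("tmat rows must be non-negative and sum to 1")

    @property
    def n_states(self) -> int:
        return self.step_means.size

    @property
    def delta(self) -> np.ndarray:
        """Stationary initial distribution implied by the transition matrix."""
        return stationary_distribution(self.tmat)

    @property
    def gamma_shapes(self) -> np.ndarray:
        return self.step_means**2 / self.step_sds**2

    @property
    def gamma_scales(self) -> np.ndarray:
        return self.step_sds**2 / self.step_means

    def sort_by_mean(self) -> tuple["HMMParams", np.ndarray]:
        """States permuted to ascending mean step length; returns (params, order)."""
        order = np.argsort(self.step_means, kind="stable")
        return (
            HMMParams(
                self.step_means[order],
                self.step_sds[order],
                self.zero_mass[order],
                self.angle_means[order],
                self.kappas[order],
                self.tmat[np.ix_(order, order)],
            ),
            order,
        )

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "step_means": self.step_means.tolist(),
            "step_sds": self.step_sds.tolist(),
            "zero_mass": self.zero_mass.tolist(),
            "angle_means": self.angle_means.tolist(),
            "kappas": self.kappas.tolist(),
            "tmat": self.tmat.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(
            d["step_means"], d["step_sds"], d["zero_mass"],
            d["angle_means"], d["kappas"], d["tmat"],
        )


def stationary_distribution(tmat: np.ndarray) -> np.ndarray:
    """Solve delta @ tmat = delta with sum(delta) = 1.

    Raises if the chain has no unique stationary distribution (e.g. the
    identity matrix, or any reducible chain with several closed classes).
    """
    tmat = np.asarray(tmat, dtype=float)
    K = tmat.shape[0]
    if tmat.shape != (K, K):
        raise ValueError("tmat must be square")
    if np.any(tmat < 0) or np.any(np.abs(tmat.sum(axis=1) - 1) > 1e-9):
        raise ValueError("tmat must be row-stochastic")
    if K == 1:
        return np.ones(1)
    eigvals, eigvecs = np.linalg.eig(tmat.T)
    close = np.flatnonzero(np.abs(eigvals - 1.0) < 1e-8)
    if close.size != 1:
        raise ValueError("chain has no unique stationary distribution")
    v = np.real(eigvecs[:, close[0]])
    delta = v / v.sum()
    if np.any(delta < -1e-10):
        raise ValueError("invalid stationary distribution")
    return np.clip(delta, 0.0, None) / np.clip(delta, 0.0, None).sum()


# ---------------------------------------------------------------------------
# emission densities

def step_emission(L, mean, sd, z=0.0):
    """Zero-inflated gamma step-length likelihood.

    Returns ``z`` at L = 0, else ``(1 - z)`` times the gamma density with the
    given mean and SD (shape = mean^2/sd^2, scale = sd^2/mean).
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("step lengths must be non-negative")
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    if not 0 <= z < 1:
        raise ValueError("z must lie in [0, 1)")
    shape = mean**2 / sd**2
    scale = sd**2 / mean
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        logpdf = (
            (shape - 1) * np.log(L)
            - L / scale
            - special.gammaln(shape)
            - shape * np.log(scale)
        )
        dens = np.where(L == 0, z, (1 - z) * np.exp(logpdf))
    return dens if dens.ndim else float(dens)

def angle_emission(phi, m, kappa):
    """Von Mises turning-angle likelihood; missing (NaN) angles contribute 1.

    Density exp(kappa * cos(phi - m)) / (2 pi I0(kappa)); kappa = 0 is the
    circular uniform 1/(2 pi). Evaluated via the exponentially scaled Bessel
    function for stability at large kappa.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    phi = np.asarray(phi, dtype=float)
    with np.errstate(invalid="ignore"):
        dens = np.exp(kappa * (np.cos(phi - m) - 1.0)) / (2 * np.pi * special.i0e(kappa))
        dens = np.where(np.isnan(phi), 1.0, dens)
    return dens if dens.ndim else float(dens)


def _emission_matrix(series: StepSeries, params: HMMParams) -> np.ndarray:
    """(T, K) per-step emission probabilities for one series."""
    T, K = len(series), params.n_states
    B = np.empty((T, K))
    for k in range(K):
        B[:, k] = step_emission(
            series.lengths, params.step_means[k], params.step_sds[k],
            params.zero_mass[k],
        ) * angle_emission(series.angles, params.angle_means[k], params.kappas[k])
    return B


# ---------------------------------------------------------------------------
# core algorithms

def _as_series_list(series) -> list[StepSeries]:
    return [series] if isinstance(series, StepSeries) else list(series)


def forward_loglik(series_list, params: HMMParams, delta=None) -> float:
    """Pooled log-likelihood; each burst restarts from the initial law.

    The initial distribution is the stationary distribution of the
    transition matrix unless ``delta`` overrides it (e.g. a fixed start
    state with a chain that has no unique stationary law).
    """
    delta = params.delta if delta is None else np.asarray(delta, dtype=float)
    total = 0.0
    for series in _as_series_list(series_list):
        B = _emission_matrix(series, params)
        ll, fail = forward_scaled(delta, params.tmat, B)
        if fail >= 0:
            raise ValueError(
                f"zero emission likelihood at step {fail} of burst "
                f"{series.burst_id!r}"
            )
        total += ll
    return total


def viterbi(series: StepSeries, params: HMMParams, delta=None) -> np.ndarray:
    """Most likely state path (1-based states); ties go to the lower state."""
    delta = params.delta if delta is None else np.asarray(delta, dtype=float)
    B = _emission_matrix(series, params)
    with np.errstate(divide="ignore"):
        logB = np.log(B)
        log_delta = np.log(delta)
        log_tmat = np.log(params.tmat)
    return viterbi_path(log_delta, log_tmat, logB) + 1


def state_posteriors(series: StepSeries, params: HMMParams, delta=None) -> np.ndarray:
    """Forward-backward smoothed state probabilities, rows summing to 1."""
    delta = params.delta if delta is None else np.asarray(delta, dtype=float)
    B = _emission_matrix(series, params)
    post, fail = forward_backward(delta, params.tmat, B)
    if fail >= 0:
        raise ValueError(
            f"zero emission likelihood at step {fail} of burst {series.burst_id!r}"
        )
    return post


@dataclasses.dataclass
class DecodedBurst:
    """Viterbi path and smoothed probabilities for one burst.

    ``states`` are 1-based; ``max_posterior`` is the probability of the most
    likely state at each step (the ingredient of the predictive-power index).
    """

    burst_id: str
    states: np.ndarray
    posteriors: np.ndarray
    max_posterior: np.ndarray = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        if np.any(np.abs(self.posteriors.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("posterior rows must sum to 1")
        self.max_posterior = self.posteriors.max(axis=1)


def decode(series_list, params: HMMParams) -> list[DecodedBurst]:
    return [
        DecodedBurst(s.burst_id, viterbi(s, params), state_posteriors(s, params))
        for s in _as_series_list(series_list)
    ]


def predictive_power(decoded: Iterable[DecodedBurst]) -> tuple[float, bool]:
    """Mean max-posterior over all pooled steps; strong iff >= 0.90."""
    pooled = np.concatenate([d.max_posterior for d in _as_list(decoded)])
    index = float(pooled.mean())
    # inclusive boundary, robust to accumulation error in the mean
    return index, index >= PREDICTIVE_POWER_THRESHOLD - 1e-12


def _as_list(x):
    return [x] if isinstance(x, DecodedBurst) else list(x)


def count_free_params(n_states: int, zero_inflated: bool) -> int:
    """Free parameters: 4 emission + (1 zero-mass) per state + K(K-1) transitions.

    The initial distribution is tied to the transition matrix and adds none.
    """
    K = n_states
    return K * 4 + K * int(zero_inflated) + K * (K - 1)


def aic(loglik: float, n_params: int) -> float:
    return -2.0 * loglik + 2.0 * n_params


@dataclasses.dataclass
class PlausibilityReport:
    """Biological-realism screen of a fitted model's states."""

    plausible: bool
    labels: tuple[str, ...]           # per fitted state index
    order: np.ndarray                 # state indices sorted by mean step length
    reasons: list[str]

    def __bool__(self) -> bool:
        return self.plausible


def plausibility_check(
    params: HMMParams, separation_threshold: float = 2.0
) -> PlausibilityReport:
    """Label states by mean step length and screen for distinctness.

    States ordered by mean are labeled encamped / (foraging / searching) /
    traveling depending on K. The model fails the screen if any consecutive
    pair of ordered means is within ``separation_threshold`` (ratio), or if
    the traveling state does not have the highest angular concentration
    among the moving states (traveling is the most directed behavior).
    """
    K = params.n_states
    if K not in STATE_LABELS:
        raise ValueError("plausibility labels defined for K in 1..4")
    order = np.argsort(params.step_means, kind="stable")
    means = params.step_means[order]
    reasons: list[str] = []
    for a, b in itertools.pairwise(means):
        if b / a < separation_threshold:
            reasons.append(
                f"indistinct states: mean step lengths {a:.1f} m and {b:.1f} m "
                f"differ by less than x{separation_threshold}"
            )
    if K >= 3:
        moving_kappas = params.kappas[order][1:]
        if np.argmax(moving_kappas) != moving_kappas.size - 1:
            reasons.append(
                "traveling state does not have the highest angular concentration "
                "among moving states"
            )
    labels = [""] * K
    for rank, state in enumerate(order):
        labels[state] = STATE_LABELS[K][rank]
    return PlausibilityReport(not reasons, tuple(labels), order, reasons)


# ---------------------------------------------------------------------------
# working-scale parameterization and multi-start fitting

class _Workscale:
    """Bijection between HMMParams and an unconstrained working vector.

    log means, log SDs, logit zero-mass (only when the data contain zeros),
    raw angle means (wrapped on unpacking), log concentrations, and row-wise
    multinomial logits for the off-diagonal transition probabilities
    (diagonal as reference category).
    """

    def __init__(self, n_states: int, zero_inflated: bool):
        self.K = n_states
        self.zero_inflated = zero_inflated
        self.n = count_free_params(n_states, zero_inflated)

    def pack(self, p: HMMParams) -> np.ndarray:
        K = self.K
        parts = [np.log(p.step_means), np.log(p.step_sds)]
        if self.zero_inflated:
            z = np.clip(p.zero_mass, 1e-10, 1 - 1e-10)
            parts.append(np.log(z / (1 - z)))
        parts.append(p.angle_means.copy())
        parts.append(np.log(np.clip(p.kappas, 1e-8, None)))
        eta = []
        for i in range(K):
            row = np.clip(p.tmat[i], 1e-12, None)
            for j in range(K):
                if j != i:
                    eta.append(np.log(row[j] / row[i]))
        parts.append(np.asarray(eta))
        return np.concatenate(parts)

    def unpack(self, x: np.ndarray) -> HMMParams:
        K = self.K
        pos = 0

        def take(n):
            nonlocal pos
            out = x[pos : pos + n]
            pos += n
            return out

        means = np.exp(take(K))
        sds = np.exp(take(K))
        if self.zero_inflated:
            z = special.expit(take(K))
        else:
            z = np.zeros(K)
        m = take(K)
        m = (m + np.pi) % (2 * np.pi) - np.pi
        m[m == -np.pi] = np.pi
        kappas = np.exp(take(K))
        tmat = np.eye(K)
        if K > 1:
            eta = take(K * (K - 1)).reshape(K, K - 1)
            tmat = np.empty((K, K))
            for i in range(K):
                row = np.ones(K)
                row[np.arange(K) != i] = np.exp(np.clip(eta[i], -500, 500))
                tmat[i] = row / row.sum()
        return HMMParams(means, sds, z, m, kappas, tmat)

    def bounds(self) -> list[tuple[float, float]]:
        K = self.K
        b = [(math.log(1e-4), math.log(1e7))] * (2 * K)
        if self.zero_inflated:
            b += [(-15.0, 15.0)] * K
        b += [(-10.0, 10.0)] * K            # angle means (wrapped anyway)
        b += [(math.log(1e-4), math.log(700.0))] * K
        b += [(-15.0, 15.0)] * (K * (K - 1))
        return b


def build_start_grid(
    series_list,
    n_states: int,
    mean_quantile_sets: Sequence[Sequence[float]] | None = None,
    angle_candidates: Sequence[float] = (0.0, np.pi),
    kappa_candidates: Sequence[float] = (0.5, 2.0),
    diag: float = 0.9,
) -> list[HMMParams]:
    """Cartesian grid of optimizer starting points.

    Candidate per-state step means come from quantiles of the positive step
    lengths (each quantile-level set, ascending, assigns one mean per
    state); SD candidates equal the means; angle-mean and concentration
    candidates apply to all states; the transition matrix starts at
    ``diag`` on the diagonal. The grid has
    ``len(mean_quantile_sets) * len(angle_candidates) * len(kappa_candidates)``
    points.
    """
    K = n_states
    series_list = _as_series_list(series_list)
    L = np.concatenate([s.lengths for s in series_list])
    pos = L[L > 0]
    if pos.size == 0:
        raise ValueError("no positive step lengths in the data")
    zero_frac = float(np.mean(L == 0))
    if mean_quantile_sets is None:
        mean_quantile_sets = [
            np.arange(1, K + 1) / (K + 1),
            np.linspace(0.05, 0.95, K),
        ]
    tmat = np.full((K, K), (1 - diag) / max(K - 1, 1))
    np.fill_diagonal(tmat, diag if K > 1 else 1.0)
    z0 = np.full(K, np.clip(zero_frac, 1e-3, 0.5)) if zero_frac > 0 else np.zeros(K)
    grid = []
    for levels in mean_quantile_sets:
        means = np.sort(np.quantile(pos, np.asarray(levels, float)))
        means = np.maximum(means, 1e-6)
        for m in angle_candidates:
            for kappa in kappa_candidates:
                grid.append(
                    HMMParams(
                        means.copy(), means.copy(), z0.copy(),
                        np.full(K, _wrap(m)), np.full(K, float(kappa)), tmat.copy(),
                    )
                )
    return grid


def _wrap(a: float) -> float:
    w = (a + np.pi) % (2 * np.pi) - np.pi
    return np.pi if w == -np.pi else w


class MovementHMM:
    """K-state movement HMM bound to pooled step series.

    Parameters
    ----------
    series_list : StepSeries or sequence of StepSeries
        Per-burst observations; each burst restarts from the stationary
        distribution in the likelihood.
    n_states : int
        Number of behavioral states (1-4 supported by the labeling scheme).
    zero_inflated : bool, optional
        Include per-state zero-mass parameters. Defaults to True exactly
        when the data contain zero-length steps.
    """

    def __init__(self, series_list, n_states: int, zero_inflated: bool | None = None):
        self.series = _as_series_list(series_list)
        if not self.series:
            raise ValueError("need at least one step series")
        self.n_states = int(n_states)
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        L = np.concatenate([s.lengths for s in self.series])
        self.n_obs = int(L.size)
        has_zeros = bool(np.any(L == 0))
        self.zero_inflated = has_zeros if zero_inflated is None else bool(zero_inflated)
        if has_zeros and not self.zero_inflated:
            raise ValueError("data contain zero-length steps; zero inflation required")
        self.df_model = count_free_params(self.n_states, self.zero_inflated)

    @classmethod
    def from_bursts(cls, bursts, n_states: int, **kw) -> "MovementHMM":
        from .preprocess import steps_and_angles

        return cls([steps_and_angles(b) for b in bursts], n_states, **kw)

    def loglike(self, params: HMMParams) -> float:
        return forward_loglik(self.series, params)

    def _loglike_safe(self, params: HMMParams) -> float:
        try:
            return self.loglike(params)
        except (ValueError, np.linalg.LinAlgError):
            return -np.inf

    def fit(
        self,
        start_grid: Sequence[HMMParams] | None = None,
        maxiter: int = 500,
        ftol: float = 1e-10,
        warn_small: bool = True,
    ) -> "MovementHMMResults":
        """Maximize the pooled likelihood from every start-grid point.

        Each start is optimized by L-BFGS-B on the working scale; the best
        converged start wins. Failed starts are recorded and skipped.
        """
        if warn_small and self.n_obs < 50 * self.df_model:
            import warnings

            warnings.warn(
                f"only {self.n_obs} steps for {self.df_model} free parameters; "
                "estimates may be unstable",
                stacklevel=2,
            )
        if start_grid is None:
            start_grid = build_start_grid(self.series, self.n_states)
        ws = _Workscale(self.n_states, self.zero_inflated)

        def nll(x: np.ndarray) -> float:
            try:
                params = ws.unpack(x)
                ll = self._loglike_safe(params)
            except (ValueError, FloatingPointError):
                return 1e12
            return 1e12 if not np.isfinite(ll) else -ll

        records = []
        best = None
        for i, start in enumerate(start_grid):
            x0 = ws.pack(start)
            try:
                res = optimize.minimize(
                    nll, x0, method="L-BFGS-B", bounds=ws.bounds(),
                    options={"maxiter": maxiter, "ftol": ftol},
                )
                ok = bool(res.success) and res.fun < 1e11
                rec = {
                    "start": i, "loglik": -float(res.fun) if res.fun < 1e11 else None,
                    "converged": ok, "message": str(res.message),
                }
                if res.fun < 1e11 and (best is None or res.fun < best[0]):
                    best = (res.fun, res.x, ok)
            except (ValueError, FloatingPointError) as exc:  # pragma: no cover
                rec = {"start": i, "loglik": None, "converged": False,
                       "message": str(exc)}
            records.append(rec)
        if best is None:
            raise RuntimeError(
                "all optimizer starts failed: "
                + "; ".join(r["message"] for r in records)
            )
        params = ws.unpack(best[1])
        llf = -best[0]
        return MovementHMMResults(self, params, llf, records, best[2])

    def fit_from_params(self, params: HMMParams, **kw) -> "MovementHMMResults":
        """Fit with a single user-supplied starting point."""
        return self.fit(start_grid=[params], **kw)


class MovementHMMResults:
    """Fitted movement HMM: parameters, fit statistics and decoding."""

    def __init__(self, model, params, llf, start_records, converged):
        self.model = model
        self.params = params
        self.llf = float(llf)
        self.start_records = start_records
        self.converged = bool(converged)
        self.df_model = model.df_model
        self.nobs = model.n_obs
        self.aic = aic(self.llf, self.df_model)

    @property
    def n_states(self) -> int:
        return self.params.n_states

    @property
    def start_logliks(self) -> list[float | None]:
        return [r["loglik"] for r in self.start_records]

    def decode(self, series_list=None) -> list[DecodedBurst]:
        series_list = self.model.series if series_list is None else series_list
        return decode(series_list, self.params)

    def predictive_power(self, decoded=None) -> tuple[float, bool]:
        return predictive_power(decoded if decoded is not None else self.decode())

    def plausibility(self, separation_threshold: float = 2.0) -> PlausibilityReport:
        return plausibility_check(self.params, separation_threshold)

    def sorted_params(self) -> tuple[HMMParams, np.ndarray]:
        return self.params.sort_by_mean()

    def to_dict(self) -> dict:
        index, strong = self.predictive_power()
        report = self.plausibility()
        return {
            "params": self.params.to_dict(),
            "delta": self.params.delta.tolist(),
            "loglik": self.llf,
            "aic": self.aic,
            "n_params": self.df_model,
            "n_obs": self.nobs,
            "converged": self.converged,
            "predictive_power": index,
            "strongly_predictive": strong,
            "plausible": report.plausible,
            "state_labels": list(report.labels),
            "plausibility_reasons": report.reasons,
            "starts": self.start_records,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        p, order = self.sorted_params()
        report = self.plausibility()
        index, strong = self.predictive_power()
        lines = [
            f"Movement HMM, K={self.n_states} states, {self.nobs} steps "
            f"in {len(self.model.series)} burst(s)",
            f"log-likelihood {self.llf:.3f}   AIC {self.aic:.1f}   "
            f"free params {self.df_model}",
            f"predictive power {index:.3f} "
            f"({'strong' if strong else 'not strong'})   "
            f"plausible: {report.plausible}",
            "",
            f"{'state':<12}{'mean (m)':>10}{'SD (m)':>10}{'zero':>8}"
            f"{'angle mean':>12}{'kappa':>8}{'stationary':>12}",
        ]
        delta = p.delta
        labels = STATE_LABELS.get(self.n_states, tuple(f"s{i}" for i in range(self.n_states)))
        for k in range(self.n_states):
            lines.append(
                f"{labels[k]:<12}{p.step_means[k]:>10.1f}{p.step_sds[k]:>10.1f}"
                f"{p.zero_mass[k]:>8.3f}{p.angle_means[k]:>12.2f}"
                f"{p.kappas[k]:>8.2f}{delta[k]:>12.3f}"
            )
        lines.append("")
        lines.append("transition matrix (states ordered by mean step length):")
        for row in p.tmat:
            lines.append("  " + "  ".join(f"{v:.3f}" for v in row))
        if report.reasons:
            lines.append("plausibility issues: " + "; ".join(report.reasons))
        return "\n".join(lines)

    def plot_state_densities(self, ax=None, bins=60):
        """Diagnostic plot: pooled step-length histogram with the fitted
        per-state gamma densities weighted by the stationary law.

        Requires matplotlib (optional dependency); returns the axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        L = np.concatenate([s.lengths for s in self.model.series])
        pos = L[L > 0]
        ax.hist(pos, bins=bins, density=True, alpha=0.4, color="grey",
                label="observed steps")
        grid = np.linspace(pos.min(), pos.max(), 500)
        p, _ = self.sorted_params()
        delta = p.delta
        labels = STATE_LABELS.get(self.n_states,
                                  tuple(f"s{i}" for i in range(self.n_states)))
        for k in range(self.n_states):
            dens = delta[k] * step_emission(
                grid, p.step_means[k], p.step_sds[k], 0.0
            )
            ax.plot(grid, dens, label=f"{labels[k]} (mean {p.step_means[k]:.0f} m)")
        ax.set_xlabel("step length (m)")
        ax.set_ylabel("density")
        ax.legend()
        return ax

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MovementHMMResults K={self.n_states} llf={self.llf:.2f} "
            f"aic={self.aic:.1f}>"
        )


def fit_hmm(
    series_list, n_states: int, start_grid=None, **fit_options
) -> MovementHMMResults:
    """Convenience wrapper: build a :class:`MovementHMM` and fit it."""
    return MovementHMM(series_list, n_states).fit(start_grid=start_grid, **fit_options)
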