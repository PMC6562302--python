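"""Synthetic GPS-track and imperviousness-raster generation.

The generator is the inverse of the movement model fitted elsewhere in the
package: a K-state Markov chain emits step lengths from zero-inflated gamma
distributions and turning angles from von Mises distributions; angles are
integrated into headings (uniform initial heading) and headings into planar
positions. Territorial ("anchored") space use is produced by a heading
mixture that points a fraction of steps straight at an anchor, which bounds
displacement without modeling streets, barriers or resource selection.

Every simulated quantity with a downstream estimator keeps its ground truth
on the returned :class:`~movescape.tracks.SimulatedTrack`.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .tracks import SimulatedTrack, Track


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the generative movement model.

    Step lengths for state k are 0 with probability ``zero_mass[k]`` and
    otherwise gamma with mean ``step_means[k]`` (m) and SD ``step_sds[k]``
    (m). Turning angles are von Mises with mean direction ``angle_means[k]``
    (rad) and concentration ``kappas[k]``. ``tmat`` is the row-stochastic
    K x K transition matrix; the chain starts from its stationary
    distribution unless a start state is forced.
    """

    n_states: int
    step_means: np.ndarray
    step_sds: np.ndarray
    zero_mass: np.ndarray
    angle_means: np.ndarray
    kappas: np.ndarray
    tmat: np.ndarray
    fix_interval_s: float = 900.0
    n_steps: int = 1000
    start: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    anchor: tuple[float, float] | Sequence[tuple[float, float]] | None = None
    attraction: float = 0.0
    anchor_switch_steps: int = 0
    anchor_kappa: float = 2.0

    def __post_init__(self) -> None:
        K = self.n_states
        if K < 1:
            raise ValueError("n_states must be >= 1")
        for name in ("step_means", "step_sds", "zero_mass", "angle_means", "kappas"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if arr.size != K:
                raise ValueError(f"{name} must have length n_states={K}")
            setattr(self, name, arr)
        self.tmat = np.asarray(self.tmat, dtype=float).reshape(K, K)
        if np.any(self.tmat < 0) or np.any(
            np.abs(self.tmat.sum(axis=1) - 1.0) > 1e-12
        ):
            raise ValueError("tmat rows must be non-negative and sum to 1")
        if np.any(self.step_means <= 0) or np.any(self.step_sds <= 0):
            raise ValueError("step means and SDs must be positive")
        if np.any(self.zero_mass < 0) or np.any(self.zero_mass >= 1):
            raise ValueError("zero_mass must lie in [0, 1)")
        if np.any(self.kappas < 0):
            raise ValueError("kappas must be non-negative")
        if not 0 <= self.attraction < 1:
            raise ValueError("attraction weight must lie in [0, 1)")
        if self.fix_interval_s <= 0:
            raise ValueError("fix_interval_s must be positive")
        if self.anchor is not None:
            self.anchor = np.atleast_2d(np.asarray(self.anchor, dtype=float))
            if self.anchor.shape[1] != 2:
                raise ValueError("anchor must be an (x, y) point or a list of them")
        if self.anchor_switch_steps < 0:
            raise ValueError("anchor_switch_steps must be non-negative")
        if self.anchor_kappa <= 0:
            raise ValueError("anchor_kappa must be positive")

    @property
    def gamma_shapes(self) -> np.ndarray:
        return self.step_means**2 / self.step_sds**2

    @property
    def gamma_scales(self) -> np.ndarray:
        return self.step_sds**2 / self.step_means


def transition_matrix_for_stationary(
    delta, switching_rate: float = 0.3
) -> np.ndarray:
    """Reversible transition matrix whose stationary distribution is ``delta``.

    Off-diagonals are ``switching_rate * delta_j``, so detailed balance
    ``delta_i * g_ij = delta_j * g_ji`` holds and the rows stay stochastic for
    ``switching_rate`` in (0, 1]. Larger rates switch states more often.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0) or abs(delta.sum() - 1.0) > 1e-9:
        raise ValueError("delta must be a positive probability vector")
    delta = delta / delta.sum()
    if not 0 < switching_rate <= 1:
        raise ValueError("switching_rate must lie in (0, 1]")
    K = delta.size
    tmat = switching_rate * np.tile(delta, (K, 1))
    np.fill_diagonal(tmat, 0.0)
    np.fill_diagonal(tmat, 1.0 - tmat.sum(axis=1))
    return tmat


def _simulate_states(config: SimulationConfig, rng, start_state):
    from .hmm import stationary_distribution

    K, n = config.n_states, config.n_steps
    states = np.empty(n, dtype=np.int64)
    if start_state is None:
        delta = stationary_distribution(config.tmat) if K > 1 else np.ones(1)
        states[0] = rng.choice(K, p=delta)
    else:
        if not 0 <= start_state < K:
            raise ValueError("start_state out of range")
        states[0] = start_state
    cum = np.cumsum(config.tmat, axis=1)
    u = rng.random(n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")
    np.clip(states, 0, K - 1, out=states)
    return states


def _simulate_track(
    config: SimulationConfig, start_state=None, animal_id: str = "sim"
) -> SimulatedTrack:
    """Shared generative core; attraction weight 0 reduces to the plain HMM."""
    rng = np.random.default_rng(config.seed)
    n = config.n_steps
    states = _simulate_states(config, rng, start_state)

    # draw everything up front in a fixed order so that the random stream is
    # identical whether or not territorial attraction is switched on
    zero_u = rng.random(n)
    gamma_draws = rng.gamma(
        config.gamma_shapes[states], config.gamma_scales[states]
    )
    angles = rng.vonmises(config.angle_means[states], config.kappas[states])
    heading0 = rng.uniform(-np.pi, np.pi)
    mix_u = rng.random(n)
    anchor_noise = rng.vonmises(0.0, config.anchor_kappa, n)

    lengths = np.where(zero_u < config.zero_mass[states], 0.0, gamma_draws)

    w = config.attraction
    anchors = config.anchor
    if w > 0 and anchors is None:
        raise ValueError("territorial simulation requires an anchor point")
    switch = config.anchor_switch_steps

    x = np.empty(n + 1)
    y = np.empty(n + 1)
    x[0], y[0] = config.start
    heading = heading0
    true_angles = np.full(n, np.nan)
    for t in range(n):
        if t > 0:
            heading = _wrap_angle(heading + angles[t])
            true_angles[t] = angles[t]
        if w > 0 and mix_u[t] < w:
            a_idx = (t // switch) % len(anchors) if switch > 0 else 0
            ax, ay = anchors[a_idx]
            # homing is directed but not a beeline: von Mises scatter around
            # the bearing to the anchor keeps observed angles non-degenerate
            heading = _wrap_angle(np.arctan2(ay - y[t], ax - x[t]) + anchor_noise[t])
            true_angles[t] = np.nan  # observed turn no longer the HMM draw
        x[t + 1] = x[t] + lengths[t] * np.cos(heading)
        y[t + 1] = y[t] + lengths[t] * np.sin(heading)

    # the angle observation is undefined next to zero-length steps
    true_angles[0] = np.nan
    zero = lengths == 0
    true_angles[zero] = np.nan
    true_angles[1:][zero[:-1]] = np.nan

    times = np.arange(n + 1) * config.fix_interval_s
    return SimulatedTrack(
        animal_id=animal_id,
        times=times,
        x=x,
        y=y,
        true_states=states,
        true_steps=lengths,
        true_angles=true_angles,
    )


def _wrap_angle(a):
    """Wrap to (-pi, pi]."""
    w = (a + np.pi) % (2 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w) if np.ndim(w) else (np.pi if w == -np.pi else w)


def simulate_hmm_track(
    config: SimulationConfig, start_state: int | None = None, animal_id: str = "sim"
) -> SimulatedTrack:
    """Simulate a movement track from the K-state switching model.

    The state chain starts from the stationary distribution of ``tmat``
    (or from ``start_state`` if given); positions accumulate headings that
    integrate the von Mises turning angles from a uniform initial heading.
    """
    cfg = dataclasses.replace(config, attraction=0.0)
    return _simulate_track(cfg, start_state=start_state, animal_id=animal_id)


def simulate_territorial_track(
    config: SimulationConfig, start_state: int | None = None, animal_id: str = "sim"
) -> SimulatedTrack:
    """Simulate an anchored (territory-holding) track.

    Each step's heading is, with probability ``config.attraction``, pointed
    straight at ``config.anchor``; otherwise it follows the plain switching
    model. With weight 0 the output is bit-identical to
    :func:`simulate_hmm_track` under the same seed.
    """
    if config.attraction > 0 and config.anchor is None:
        raise ValueError("anchor must be set for territorial simulation")
    return _simulate_track(config, start_state=start_state, animal_id=animal_id)


def make_fix_schedule(
    duration_s: float, interval_s: float, dropout_prob: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Regular fix-time grid over ``[0, duration_s]`` with Bernoulli dropout.

    A 24-h schedule at 15-min intervals has 97 grid points (both endpoints
    included); each fix is independently dropped with ``dropout_prob``.
    """
    if interval_s <= 0:
        raise ValueError("interval must be positive")
    if not 0 <= dropout_prob < 1:
        raise ValueError("dropout_prob must lie in [0, 1)")
    grid = np.arange(0.0, duration_s + interval_s * 1e-9, interval_s)
    if dropout_prob > 0:
        rng = np.random.default_rng(seed)
        grid = grid[rng.random(grid.size) >= dropout_prob]
    return grid


def apply_fix_schedule(track: Track, schedule_times: np.ndarray, t0: float | None = None) -> Track:
    """Keep only the fixes whose (offset) timestamps appear in the schedule."""
    t0 = track.times[0] if t0 is None else t0
    mask = np.isin(track.times - t0, np.asarray(schedule_times))
    return track.subset(np.flatnonzero(mask))


def inject_position_errors(
    track: Track, n_spikes: int, spike_distance: float, seed: int = 0,
    candidate_indices: np.ndarray | None = None,
) -> tuple[Track, np.ndarray]:
    """Displace ``n_spikes`` interior fixes by ``spike_distance`` m.

    Emulates teleportation-style GPS errors; directions are uniform and the
    first and last fixes are never touched. ``candidate_indices`` restricts
    where spikes may land (e.g. to fixes on a fast schedule). Returns the
    corrupted track and the sorted displaced fix indices.
    """
    if spike_distance <= 0:
        raise ValueError("spike_distance must be positive")
    if candidate_indices is None:
        candidates = np.arange(1, max(len(track) - 1, 1))
    else:
        candidates = np.asarray(candidate_indices, dtype=int)
        if np.any(candidates < 1) or np.any(candidates >= len(track) - 1):
            raise ValueError("candidate indices must be interior fixes")
    if n_spikes > candidates.size:
        raise ValueError("n_spikes must be smaller than the number of interior fixes")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(candidates, size=n_spikes, replace=False))
    x, y = track.x.copy(), track.y.copy()
    theta = rng.uniform(-np.pi, np.pi, size=n_spikes)
    x[idx] += spike_distance * np.cos(theta)
    y[idx] += spike_distance * np.sin(theta)
    return Track(track.animal_id, track.times.copy(), x, y), idx


@dataclasses.dataclass
class ImperviousnessRaster:
    """Gridded percent surface imperviousness (0-100) on a planar extent.

    ``values[i, j]`` covers the cell whose center is
    ``(x0 + (j + 0.5) * cell_size, y0 + (i + 0.5) * cell_size)``; ``(x0, y0)``
    is the lower-left corner of the extent.
    """

    values: np.ndarray
    x0: float
    y0: float
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ValueError("imperviousness must lie in [0, 100]")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        ny, nx = self.values.shape
        return (self.x0, self.y0, self.x0 + nx * self.cell_size, self.y0 + ny * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat arrays of all cell-center x and y coordinates."""
        ny, nx = self.values.shape
        cx = self.x0 + (np.arange(nx) + 0.5) * self.cell_size
        cy = self.y0 + (np.arange(ny) + 0.5) * self.cell_size
        gx, gy = np.meshgrid(cx, cy)
        return gx.ravel(), gy.ravel()

    def save(self, path) -> None:
        """Plain-text grid plus a JSON sidecar with the georeference."""
        path = Path(path)
        np.savetxt(path, self.values, fmt="%.4f")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"x0": self.x0, "y0": self.y0, "cell_size": self.cell_size})
        )

    @classmethod
    def load(cls, path) -> "ImperviousnessRaster":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(np.atleast_2d(np.loadtxt(path)), meta["x0"], meta["y0"], meta["cell_size"])


def make_imperviousness_raster(
    extent: tuple[float, float, float, float],
    cell_size: float = 30.0,
    pattern: str = "uniform",
    level: float = 35.0,
    seed: int = 0,
    n_patches: int = 8,
    background: float = 5.0,
) -> ImperviousnessRaster:
    """Synthetic stand-in for a developed-imperviousness raster.

    ``uniform`` fills every cell with ``level``; ``gradient`` ramps linearly
    from 0 at the west edge to ``level`` at the east edge; ``patches`` places
    seeded Gaussian blobs of intensity ``level`` on a low background. The
    default 30-m cell echoes standard land-cover products.
    """
    xmin, ymin, xmax, ymax = extent
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("extent must have positive width and height")
    if not 0 <= level <= 100:
        raise ValueError("level must lie in [0, 100]")
    nx = max(int(np.ceil((xmax - xmin) / cell_size)), 1)
    ny = max(int(np.ceil((ymax - ymin) / cell_size)), 1)
    if pattern == "uniform":
        values = np.full((ny, nx), float(level))
    elif pattern == "gradient":
        ramp = np.linspace(0.0, level, nx)
        values = np.tile(ramp, (ny, 1))
    elif pattern == "patches":
        rng = np.random.default_rng(seed)
        cx = rng.uniform(0, nx, n_patches)
        cy = rng.uniform(0, ny, n_patches)
        radius = rng.uniform(0.05, 0.2, n_patches) * max(nx, ny)
        jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
        values = np.full((ny, nx), float(background))
        for k in range(n_patches):
            d2 = (jj - cx[k]) ** 2 + (ii - cy[k]) ** 2
            values += level * np.exp(-d2 / (2 * radius[k] ** 2))
        values = np.clip(values, 0.0, 100.0)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return ImperviousnessRaster(values, float(xmin), float(ymin), float(cell_size))
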