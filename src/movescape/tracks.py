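"""Telemetry containers and delimited-text I/O.

All coordinates are planar meters; timestamps are seconds since the Unix
epoch internally and ISO-8601 strings on disk. No geographic CRS handling
is done anywhere in the package.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TRACK_COLUMNS = ("animal_id", "timestamp", "x_m", "y_m")


@dataclasses.dataclass
class Track:
    """Ordered GPS fixes for one animal.

    Parameters
    ----------
    animal_id : str
        Identifier of the collared animal.
    times : ndarray of float
        Fix timestamps in seconds since the epoch, strictly increasing.
    x, y : ndarray of float
        Projected planar coordinates in meters.
    """

    animal_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.times.shape == self.x.shape == self.y.shape):
            raise ValueError("times, x and y must have equal length")
        if self.times.ndim != 1:
            raise ValueError("fix arrays must be one-dimensional")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_fixes(self) -> int:
        return self.times.size

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0

    @property
    def duration_days(self) -> float:
        return self.duration_s / 86400.0

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of x/y coordinates."""
        return np.column_stack([self.x, self.y])

    def subset(self, index: np.ndarray) -> "Track":
        """New Track restricted to the given fix indices (order preserved)."""
        index = np.asarray(index)
        return Track(self.animal_id, self.times[index], self.x[index], self.y[index])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "timestamp": pd.to_datetime(self.times, unit="s").strftime(
                    "%Y-%m-%dT%H:%M:%S"
                ),
                "x_m": self.x,
                "y_m": self.y,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, animal_id: str | None = None) -> "Track":
        if animal_id is None:
            ids = df["animal_id"].unique()
            if len(ids) != 1:
                raise ValueError("dataframe holds multiple animals; pass animal_id")
            animal_id = str(ids[0])
        else:
            df = df[df["animal_id"].astype(str) == str(animal_id)]
        times = pd.to_datetime(df["timestamp"]).astype("int64").to_numpy() / 1e9
        return cls(str(animal_id), times, df["x_m"].to_numpy(), df["y_m"].to_numpy())


@dataclasses.dataclass
class SimulatedTrack(Track):
    """Track with generative ground truth attached.

    ``true_states`` / ``true_steps`` / ``true_angles`` have one entry per
    movement step (``n_fixes - 1``); the first turning angle and any angle
    adjacent to a zero-length step are NaN (undefined heading).
    """

    true_states: np.ndarray = dataclasses.field(default_factory=lambda: np.empty(0, int))
    true_steps: np.ndarray = dataclasses.field(default_factory=lambda: np.empty(0))
    true_angles: np.ndarray = dataclasses.field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        super().__post_init__()
        n_steps = len(self) - 1
        for name in ("true_states", "true_steps", "true_angles"):
            arr = np.asarray(getattr(self, name))
            if arr.size != n_steps:
                raise ValueError(f"{name} must have one entry per step ({n_steps})")
            setattr(self, name, arr)

    def to_dataframe(self) -> pd.DataFrame:
        df = super().to_dataframe()
        # state of the step leaving each fix; last fix has no outgoing step
        states = np.append(self.true_states + 1, -1)
        df["true_state"] = states
        return df


@dataclasses.dataclass
class Burst(Track):
    """Unbroken run of nominally 15-min fixes at least 24 h long."""

    burst_id: str = ""

    @property
    def duration_h(self) -> float:
        return self.duration_s / 3600.0


@dataclasses.dataclass
class StepSeries:
    """Per-step observations derived from a burst.

    ``lengths`` are Euclidean step lengths in meters (>= 0). ``angles`` are
    signed turning angles in (-pi, pi], NaN where undefined: at the series
    start and wherever either adjacent step has zero length.
    """

    lengths: np.ndarray
    angles: np.ndarray
    burst_id: str = ""

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.lengths.shape != self.angles.shape:
            raise ValueError("lengths and angles must have equal length")
        if np.any(self.lengths < 0):
            raise ValueError("step lengths must be non-negative")

    def __len__(self) -> int:
        return self.lengths.size


def write_tracks(tracks: Iterable[Track], path) -> None:
    """Write tracks as delimited text (``animal_id,timestamp,x_m,y_m[,true_state]``)."""
    frames = [t.to_dataframe() for t in tracks]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks(path) -> list[Track]:
    """Read a delimited track file; one Track per distinct animal id."""
    df = pd.read_csv(path)
    return [
        Track.from_dataframe(group, animal_id=str(aid))
        for aid, group in df.groupby("animal_id", sort=True)
    ]
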