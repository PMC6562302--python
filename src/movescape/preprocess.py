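"""Telemetry cleaning, subsampling, burst extraction and step geometry.

The cleaning rules mirror common GPS-collar practice: segments faster than a
review threshold (default 10 km/h) are flagged for inspection, and fixes
producing impossible speeds (default > 50 km/h) are removed automatically by
an out-and-back spike test. Home-range analyses run on fixes subsampled to
roughly one per 7.25 h; behavioral analyses run on bursts of consecutive
15-min fixes at least 24 h long.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .tracks import Burst, StepSeries, Track

REVIEW_SPEED_KMH = 10.0
HARD_SPEED_KMH = 50.0
SUBSAMPLE_INTERVAL_S = 7.25 * 3600.0
BURST_INTERVAL_S = 15 * 60.0
BURST_MIN_DURATION_S = 24 * 3600.0
# GPS collars jitter around their schedule; tolerances are ours to declare
BURST_TOLERANCE_S = 120.0
SUBSAMPLE_TOLERANCE_S = 1800.0


@dataclasses.dataclass
class RemovalRecord:
    """One fix removed by the spike filter, with the triggering evidence."""

    index: int
    time: float
    x: float
    y: float
    speed_in_kmh: float
    speed_out_kmh: float
    reason: str


def compute_speeds(track: Track) -> np.ndarray:
    """Per-segment straight-line speeds in km/h (length ``n_fixes - 1``)."""
    if len(track) < 2:
        raise ValueError("need at least 2 fixes to compute speeds")
    dt = np.diff(track.times)
    if np.any(dt <= 0):
        raise ValueError("non-increasing timestamps")
    dist_km = np.hypot(np.diff(track.x), np.diff(track.y)) / 1000.0
    return dist_km / (dt / 3600.0)


def flag_speed_outliers(
    track: Track, review_threshold_kmh: float = REVIEW_SPEED_KMH
) -> np.ndarray:
    """Indices of fixes adjacent to any segment faster than the threshold.

    Flags are advisory — nothing is removed. Every fix the hard spike filter
    would delete is necessarily flagged here as long as the review threshold
    does not exceed the hard threshold.
    """
    speeds = compute_speeds(track)
    fast = np.flatnonzero(speeds > review_threshold_kmh)
    return np.unique(np.concatenate([fast, fast + 1]))


def remove_spikes(
    track: Track, hard_threshold_kmh: float = HARD_SPEED_KMH
) -> tuple[Track, list[RemovalRecord]]:
    """Iteratively delete interior fixes causing impossible speeds.

    An interior fix is removed when it sits at the tip of an out-and-back
    spike — both adjacent segments exceed ``hard_threshold_kmh`` — or when
    one adjacent segment exceeds the threshold and bridging over the fix
    brings the speed back under it. Removal repeats until no segment
    exceeds the threshold or no single fix explains one.
    """
    if len(track) < 3:
        raise ValueError("need at least 3 fixes to screen for spikes")
    times, x, y = track.times.copy(), track.x.copy(), track.y.copy()
    orig_index = np.arange(len(track))
    log: list[RemovalRecord] = []

    def seg_speed(i, j):
        return (
            np.hypot(x[j] - x[i], y[j] - y[i]) / 1000.0 / ((times[j] - times[i]) / 3600.0)
        )

    while len(times) >= 3:
        speeds = (
            np.hypot(np.diff(x), np.diff(y)) / 1000.0 / (np.diff(times) / 3600.0)
        )
        offending = np.flatnonzero(speeds > hard_threshold_kmh)
        if offending.size == 0:
            break
        removed = None
        candidates = [
            int(i)
            for i in np.unique(np.concatenate([offending, offending + 1]))
            if 0 < i < len(times) - 1
        ]
        # prefer unambiguous out-and-back tips (fast in AND out) over fixes
        # that merely bridge plausibly when skipped — the latter test would
        # otherwise also fire on the innocent neighbor of a spike
        pick = None
        for i in candidates:
            if speeds[i - 1] > hard_threshold_kmh and speeds[i] > hard_threshold_kmh:
                pick = (i, "out-and-back spike")
                break
        if pick is None:
            for i in candidates:
                if (
                    max(speeds[i - 1], speeds[i]) > hard_threshold_kmh
                    and seg_speed(i - 1, i + 1) <= hard_threshold_kmh
                ):
                    pick = (i, "bridging speed plausible")
                    break
        if pick is not None:
            i, reason = pick
            log.append(
                RemovalRecord(
                    int(orig_index[i]), times[i], x[i], y[i],
                    float(speeds[i - 1]), float(speeds[i]), reason,
                )
            )
            removed = i
        if removed is None:
            break  # no single interior fix explains the remaining segment(s)
        keep = np.ones(len(times), bool)
        keep[removed] = False
        times, x, y, orig_index = times[keep], x[keep], y[keep], orig_index[keep]

    if len(times) < 2:
        raise ValueError("spike removal left fewer than 2 fixes")
    return Track(track.animal_id, times, x, y), log


def removal_log_frame(log: list[RemovalRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in log])


def subsample(
    track: Track,
    target_interval_s: float = SUBSAMPLE_INTERVAL_S,
    tolerance_s: float = SUBSAMPLE_TOLERANCE_S,
) -> Track:
    """Thin a track to roughly one fix per ``target_interval_s``.

    A time grid anchored at the first fix advances in steps of the target
    interval; the nearest fix within tolerance of each grid slot is kept
    (one per slot). Output gaps are never shorter than
    ``target_interval_s - tolerance_s``.
    """
    if track.duration_s < target_interval_s:
        raise ValueError("track is shorter than the target interval")
    kept = [0]
    last_time = track.times[0]
    n_slots = int(np.floor((track.times[-1] - track.times[0]) / target_interval_s + 0.5))
    for k in range(1, n_slots + 1):
        target = track.times[0] + k * target_interval_s
        diffs = np.abs(track.times - target)
        i = int(np.argmin(diffs))
        if (
            diffs[i] <= tolerance_s
            and i != kept[-1]
            and track.times[i] - last_time >= target_interval_s - tolerance_s
        ):
            kept.append(i)
            last_time = track.times[i]
    if len(kept) < 2:
        raise ValueError("subsampling produced fewer than 2 fixes")
    return track.subset(np.asarray(kept))


def extract_bursts(
    track: Track,
    nominal_interval_s: float = BURST_INTERVAL_S,
    tolerance_s: float = BURST_TOLERANCE_S,
    min_duration_s: float = BURST_MIN_DURATION_S,
) -> list[Burst]:
    """Maximal runs of consecutive fixes at the nominal interval.

    Runs break wherever the inter-fix gap leaves
    ``nominal_interval_s +/- tolerance_s``; runs spanning less than
    ``min_duration_s`` are dropped. The empty list is a valid result.
    """
    if len(track) < 2:
        return []
    gaps = np.diff(track.times)
    ok = np.abs(gaps - nominal_interval_s) <= tolerance_s
    bursts: list[Burst] = []
    start = 0
    n_runs = 0
    for i in range(len(gaps) + 1):
        boundary = i == len(gaps) or not ok[i]
        if boundary:
            if track.times[i] - track.times[start] >= min_duration_s:
                n_runs += 1
                idx = np.arange(start, i + 1)
                bursts.append(
                    Burst(
                        animal_id=track.animal_id,
                        times=track.times[idx],
                        x=track.x[idx],
                        y=track.y[idx],
                        burst_id=f"{track.animal_id}-b{n_runs}",
                    )
                )
            start = i + 1
    return bursts


def steps_and_angles(burst: Track) -> StepSeries:
    """Step lengths and signed turning angles from a burst of fixes.

    With T+1 fixes there are T steps. ``angles[t]`` is the change of heading
    between step t-1 and step t wrapped to (-pi, pi] (left turns positive);
    it is NaN at t=0 and wherever either adjacent step has zero length.
    """
    if len(burst) < 3:
        raise ValueError("need at least 3 fixes for turning angles")
    dx, dy = np.diff(burst.x), np.diff(burst.y)
    lengths = np.hypot(dx, dy)
    headings = np.arctan2(dy, dx)
    angles = np.full(lengths.size, np.nan)
    raw = headings[1:] - headings[:-1]
    wrapped = (raw + np.pi) % (2 * np.pi) - np.pi
    wrapped[wrapped == -np.pi] = np.pi
    angles[1:] = wrapped
    zero = lengths == 0
    angles[zero] = np.nan
    angles[1:][zero[:-1]] = np.nan
    burst_id = getattr(burst, "burst_id", "") or burst.animal_id
    return StepSeries(lengths=lengths, angles=angles, burst_id=burst_id)
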