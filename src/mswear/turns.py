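"""Turning-episode detection from chest or ankle yaw rate.

A turn is a sustained yaw-rate excursion: the low-passed (1.5 Hz, zero-phase)
signal exceeds an entry threshold, the episode is expanded outward to a lower
exit threshold, nearby episodes are merged, and episodes whose integrated
angle is below a minimum are discarded. The turn angle is the trapezoid
quadrature of the *raw* yaw rate over the detected span, so filtering cannot
bias it; the sign of the angle is preserved internally while summaries use
magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import TurnConfig
from scipy import signal as sp_signal


@dataclass(frozen=True)
class TurnEvent:
    start_s: float
    end_s: float
    duration_s: float
    angle_deg: float               # signed integral of yaw rate
    peak_velocity_deg_s: float     # max |yaw| within the event
    mean_velocity_deg_s: float
    source_location: str = "chest"


@dataclass(frozen=True)
class TurnSummary:
    """Across-turn aggregates: a single turn has no velocity spread, so the
    max/mean/std velocity features aggregate per-turn values across the
    session's turns (mean of maxima, mean of means, population std of means).
    """

    n_turns: int
    mean_angle_deg: float
    mean_duration_s: float
    velocity_max_deg_s: float
    velocity_mean_deg_s: float
    velocity_std_deg_s: float


def detect_turns(yaw_rate: np.ndarray, fs: float,
                 config: TurnConfig | None = None,
                 t: np.ndarray | None = None,
                 source_location: str = "chest") -> list[TurnEvent]:
    """Detect turning episodes in a yaw-rate series (deg/s)."""
    config = config or TurnConfig()
    if fs < config.min_fs_hz:
        raise ValueError(f"fs < {config.min_fs_hz:g} Hz is too slow for turns")
    y = np.asarray(yaw_rate, dtype=float)
    if y.size < int(1.0 * fs):
        raise ValueError("need at least 1 s of signal")
    if t is None:
        t = np.arange(y.size) / fs
    sos = sp_signal.butter(2, config.lowpass_hz, "lowpass", fs=fs, output="sos")
    f = sp_signal.sosfiltfilt(sos, y)
    af = np.abs(f)

    above_enter = af > config.enter_threshold_deg_s
    if not above_enter.any():
        return []
    below_exit = af < config.exit_threshold_deg_s

    # expand every entry region outward to the surrounding exit crossings
    regions: list[tuple[int, int]] = []
    changes = np.where(np.diff(above_enter.astype(int)) != 0)[0] + 1
    starts = np.concatenate([[0], changes])
    stops = np.concatenate([changes, [above_enter.size]])
    for a, b in zip(starts, stops):
        if not above_enter[a]:
            continue
        lo = a
        while lo > 0 and not below_exit[lo - 1]:
            lo -= 1
        hi = b
        while hi < y.size and not below_exit[hi]:
            hi += 1
        regions.append((lo, hi))

    # merge overlapping regions and gaps shorter than merge_gap_s
    gap = int(config.merge_gap_s * fs)
    merged: list[list[int]] = []
    for lo, hi in sorted(regions):
        if merged and lo - merged[-1][1] <= gap:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    events: list[TurnEvent] = []
    ay = np.abs(y)
    for lo, hi in merged:
        hi = min(hi, y.size - 1)
        # the low-pass filter smears sharp pulse edges outward; shrink the
        # span to the raw signal's exit-threshold support so durations (and
        # |angle|/duration mean velocities) are not diluted
        while lo < hi and ay[lo] < config.exit_threshold_deg_s:
            lo += 1
        while hi > lo and ay[hi] < config.exit_threshold_deg_s:
            hi -= 1
        if hi <= lo:
            continue
        angle = float(np.trapezoid(y[lo:hi + 1], t[lo:hi + 1]))
        if abs(angle) < config.min_angle_deg:
            continue
        duration = float(t[hi] - t[lo])
        peak = float(np.max(np.abs(y[lo:hi + 1])))
        if config.mean_velocity_mode == "angle_over_duration":
            mean_v = abs(angle) / duration
        else:
            mean_v = float(np.mean(np.abs(y[lo:hi + 1])))
        events.append(TurnEvent(float(t[lo]), float(t[hi]), duration, angle,
                                peak, mean_v, source_location))
    return events


def summarize_turns(turns: list[TurnEvent]) -> TurnSummary:
    """Aggregate per-turn features across a session (see class docstring)."""
    if not turns:
        return TurnSummary(0, float("nan"), float("nan"), float("nan"),
                           float("nan"), float("nan"))
    angles = np.array([abs(tn.angle_deg) for tn in turns])
    durations = np.array([tn.duration_s for tn in turns])
    peaks = np.array([tn.peak_velocity_deg_s for tn in turns])
    means = np.array([tn.mean_velocity_deg_s for tn in turns])
    return TurnSummary(
        n_turns=len(turns),
        mean_angle_deg=float(angles.mean()),
        mean_duration_s=float(durations.mean()),
        velocity_max_deg_s=float(peaks.mean()),
        velocity_mean_deg_s=float(means.mean()),
        velocity_std_deg_s=float(means.std()),  # population std across turns
    )
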