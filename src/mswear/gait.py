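"""Gait event detection from ankle sagittal angular velocity.

The walking signal at the ankle is near zero while the foot is on the ground
(stance) and shows one large positive angular-velocity pulse per swing. The
detector band-passes the signal (0.5-6 Hz, zero phase), finds mid-swing peaks
above a threshold, and brackets each swing with toe-off and heel-strike
threshold crossings. Because a fixed absolute threshold on the rising/falling
flanks is systematically inside the true pulse edges, crossing times are then
refined from the half-amplitude width of the pulse measured on a lightly
low-passed copy of the signal: for a symmetric swing pulse the half-amplitude
points sit exactly one quarter width inside each edge, so
``edge = half-crossing -/+ width / 2``. Crossings are linearly interpolated
for sub-sample resolution.

Stance of stride i is toe_off(i+1) - heel_strike(i); the final swing of a
bout therefore has no stance/stride time (fields are None).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .config import GaitConfig
from .segmentation import TaskWindow


@dataclass(frozen=True)
class StrideFeatures:
    """One detected step (swing pulse) and, when the next step on the same
    foot exists, the completed stride built on it."""

    foot: str
    toe_off_t: float
    heel_strike_t: float
    swing_time_s: float
    stance_time_s: float | None = None
    stride_time_s: float | None = None

    @property
    def complete(self) -> bool:
        return self.stance_time_s is not None


@dataclass(frozen=True)
class GaitSummary:
    n_steps: int
    median_stance_time_s: float
    median_swing_time_s: float
    mobility_activity_time_s: float
    low_confidence: bool


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float,
                     i0: int, i1: int, rising: bool) -> float | None:
    """Linearly interpolated crossing time of ``level`` inside [i0, i1]."""
    seg = y[i0:i1 + 1]
    if rising:
        hits = np.where((seg[:-1] < level) & (seg[1:] >= level))[0]
        if hits.size == 0:
            return None
        i = int(hits[-1]) + i0     # last upward crossing before the peak
    else:
        hits = np.where((seg[:-1] >= level) & (seg[1:] < level))[0]
        if hits.size == 0:
            return None
        i = int(hits[0]) + i0      # first downward crossing after the peak
    y0, y1 = y[i], y[i + 1]
    frac = 0.0 if y1 == y0 else (level - y0) / (y1 - y0)
    return float(t[i] + frac * (t[i + 1] - t[i]))


def detect_gait_events(gyro_sagittal: np.ndarray, fs: float,
                       config: GaitConfig | None = None,
                       t: np.ndarray | None = None,
                       foot: str = "left") -> list[StrideFeatures]:
    """Detect steps and strides in one foot's sagittal angular velocity.

    Returns one ``StrideFeatures`` per detected swing pulse, time-ordered;
    an empty signal or a signal with no qualifying peaks gives an empty list.
    """
    config = config or GaitConfig()
    if fs < config.min_fs_hz:
        raise ValueError(f"fs < {config.min_fs_hz:g} Hz under-samples swing")
    y = np.asarray(gyro_sagittal, dtype=float)
    if y.size < int(2.0 * fs):
        raise ValueError("need at least 2 s of signal")
    if t is None:
        t = np.arange(y.size) / fs
    sos = sp_signal.butter(2, config.band_hz, "bandpass", fs=fs, output="sos")
    f = sp_signal.sosfiltfilt(sos, y)
    peaks, _ = sp_signal.find_peaks(
        f, height=config.peak_threshold_deg_s,
        distance=max(1, int(config.min_peak_separation_s * fs)))
    if peaks.size == 0:
        return []

    if config.refine_edges:
        sos_lp = sp_signal.butter(2, config.refine_lowpass_hz, "lowpass",
                                  fs=fs, output="sos")
        g = sp_signal.sosfiltfilt(sos_lp, y)
    else:
        g = f
    below = g[g < config.edge_threshold_deg_s]
    baseline = float(np.median(below)) if below.size else 0.0

    events: list[tuple[float, float]] = []
    reach = int(1.2 * fs)
    for p in peaks:
        lo = max(0, p - reach)
        hi = min(g.size - 1, p + reach)
        level = baseline + config.edge_threshold_deg_s
        toe_off = _interp_crossing(t, g, level, lo, p, rising=True)
        heel_strike = _interp_crossing(t, g, level, p, hi, rising=False)
        if toe_off is None or heel_strike is None:
            continue
        if config.refine_edges:
            half = baseline + 0.5 * (g[p] - baseline)
            up = _interp_crossing(t, g, half, lo, p, rising=True)
            down = _interp_crossing(t, g, half, p, hi, rising=False)
            if up is not None and down is not None and down > up:
                width = down - up
                toe_off, heel_strike = up - width / 2.0, down + width / 2.0
        if heel_strike > toe_off:
            events.append((toe_off, heel_strike))

    strides: list[StrideFeatures] = []
    for i, (to, hs) in enumerate(events):
        if i + 1 < len(events):
            stance = events[i + 1][0] - hs
            if stance <= 0:
                continue
            strides.append(StrideFeatures(foot, to, hs, hs - to, stance,
                                          (hs - to) + stance))
        else:
            strides.append(StrideFeatures(foot, to, hs, hs - to))
    return strides


def summarize_gait(strides: list[StrideFeatures],
                   mobility_window: TaskWindow,
                   config: GaitConfig | None = None) -> GaitSummary:
    """Session summary over the strides inside one mobility task window.

    Medians (not means) summarize per-stride times; mobility activity time is
    the duration of the mobility window itself. Fewer than
    ``config.min_strides_for_summary`` complete strides flags the summary as
    low-confidence (medians are NaN when there are none).
    """
    config = config or GaitConfig()
    if mobility_window.label not in ("tug", "walk_2min"):
        raise ValueError("mobility window must be a tug or walk_2min window")
    inside = [s for s in strides
              if mobility_window.start_s <= s.toe_off_t < mobility_window.end_s]
    complete = [s for s in inside if s.complete]
    med_stance = (float(np.median([s.stance_time_s for s in complete]))
                  if complete else math.nan)
    med_swing = (float(np.median([s.swing_time_s for s in inside]))
                 if inside else math.nan)
    return GaitSummary(
        n_steps=len(inside),
        median_stance_time_s=med_stance,
        median_swing_time_s=med_swing,
        mobility_activity_time_s=mobility_window.duration_s,
        low_confidence=len(complete) < config.min_strides_for_summary,
    )
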