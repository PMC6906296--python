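"""Sleep and fatigue features: HRV epochs, a REM-percent stand-in model,
leg-movement rate during tagged sleep, and PVT reaction-time features.

REM staging: the study used a proprietary model trained to map heart-rate
variability to REM stages. Short-term IBI variability (RMSSD) is higher in
REM than NREM, so the stand-in is an explicit, seed-free rule - an epoch is
REM when its RMSSD exceeds ``rem_rmssd_threshold_ms`` (default 32.5 ms, the
midpoint of the generator's planted NREM/REM RMSSD scales of 20 and 45 ms) -
followed by 3-epoch majority smoothing. This is a documented stand-in
contract, not a polysomnography emulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .config import SleepConfig
from .io_formats import PvtLog


@dataclass(frozen=True)
class PvtFeatures:
    mean_delay_total_ms: float
    mean_delay_first_1_ms: float
    mean_delay_first_3_ms: float
    mean_delay_first_5_ms: float
    mean_delay_first_7_ms: float
    n_challenges: int
    n_false_starts: int


@dataclass
class SleepNight:
    subject_id: str
    epochs: pd.DataFrame        # per-epoch HRV features + stage
    rem_percent: float
    leg_movement_rate_h: float


# ---------------------------------------------------------------------------
# HRV
# ---------------------------------------------------------------------------


def filter_ectopic(ibi_ms: np.ndarray, t_s: np.ndarray,
                   config: SleepConfig | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Drop physiologically implausible IBIs: outside the valid range or
    deviating more than ``ectopic_fraction`` from the running median."""
    config = config or SleepConfig()
    ibi = np.asarray(ibi_ms, dtype=float)
    t = np.asarray(t_s, dtype=float)
    lo, hi = config.ibi_valid_ms
    keep = (ibi >= lo) & (ibi <= hi)
    if ibi.size >= config.ectopic_median_window:
        med = pd.Series(ibi).rolling(
            config.ectopic_median_window, center=True, min_periods=1).median().to_numpy()
        keep &= np.abs(ibi - med) <= config.ectopic_fraction * med
    return t[keep], ibi[keep]


def hrv_epochs(ibi_t_s: np.ndarray, ibi_ms: np.ndarray,
               epoch_s: float | None = None,
               config: SleepConfig | None = None) -> pd.DataFrame:
    """Per-epoch HRV features after ectopic filtering.

    Columns: epoch_start_s, n_beats, mean_ibi_ms, sdnn_ms, rmssd_ms, valid.
    SDNN is the sd of the epoch's IBIs; RMSSD the root-mean-square of
    successive differences. Epochs with fewer than ``min_beats_per_epoch``
    beats are flagged invalid.
    """
    config = config or SleepConfig()
    epoch_s = epoch_s or config.epoch_s
    t, ibi = filter_ectopic(ibi_ms, ibi_t_s, config)
    if t.size == 0:
        return pd.DataFrame(columns=["epoch_start_s", "n_beats", "mean_ibi_ms",
                                     "sdnn_ms", "rmssd_ms", "valid"])
    t0 = t[0]
    idx = np.floor((t - t0) / epoch_s).astype(int)
    rows = []
    for e in range(int(idx.max()) + 1):
        x = ibi[idx == e]
        n = x.size
        if n >= 2:
            sdnn = float(np.std(x, ddof=1))
            rmssd = float(np.sqrt(np.mean(np.diff(x) ** 2)))
        else:
            sdnn = rmssd = math.nan
        rows.append({
            "epoch_start_s": t0 + e * epoch_s, "n_beats": n,
            "mean_ibi_ms": float(np.mean(x)) if n else math.nan,
            "sdnn_ms": sdnn, "rmssd_ms": rmssd,
            "valid": n >= config.min_beats_per_epoch,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# REM percent stand-in
# ---------------------------------------------------------------------------


def estimate_rem_percent(epochs: pd.DataFrame,
                         config: SleepConfig | None = None,
                         ) -> tuple[float, np.ndarray]:
    """REM percentage of valid epochs plus the per-epoch stage sequence.

    Rule: epoch is REM when RMSSD > threshold; 3-epoch majority smoothing
    over the valid-epoch sequence. Requires >= ``min_valid_epochs`` valid
    epochs.
    """
    config = config or SleepConfig()
    valid = epochs[epochs["valid"]].reset_index(drop=True)
    if len(valid) < config.min_valid_epochs:
        raise ValueError(
            f"need >= {config.min_valid_epochs} valid epochs, got {len(valid)}")
    rem = (valid["rmssd_ms"] > config.rem_rmssd_threshold_ms).to_numpy()
    k = config.stage_smoothing_epochs
    if k > 1 and rem.size >= k:
        half = k // 2
        smoothed = rem.copy()
        for i in range(rem.size):
            lo, hi = max(0, i - half), min(rem.size, i + half + 1)
            smoothed[i] = rem[lo:hi].sum() * 2 > (hi - lo)
        rem = smoothed
    stages = np.where(rem, "REM", "NREM")
    return float(100.0 * rem.mean()), stages


# ---------------------------------------------------------------------------
# Leg movements
# ---------------------------------------------------------------------------


def leg_movement_rate(accel_xyz: np.ndarray, fs: float,
                      config: SleepConfig | None = None,
                      ) -> tuple[float, list[tuple[float, float]]]:
    """Movements per hour of tagged sleep from an ankle accelerometer trace.

    A movement is an excursion of the band-passed (0.5-10 Hz) acceleration
    magnitude above threshold lasting at least ``movement_min_duration_s``;
    after each counted event, further activity within the refractory period
    is merged into it. Returns (rate per hour, event (start, end) times).
    """
    config = config or SleepConfig()
    accel = np.asarray(accel_xyz, dtype=float)
    n = accel.shape[0]
    duration_h = n / fs / 3600.0
    if duration_h < 1.0:
        raise ValueError("tagged sleep must last at least 1 h")
    hi = min(config.movement_band_hz[1], 0.49 * fs)
    sos = sp_signal.butter(2, (config.movement_band_hz[0], hi), "bandpass",
                           fs=fs, output="sos")
    mag = np.linalg.norm(sp_signal.sosfiltfilt(sos, accel, axis=0), axis=1)
    # envelope via short moving RMS so oscillation zero-crossings do not
    # fragment a single movement below the minimum duration
    win = max(1, int(0.25 * fs))
    kernel = np.ones(win) / win
    envelope = np.sqrt(np.convolve(mag ** 2, kernel, mode="same"))
    above = envelope > config.movement_threshold_ms2
    changes = np.where(np.diff(above.astype(int)) != 0)[0] + 1
    starts = np.concatenate([[0], changes])
    stops = np.concatenate([changes, [above.size]])
    min_len = int(config.movement_min_duration_s * fs)
    events: list[tuple[float, float]] = []
    for a, b in zip(starts, stops):
        if not above[a] or b - a < min_len:
            continue
        t0, t1 = a / fs, b / fs
        if events and t0 - events[-1][1] < config.movement_refractory_s:
            events[-1] = (events[-1][0], t1)   # merged into the previous event
        else:
            events.append((t0, t1))
    return len(events) / duration_h, events


# ---------------------------------------------------------------------------
# PVT
# ---------------------------------------------------------------------------


def pvt_features(log: PvtLog) -> PvtFeatures:
    """Mean reaction delay over the whole ~3-min test and over the first
    1, 3, 5, and 7 valid (non-false-start) challenges."""
    valid = log.valid_delays_ms
    if valid.size == 0:
        raise ValueError("PVT log has no valid challenges")

    def first_k(k: int) -> float:
        return float(np.mean(valid[:k]))

    return PvtFeatures(
        mean_delay_total_ms=float(np.mean(valid)),
        mean_delay_first_1_ms=first_k(1),
        mean_delay_first_3_ms=first_k(3),
        mean_delay_first_5_ms=first_k(5),
        mean_delay_first_7_ms=first_k(7),
        n_challenges=int(log.delay_ms.size),
        n_false_starts=int(log.false_start.sum()),
    )
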