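"""Free-living analysis: activity classification, per-day aggregation,
idle minutes, wear time, and protocol-compliance grouping.

The original study labelled free-living time with a proprietary deep neural
network activity classifier; here a transparent threshold classifier with
the same label set {idle, walking, running, other} stands in: per 5-s window
the accelerometer-magnitude variance separates idle from moving, and within
moving windows the dominant frequency of the magnitude spectrum (0.5-4 Hz)
together with a periodicity score separates rhythmic walking (stride-rate
band 0.6-1.4 Hz) and running (1.4-3.5 Hz, high magnitude) from everything
else. Walking bouts are then analyzed with the same gait and turn extractors
as the in-clinic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ActivityConfig, GaitConfig, TurnConfig
from .gait import StrideFeatures, detect_gait_events
from .io_formats import SensorRecording
from .synthetic_cohort import GRAVITY_MS2, GYRO_SAGITTAL_AXIS, GYRO_YAW_AXIS
from .turns import TurnEvent, detect_turns


@dataclass(frozen=True)
class ActivityBout:
    label: str                 # idle | walking | running | other
    start_s: float
    end_s: float
    confidence: float = 1.0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class DailyFeatures:
    subject_id: str
    day_index: int
    median_stance_time_s: float
    median_swing_time_s: float
    n_strides: int
    turn_mean_angle_deg: float
    n_turns: int
    idle_minutes: float
    worn_hours: float


@dataclass(frozen=True)
class ComplianceReport:
    subject_id: str
    weekly_fraction: tuple[float, ...]  # worn hours / target, per week
    group: str                          # high | declining | low


# ---------------------------------------------------------------------------
# Windowed features
# ---------------------------------------------------------------------------


def extract_windows(recording: SensorRecording, window_s: float = 5.0,
                    hop_s: float = 5.0) -> pd.DataFrame:
    """Per-window feature vectors from one recording.

    Columns: t_start, t_end, accel_mean, accel_var, sma (signal magnitude
    area), dom_freq_hz (dominant frequency in 0.5-4 Hz, 0 when the band is
    empty or the window is still), periodicity (dominant-bin share of band
    power), gyro_rms. Timestamp gaps yield no window.
    """
    fs = recording.sample_rate_hz
    need = int(round(window_s * fs))
    if recording.t.size < need:
        raise ValueError("need at least one full window of data")
    rows = []
    for seg in recording.segments():
        t = recording.t[seg]
        accel = recording.accel_xyz[seg]
        gyro = recording.gyro_xyz[seg]
        n_windows = int((t.size - need) // int(round(hop_s * fs))) + 1 if t.size >= need else 0
        hop = int(round(hop_s * fs))
        for w in range(n_windows):
            sl = slice(w * hop, w * hop + need)
            mag = np.linalg.norm(accel[sl], axis=1)
            centered = mag - mag.mean()
            var = float(np.var(centered))
            spec = np.abs(np.fft.rfft(centered)) ** 2
            freqs = np.fft.rfftfreq(need, 1.0 / fs)
            band = (freqs >= 0.5) & (freqs <= 4.0)
            if band.any() and spec[band].sum() > 0 and var > 1e-12:
                k = int(np.argmax(spec[band]))
                dom = float(freqs[band][k])
                periodicity = float(spec[band][k] / spec[band].sum())
            else:
                dom, periodicity = 0.0, 0.0
            rows.append({
                "t_start": float(t[sl][0]),
                "t_end": float(t[sl][-1] + 1.0 / fs),
                "accel_mean": float(mag.mean()),
                "accel_var": var,
                "sma": float(np.mean(np.sum(np.abs(accel[sl] - accel[sl].mean(axis=0)), axis=1))),
                "dom_freq_hz": dom,
                "periodicity": periodicity,
                "gyro_rms": float(np.sqrt(np.mean(gyro[sl] ** 2))),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Threshold classifier (DNN stand-in)
# ---------------------------------------------------------------------------


def _classify_window(row: pd.Series, config: ActivityConfig) -> str:
    if row["accel_var"] < config.idle_var_threshold:
        return "idle"
    lo, hi = config.walk_band_hz
    if lo <= row["dom_freq_hz"] <= hi and row["periodicity"] > config.periodicity_threshold:
        return "walking"
    rlo, rhi = config.run_band_hz
    if (rlo < row["dom_freq_hz"] <= rhi
            and np.sqrt(row["accel_var"]) > config.run_magnitude_threshold):
        return "running"
    return "other"


def classify_activity(windows: pd.DataFrame,
                      config: ActivityConfig | None = None) -> list[ActivityBout]:
    """Label windows, majority-smooth over 3 windows, and merge contiguous
    same-label windows into bouts."""
    config = config or ActivityConfig()
    if windows.empty:
        return []
    labels = [_classify_window(row, config) for _, row in windows.iterrows()]
    k = config.smoothing_windows
    if k > 1 and len(labels) >= k:
        half = k // 2
        smoothed = list(labels)
        for i in range(len(labels)):
            lo, hi = max(0, i - half), min(len(labels), i + half + 1)
            vals, counts = np.unique(labels[lo:hi], return_counts=True)
            best = vals[counts == counts.max()]
            # keep the center label on ties, else take the local majority
            smoothed[i] = labels[i] if labels[i] in best else str(best[0])
        labels = smoothed
    bouts: list[ActivityBout] = []
    for label, t0, t1 in zip(labels, windows["t_start"], windows["t_end"]):
        if bouts and bouts[-1].label == label and abs(bouts[-1].end_s - t0) < 1e-6:
            bouts[-1] = ActivityBout(label, bouts[-1].start_s, float(t1))
        else:
            bouts.append(ActivityBout(label, float(t0), float(t1)))
    return bouts


def is_worn(windows: pd.DataFrame, config: ActivityConfig | None = None) -> np.ndarray:
    """Per-window wear flag: accel variance above the noise floor OR any
    gyroscope activity."""
    config = config or ActivityConfig()
    return ((windows["accel_var"].to_numpy() > config.wear_var_floor)
            | (windows["gyro_rms"].to_numpy() > 0.0))


# ---------------------------------------------------------------------------
# Walking-bout analysis and daily aggregation
# ---------------------------------------------------------------------------


def analyze_walking_bouts(recordings: dict[str, SensorRecording],
                          bouts: list[ActivityBout],
                          gait_config: GaitConfig | None = None,
                          turn_config: TurnConfig | None = None,
                          ) -> tuple[list[StrideFeatures], list[TurnEvent]]:
    """Run the in-clinic gait and turn extractors inside each walking bout.

    Gait uses the ankle sagittal gyro (absent ankle stream -> no gait
    features); turns use the chest yaw gyro restricted to walking bouts.
    """
    strides: list[StrideFeatures] = []
    turns: list[TurnEvent] = []
    ankle = recordings.get("left_ankle") or recordings.get("right_ankle")
    chest = recordings.get("chest")
    for bout in bouts:
        if bout.label != "walking":
            continue
        if ankle is not None:
            sub = ankle.slice(bout.start_s, bout.end_s)
            if sub.t.size >= int(2 * sub.sample_rate_hz):
                strides.extend(detect_gait_events(
                    sub.gyro_xyz[:, GYRO_SAGITTAL_AXIS], sub.sample_rate_hz,
                    gait_config, t=sub.t,
                    foot=("left" if ankle.body_location.startswith("left")
                          else "right")))
        if chest is not None:
            sub = chest.slice(bout.start_s, bout.end_s)
            if sub.t.size >= int(1 * sub.sample_rate_hz):
                turns.extend(detect_turns(
                    sub.gyro_xyz[:, GYRO_YAW_AXIS], sub.sample_rate_hz,
                    turn_config, t=sub.t))
    return strides, turns


def summarize_day(subject_id: str, day_index: int,
                  recordings: dict[str, SensorRecording],
                  activity_config: ActivityConfig | None = None,
                  gait_config: GaitConfig | None = None,
                  turn_config: TurnConfig | None = None) -> DailyFeatures:
    """Classify one day's wrist stream and aggregate the day's features."""
    activity_config = activity_config or ActivityConfig()
    wrist = (recordings.get("left_wrist") or recordings.get("right_wrist")
             or next(iter(recordings.values())))
    windows = extract_windows(wrist, activity_config.window_s,
                              activity_config.hop_s)
    bouts = classify_activity(windows, activity_config)
    worn = is_worn(windows, activity_config)
    worn_hours = float(worn.sum() * activity_config.window_s / 3600.0)
    idle_minutes = sum(b.duration_s for b in bouts if b.label == "idle") / 60.0
    strides, turns = analyze_walking_bouts(recordings, bouts, gait_config,
                                           turn_config)
    complete = [s.stance_time_s for s in strides if s.complete]
    enough = len(complete) >= activity_config.min_strides_per_day
    med_stance = float(np.median(complete)) if (complete and enough) else float("nan")
    swings = [s.swing_time_s for s in strides]
    med_swing = float(np.median(swings)) if (swings and enough) else float("nan")
    angles = [abs(tn.angle_deg) for tn in turns]
    return DailyFeatures(
        subject_id=subject_id, day_index=day_index,
        median_stance_time_s=med_stance, median_swing_time_s=med_swing,
        n_strides=len(complete),
        turn_mean_angle_deg=float(np.mean(angles)) if angles else float("nan"),
        n_turns=len(turns),
        idle_minutes=float(min(idle_minutes, worn_hours * 60.0)),
        worn_hours=worn_hours,
    )


# ---------------------------------------------------------------------------
# Compliance
# ---------------------------------------------------------------------------


def compliance(worn_hours_per_week: np.ndarray, target_hours: float,
               subject_id: str = "") -> ComplianceReport:
    """Classify a subject's wear behaviour across the study weeks.

    Rules (precedence low > declining > high):
    * low: mean weekly wear < 20% of target;
    * high: >= 80% of target in all but at most 2 weeks;
    * declining: first-2-week mean >= 80% and final-2-week mean <= 60%;
    * anything else falls back to declining.
    """
    if target_hours <= 0:
        raise ValueError("target_hours must be positive")
    frac = np.asarray(worn_hours_per_week, dtype=float) / target_hours
    if frac.size == 0:
        raise ValueError("need at least one week of wear data")
    if frac.mean() < 0.20:
        group = "low"
    elif frac[:2].mean() >= 0.80 and frac[-2:].mean() <= 0.60:
        group = "declining"
    elif (frac < 0.80).sum() <= 2:
        group = "high"
    else:
        group = "declining"
    return ComplianceReport(subject_id, tuple(float(f) for f in frac), group)
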