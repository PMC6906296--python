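"""Synthetic cohort generator: raw wearable signals with planted,
disability-dependent structure.

A latent disability score ``d ~ Uniform[0, 1]`` drives every planted
parameter through documented monotone effect functions whose signs mirror the
observed feature-disability correlation structure: more disabled subjects
have longer stance times, slower and smaller turns, larger postural sway,
longer PVT delays, lower HRV, less REM sleep, more leg movements during
sleep, and more idle time. Clinical scores (EDSS on the half-step grid
1.0-6.5, MSFC-4 subtests) are generated from the same latent ``d``.

Every generated signal carries its ground truth (event schedules, stage
sequences, planted parameters) so extractors can be tested against an
independent reading of the schedule.

Signal models
-------------
* Gait: ankle sagittal angular velocity is near zero during stance and one
  smooth positive raised-cosine pulse per swing, alternating feet.
* Turns: a raised-cosine yaw-rate pulse w(t) = A (1 - cos(2 pi t / T)) / 2
  whose integral is exactly the turn angle (A = 2 angle / T).
* Sway: either an analytic sinusoid (exact oracles) or low-pass filtered
  Gaussian noise scaled to a target RMS; an accelerometer trace is derived as
  the second numerical derivative on demand.
* Sleep: per-beat IBIs follow an AR(1) around a stage-dependent mean with
  planted short-term variability (RMSSD scale) higher in REM than NREM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal

from .io_formats import (AnnotationInterval, PvtLog, SensorRecording,
                         SessionAnnotation)

GRAVITY_MS2 = 9.81

# ---------------------------------------------------------------------------
# Ground-truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrideTruth:
    foot: str
    toe_off_t: float
    heel_strike_t: float

    @property
    def swing_time_s(self) -> float:
        return self.heel_strike_t - self.toe_off_t


@dataclass
class GaitBout:
    t: np.ndarray
    traces: dict[str, np.ndarray]          # foot -> sagittal gyro deg/s
    strides: dict[str, list[StrideTruth]]  # foot -> swing events
    stance_time_s: float
    swing_time_s: float
    fs: float

    @property
    def n_swing_pulses(self) -> int:
        return sum(len(v) for v in self.strides.values())


@dataclass(frozen=True)
class TurnTruth:
    start_s: float
    end_s: float
    angle_deg: float
    duration_s: float
    peak_deg_s: float
    mean_deg_s: float


@dataclass
class SwayTrack:
    t: np.ndarray
    xy_mm: np.ndarray       # (n, 2): mediolateral, anterior-posterior
    fs: float
    model: str
    a_ml_mm: float
    a_ap_mm: float
    f_hz: float

    def to_accel(self, gravity: bool = True) -> np.ndarray:
        """(n, 3) accelerometer trace in m/s^2: x=ML, y=AP, z=vertical.

        Horizontal components are the second numerical derivative of the
        displacement track; the vertical channel carries gravity."""
        out = np.zeros((self.t.size, 3))
        for k in range(2):
            x_m = self.xy_mm[:, k] / 1000.0
            v = np.gradient(x_m, self.t)
            out[:, k] = np.gradient(v, self.t)
        if gravity:
            out[:, 2] = GRAVITY_MS2
        return out


@dataclass
class NightTruth:
    stages: list[tuple[str, float, float]]  # (stage, start_s, end_s)
    rem_percent: float
    movement_times: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Elementary signal generators
# ---------------------------------------------------------------------------


def _raised_cosine_into(trace: np.ndarray, t: np.ndarray, t0: float,
                        duration: float, amplitude: float) -> None:
    mask = (t >= t0) & (t < t0 + duration)
    trace[mask] += amplitude * (1.0 - np.cos(2.0 * np.pi * (t[mask] - t0) / duration)) / 2.0


def simulate_gait_bout(stride_rate_hz: float, stance_fraction: float,
                       duration_s: float, fs: float = 100.0,
                       noise_sd: float = 0.0, seed: int | None = None,
                       amplitude_deg_s: float = 250.0,
                       feet: Sequence[str] = ("left", "right")) -> GaitBout:
    """Sagittal ankle angular velocity for a walking bout, one trace per foot.

    Per-foot true stance = stance_fraction / stride_rate and true swing =
    (1 - stance_fraction) / stride_rate; the right foot runs half a stride
    period out of phase with the left.
    """
    if fs < 20.0:
        raise ValueError("fs < 20 Hz under-samples the swing pulse")
    if not 0.0 < stance_fraction < 1.0:
        raise ValueError("stance_fraction must be in (0, 1)")
    if duration_s * stride_rate_hz < 2.0:
        raise ValueError("duration must cover at least 2 strides")
    period = 1.0 / stride_rate_hz
    stance = stance_fraction * period
    swing = period - stance
    t = np.arange(int(round(duration_s * fs))) / fs
    rng = np.random.default_rng(seed)
    traces: dict[str, np.ndarray] = {}
    strides: dict[str, list[StrideTruth]] = {}
    for i, foot in enumerate(feet):
        offset = -period / 2.0 * i
        trace = np.zeros_like(t)
        events: list[StrideTruth] = []
        k = math.ceil((-offset - stance) / period)
        while True:
            toe_off = offset + stance + k * period
            heel_strike = toe_off + swing
            if toe_off < 0:
                k += 1
                continue
            if heel_strike > duration_s:
                break
            _raised_cosine_into(trace, t, toe_off, swing, amplitude_deg_s)
            events.append(StrideTruth(foot, toe_off, heel_strike))
            k += 1
        if noise_sd > 0:
            trace = trace + rng.normal(0.0, noise_sd, t.size)
        traces[foot] = trace
        strides[foot] = events
    return GaitBout(t=t, traces=traces, strides=strides,
                    stance_time_s=stance, swing_time_s=swing, fs=fs)


def simulate_turn(angle_deg: float, duration_s: float, fs: float = 100.0,
                  noise_sd: float = 0.0, seed: int | None = None,
                  pad_s: float = 1.0) -> tuple[np.ndarray, np.ndarray, TurnTruth]:
    """Raised-cosine yaw-rate pulse integrating exactly to ``angle_deg``.

    Returns (t, yaw_deg_s, truth); the pulse is padded with ``pad_s`` of
    (noisy) zero baseline on each side.
    """
    if duration_s <= 0:
        raise ValueError("turn duration must be positive")
    total = duration_s + 2.0 * pad_s
    t = np.arange(int(round(total * fs))) / fs
    yaw = np.zeros_like(t)
    amplitude = 2.0 * angle_deg / duration_s
    _raised_cosine_into(yaw, t, pad_s, duration_s, amplitude)
    if noise_sd > 0:
        yaw = yaw + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    truth = TurnTruth(start_s=pad_s, end_s=pad_s + duration_s,
                      angle_deg=angle_deg, duration_s=duration_s,
                      peak_deg_s=abs(amplitude),
                      mean_deg_s=abs(angle_deg) / duration_s)
    return t, yaw, truth


def simulate_sway_track(model: str, a_ml_mm: float, a_ap_mm: float,
                        f_hz: float = 0.4, duration_s: float = 30.0,
                        fs: float = 100.0, seed: int | None = None) -> SwayTrack:
    """2-D body-displacement track (mm) during quiet standing.

    ``sinusoid``: x = A_ml sin(2 pi f t), y = A_ap sin(2 pi f t + pi/2) -
    analytically tractable (1-D path length 4 A f T per axis).
    ``filtered_noise``: independent low-pass (cutoff ``f_hz``) Gaussian walks
    scaled so each axis has RMS = A / sqrt(2) (the sinusoid's RMS).
    """
    if a_ml_mm < 0 or a_ap_mm < 0:
        raise ValueError("sway amplitudes must be non-negative")
    t = np.arange(int(round(duration_s * fs))) / fs
    if model == "sinusoid":
        x = a_ml_mm * np.sin(2.0 * np.pi * f_hz * t)
        y = a_ap_mm * np.sin(2.0 * np.pi * f_hz * t + np.pi / 2.0)
    elif model == "filtered_noise":
        rng = np.random.default_rng(seed)
        sos = sp_signal.butter(2, f_hz, "lowpass", fs=fs, output="sos")
        cols = []
        for amp in (a_ml_mm, a_ap_mm):
            w = sp_signal.sosfiltfilt(sos, rng.standard_normal(t.size))
            rms = float(np.sqrt(np.mean(w ** 2)))
            cols.append(np.zeros_like(t) if amp == 0 or rms == 0
                        else w * (amp / np.sqrt(2.0)) / rms)
        x, y = cols
    else:
        raise ValueError(f"unknown sway model {model!r}")
    return SwayTrack(t=t, xy_mm=np.column_stack([x, y]), fs=fs, model=model,
                     a_ml_mm=a_ml_mm, a_ap_mm=a_ap_mm, f_hz=f_hz)


@dataclass(frozen=True)
class StageParams:
    mean_ibi_ms: float
    rmssd_ms: float
    phi: float = 0.8  # AR(1) coefficient of the per-beat deviation process


DEFAULT_STAGE_PARAMS: dict[str, StageParams] = {
    # planted short-term variability is higher in REM than NREM
    "REM": StageParams(mean_ibi_ms=800.0, rmssd_ms=45.0),
    "NREM": StageParams(mean_ibi_ms=1000.0, rmssd_ms=20.0),
    "WAKE": StageParams(mean_ibi_ms=750.0, rmssd_ms=35.0),
}


def simulate_ibi_night(stage_schedule: Sequence[tuple[str, float]],
                       stage_params: dict[str, StageParams] | None = None,
                       seed: int | None = None,
                       ) -> tuple[np.ndarray, np.ndarray, NightTruth]:
    """Per-beat IBI series for a night with a known stage schedule.

    ``stage_schedule``: (stage, minutes) pairs, stage in {REM, NREM, WAKE}.
    IBIs follow an AR(1) deviation process around the stage mean with
    innovation sd chosen so the planted RMSSD equals the stage's
    ``rmssd_ms``: sd = rmssd * sqrt((1 + phi) / 2).

    Returns (t_beats_s, ibi_ms, truth); true REM% counts REM minutes over
    total sleep (REM + NREM) minutes.
    """
    if not stage_schedule:
        raise ValueError("stage schedule must be non-empty")
    params = stage_params or DEFAULT_STAGE_PARAMS
    for stage, minutes in stage_schedule:
        if stage not in params:
            raise ValueError(f"unknown stage {stage!r}")
        if minutes <= 0:
            raise ValueError("stage minutes must be positive")
    rng = np.random.default_rng(seed)
    times, ibis, stages = [], [], []
    t = 0.0
    dev = 0.0
    for stage, minutes in stage_schedule:
        p = params[stage]
        sd = p.rmssd_ms * math.sqrt((1.0 + p.phi) / 2.0)
        start = t
        end = start + minutes * 60.0
        stages.append((stage, start, end))
        while t < end:
            dev = p.phi * dev + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            ibi = max(200.0, p.mean_ibi_ms + dev)
            t += ibi / 1000.0
            if t >= end:
                break
            times.append(t)
            ibis.append(ibi)
    sleep_min = sum(m for s, m in stage_schedule if s in ("REM", "NREM"))
    rem_min = sum(m for s, m in stage_schedule if s == "REM")
    rem_percent = 100.0 * rem_min / sleep_min if sleep_min else float("nan")
    truth = NightTruth(stages=stages, rem_percent=rem_percent)
    return np.asarray(times), np.asarray(ibis), truth


def simulate_sleep_accel(duration_s: float, movement_times: Sequence[float],
                         fs: float = 25.0, seed: int | None = None,
                         noise_sd: float = 0.01, movement_amp_ms2: float = 1.0,
                         movement_duration_s: float = 1.0,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Ankle accelerometer trace for a night: gravity + noise with planted
    leg-movement bursts (amplitude-modulated 3 Hz oscillation)."""
    t = np.arange(int(round(duration_s * fs))) / fs
    rng = np.random.default_rng(seed)
    accel = np.zeros((t.size, 3))
    accel[:, 2] = GRAVITY_MS2
    if noise_sd > 0:
        accel += rng.normal(0.0, noise_sd, accel.shape)
    for t0 in movement_times:
        mask = (t >= t0) & (t < t0 + movement_duration_s)
        envelope = np.sin(np.pi * (t[mask] - t0) / movement_duration_s) ** 2
        accel[mask, 0] += movement_amp_ms2 * envelope * np.sin(
            2.0 * np.pi * 3.0 * (t[mask] - t0))
    return t, accel


# ---------------------------------------------------------------------------
# Disability effect functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Effect:
    """Linear-in-d planted effect: value = base + slope * d + N(0, sd)."""
    base: float
    slope: float
    sd: float

    def sample(self, d: float, rng: np.random.Generator, scale: float) -> float:
        noise = rng.normal(0.0, self.sd * scale) if self.sd * scale > 0 else 0.0
        return self.base + self.slope * d + noise


@dataclass
class EffectConfig:
    """Planted effect functions and their noise.

    ``noise_scale`` multiplies every between-subject effect sd; 0 makes all
    planted features deterministic, strictly monotone functions of ``d``.
    Default sds are calibrated so the planted population Spearman correlation
    between stance time and the MSFC-4 composite is about -0.6.
    """

    noise_scale: float = 1.0
    stance_time_s: Effect = field(default_factory=lambda: Effect(0.55, 0.35, 0.12))
    # stride rate < 1 Hz with |rate slope| = stance slope keeps planted swing
    # time (1/rate - stance) strictly increasing in d alongside stance time
    stride_rate_hz: Effect = field(default_factory=lambda: Effect(0.95, -0.35, 0.03))
    turn_peak_deg_s: Effect = field(default_factory=lambda: Effect(220.0, -120.0, 30.0))
    turn_angle_deg: Effect = field(default_factory=lambda: Effect(185.0, -25.0, 5.0))
    sway_a_ml_mm: Effect = field(default_factory=lambda: Effect(1.0, 6.0, 1.0))
    sway_a_ap_mm: Effect = field(default_factory=lambda: Effect(1.2, 6.0, 1.0))
    tug_duration_s: Effect = field(default_factory=lambda: Effect(8.0, 8.0, 1.0))
    pvt_delay_ms: Effect = field(default_factory=lambda: Effect(280.0, 120.0, 30.0))
    hrv_rmssd_ms: Effect = field(default_factory=lambda: Effect(45.0, -20.0, 5.0))
    rem_fraction: Effect = field(default_factory=lambda: Effect(0.24, -0.10, 0.025))
    leg_move_rate_h: Effect = field(default_factory=lambda: Effect(2.0, 8.0, 1.0))
    idle_fraction: Effect = field(default_factory=lambda: Effect(0.45, 0.25, 0.0625))
    t25fw_s: Effect = field(default_factory=lambda: Effect(4.0, 6.0, 1.5))
    nhpt_s: Effect = field(default_factory=lambda: Effect(18.0, 15.0, 3.75))
    sdmt_correct: Effect = field(default_factory=lambda: Effect(65.0, -25.0, 6.25))
    lcva_correct: Effect = field(default_factory=lambda: Effect(60.0, -20.0, 5.0))
    edss_latent_sd: float = 0.08


EDSS_COHORT_GRID = np.arange(1.0, 7.0, 0.5)  # cohort range 1.0-6.5


def edss_from_latent(d: float) -> float:
    """Quantile-map latent disability onto the EDSS half-step grid 1.0-6.5."""
    idx = min(int(np.clip(d, 0.0, 1.0 - 1e-12) * len(EDSS_COHORT_GRID)),
              len(EDSS_COHORT_GRID) - 1)
    return float(EDSS_COHORT_GRID[idx])


@dataclass
class SubjectProfile:
    """Planted (true) per-subject parameters derived from latent ``d``."""

    subject_id: str
    d: float
    edss: float
    stance_time_s: float
    swing_time_s: float
    stride_rate_hz: float
    stance_fraction: float
    cadence_steps_min: float
    turn_peak_deg_s: float
    turn_angle_deg: float
    sway_a_ml_mm: float
    sway_a_ap_mm: float
    tug_duration_s: float
    pvt_delay_ms: float
    hrv_rmssd_ms: float
    rem_fraction: float
    leg_move_rate_h: float
    idle_fraction: float
    t25fw_s: float
    nhpt_s: float
    sdmt_correct: float
    lcva_correct: float


def simulate_subject_profile(subject_id: str, d: float, effect: EffectConfig,
                             rng: np.random.Generator) -> SubjectProfile:
    ns = effect.noise_scale
    stance = float(np.clip(effect.stance_time_s.sample(d, rng, ns), 0.3, 1.2))
    rate = float(np.clip(effect.stride_rate_hz.sample(d, rng, ns), 0.5, 1.4))
    frac = float(np.clip(stance * rate, 0.4, 0.8))
    stance = frac / rate  # keep stance, fraction and rate mutually consistent
    swing = (1.0 - frac) / rate
    d_lat = float(np.clip(d + (rng.normal(0.0, effect.edss_latent_sd * ns)
                               if effect.edss_latent_sd * ns > 0 else 0.0), 0.0, 1.0))
    return SubjectProfile(
        subject_id=subject_id, d=d, edss=edss_from_latent(d_lat),
        stance_time_s=stance, swing_time_s=swing, stride_rate_hz=rate,
        stance_fraction=frac, cadence_steps_min=120.0 * rate,
        turn_peak_deg_s=float(np.clip(effect.turn_peak_deg_s.sample(d, rng, ns), 40.0, 400.0)),
        turn_angle_deg=float(np.clip(effect.turn_angle_deg.sample(d, rng, ns), 60.0, 300.0)),
        sway_a_ml_mm=float(np.clip(effect.sway_a_ml_mm.sample(d, rng, ns), 0.2, 20.0)),
        sway_a_ap_mm=float(np.clip(effect.sway_a_ap_mm.sample(d, rng, ns), 0.2, 20.0)),
        tug_duration_s=float(np.clip(effect.tug_duration_s.sample(d, rng, ns), 5.0, 30.0)),
        pvt_delay_ms=float(np.clip(effect.pvt_delay_ms.sample(d, rng, ns), 150.0, 800.0)),
        hrv_rmssd_ms=float(np.clip(effect.hrv_rmssd_ms.sample(d, rng, ns), 5.0, 120.0)),
        rem_fraction=float(np.clip(effect.rem_fraction.sample(d, rng, ns), 0.02, 0.45)),
        leg_move_rate_h=float(np.clip(effect.leg_move_rate_h.sample(d, rng, ns), 0.0, 30.0)),
        idle_fraction=float(np.clip(effect.idle_fraction.sample(d, rng, ns), 0.1, 0.9)),
        t25fw_s=float(np.clip(effect.t25fw_s.sample(d, rng, ns), 2.5, 60.0)),
        nhpt_s=float(np.clip(effect.nhpt_s.sample(d, rng, ns), 10.0, 120.0)),
        sdmt_correct=float(np.clip(effect.sdmt_correct.sample(d, rng, ns), 5.0, 110.0)),
        lcva_correct=float(np.clip(effect.lcva_correct.sample(d, rng, ns), 5.0, 70.0)),
    )


# ---------------------------------------------------------------------------
# Clinic session
# ---------------------------------------------------------------------------


@dataclass
class ClinicTruth:
    strides: dict[str, list[StrideTruth]]   # pooled over mobility windows
    turns: list[TurnTruth]                  # planted chest/ankle turns (same)
    sway: SwayTrack


@dataclass
class ClinicSession:
    subject_id: str
    recordings: dict[str, SensorRecording]
    annotation: SessionAnnotation
    pvt_log: PvtLog
    truth: ClinicTruth


# device-frame axis conventions used by the generator (and, symmetrically,
# by the extractors' location->axis mapping): gyro axis 0 = sagittal
# (pitch), axis 2 = body-vertical (yaw); accel axis 2 = vertical.
GYRO_SAGITTAL_AXIS = 0
GYRO_YAW_AXIS = 2


def simulate_clinic_session(profile: SubjectProfile, fs: float = 100.0,
                            seed: int | None = None,
                            sensor_noise_scale: float = 1.0,
                            walk_test_duration_s: float = 120.0,
                            gyro_noise_sd: float = 3.0,
                            accel_noise_sd: float = 0.05,
                            mean_clinic_ibi_ms: float = 850.0) -> ClinicSession:
    """One structured in-clinic session for a subject.

    Protocol timeline: stand 5 s, 30-s balance, sit 5 s, three timed-up-and-go
    repeats (each with a mid-walk 180-degree-class turn), and a 2-min walk.
    Emits left/right ankle and chest recordings plus annotation and PVT log.
    """
    rng = np.random.default_rng(seed)
    g_sd = gyro_noise_sd * sensor_noise_scale
    a_sd = accel_noise_sd * sensor_noise_scale

    intervals = [AnnotationInterval("stand", 0.0, 5.0),
                 AnnotationInterval("balance_30s", 5.0, 35.0),
                 AnnotationInterval("sit", 35.0, 40.0)]
    t0 = 40.0
    tug_windows = []
    for rep in (1, 2, 3):
        end = t0 + profile.tug_duration_s
        intervals.append(AnnotationInterval("tug", t0, end, rep=rep))
        tug_windows.append((t0, end))
        t0 = end + 3.0
    walk_window = (t0, t0 + walk_test_duration_s)
    intervals.append(AnnotationInterval("walk_2min", *walk_window))
    total = walk_window[1] + 2.0
    annotation = SessionAnnotation(profile.subject_id, "all", intervals)

    n = int(round(total * fs))
    t = np.arange(n) / fs

    def blank() -> tuple[np.ndarray, np.ndarray]:
        accel = np.zeros((n, 3))
        accel[:, 2] = GRAVITY_MS2
        if a_sd > 0:
            accel += rng.normal(0.0, a_sd, accel.shape)
        gyro = rng.normal(0.0, g_sd, (n, 3)) if g_sd > 0 else np.zeros((n, 3))
        return accel, gyro

    ankle = {"left": blank(), "right": blank()}
    chest_accel, chest_gyro = blank()

    # --- gait pulses on the ankle sagittal axes inside mobility windows ----
    period = 1.0 / profile.stride_rate_hz
    swing = profile.swing_time_s
    strides: dict[str, list[StrideTruth]] = {"left": [], "right": []}
    mobility_windows = tug_windows + [walk_window]
    for (w0, w1) in mobility_windows:
        for i, foot in enumerate(("left", "right")):
            offset = w0 - period / 2.0 * i
            k = 0
            while True:
                toe_off = offset + profile.stance_time_s + k * period
                heel_strike = toe_off + swing
                if toe_off < w0:
                    k += 1
                    continue
                if heel_strike > w1:
                    break
                _raised_cosine_into(ankle[foot][1][:, GYRO_SAGITTAL_AXIS], t,
                                    toe_off, swing, 250.0)
                strides[foot].append(StrideTruth(foot, toe_off, heel_strike))
                k += 1
        # vertical bobbing so energy-based auto segmentation sees activity
        mask = (t >= w0) & (t < w1)
        ankle["left"][0][mask, 2] += 1.5 * np.sin(
            2.0 * np.pi * profile.stride_rate_hz * (t[mask] - w0))
        ankle["right"][0][mask, 2] += 1.5 * np.sin(
            2.0 * np.pi * profile.stride_rate_hz * (t[mask] - w0) + np.pi)
        chest_accel[mask, 2] += 1.0 * np.sin(
            2.0 * np.pi * 2.0 * profile.stride_rate_hz * (t[mask] - w0))

    # --- one turn per TUG on chest and ankle yaw axes -----------------------
    turns: list[TurnTruth] = []
    for (w0, w1) in tug_windows:
        peak = profile.turn_peak_deg_s * (1.0 + 0.04 * rng.standard_normal())
        angle = profile.turn_angle_deg * (1.0 + 0.02 * rng.standard_normal())
        duration = 2.0 * angle / peak
        start = 0.5 * (w0 + w1) - duration / 2.0
        for trace in (chest_gyro, ankle["left"][1], ankle["right"][1]):
            _raised_cosine_into(trace[:, GYRO_YAW_AXIS], t, start, duration,
                                2.0 * angle / duration)
        turns.append(TurnTruth(start, start + duration, angle, duration,
                               2.0 * angle / duration, angle / duration))

    # --- postural sway on the chest accelerometer during balance ------------
    sway = simulate_sway_track(
        "filtered_noise", profile.sway_a_ml_mm, profile.sway_a_ap_mm,
        f_hz=0.4, duration_s=30.0, fs=fs,
        seed=int(rng.integers(0, 2 ** 31)))
    sway.t = sway.t + 5.0  # balance window starts at t = 5 s
    mask = (t >= 5.0) & (t < 35.0)
    sway_accel = sway.to_accel(gravity=False)
    chest_accel[mask, 0] += sway_accel[: mask.sum(), 0]
    chest_accel[mask, 1] += sway_accel[: mask.sum(), 1]

    # --- chest IBI stream over the whole session ----------------------------
    phi = 0.8
    sd = profile.hrv_rmssd_ms * math.sqrt((1.0 + phi) / 2.0)
    beat_t, beat_ibi, dev = [], [], 0.0
    tb = 0.0
    while True:
        dev = phi * dev + rng.normal(0.0, sd)
        ibi = max(300.0, mean_clinic_ibi_ms + dev)
        tb += ibi / 1000.0
        if tb >= total:
            break
        # snap to the sample grid so the CSV round trip is exact
        beat_t.append(round(tb * fs) / fs)
        beat_ibi.append(ibi)
    ibi_arr = np.column_stack([beat_t, beat_ibi]) if beat_t else None

    recordings = {
        "left_ankle": SensorRecording(profile.subject_id, "left_ankle", fs, t,
                                      ankle["left"][0], ankle["left"][1]),
        "right_ankle": SensorRecording(profile.subject_id, "right_ankle", fs, t,
                                       ankle["right"][0], ankle["right"][1]),
        "chest": SensorRecording(profile.subject_id, "chest", fs, t,
                                 chest_accel, chest_gyro, ibi=ibi_arr),
    }

    # --- PVT log: ~3-min test, one challenge every ~6 s ---------------------
    n_challenges = 30
    sigma = 0.15
    delays = profile.pvt_delay_ms * np.exp(
        sigma * rng.standard_normal(n_challenges) - sigma ** 2 / 2.0)
    false_start = rng.random(n_challenges) < 0.02
    pvt = PvtLog(profile.subject_id, "clinic", delays, false_start)

    truth = ClinicTruth(strides=strides, turns=turns, sway=sway)
    return ClinicSession(profile.subject_id, recordings, annotation, pvt, truth)


# ---------------------------------------------------------------------------
# Free-living days and nights
# ---------------------------------------------------------------------------


@dataclass
class FreeLivingDay:
    subject_id: str
    day_index: int
    recordings: dict[str, SensorRecording]
    schedule: list[tuple[str, float, float]]  # (label, start_s, end_s) truth
    pvt_log: PvtLog


@dataclass
class Night:
    subject_id: str
    day_index: int
    ibi_t_s: np.ndarray
    ibi_ms: np.ndarray
    ankle_t_s: np.ndarray
    ankle_accel: np.ndarray
    ankle_fs: float
    truth: NightTruth


_BLOCK_MINUTES = {"idle": 5.0, "walking": 2.0, "other": 3.0}


def simulate_free_living_day(profile: SubjectProfile, day_index: int,
                             seed: int | None = None, fs: float = 30.0,
                             day_minutes: float = 120.0,
                             sensor_noise_scale: float = 1.0) -> FreeLivingDay:
    """A compressed daytime wear stream: blocks of idle / walking / other
    activity drawn with probabilities set by the subject's planted idle
    fraction. Wrist accel carries the class signature; ankle gyro carries
    gait pulses and chest gyro one turn per walking block."""
    rng = np.random.default_rng(seed)
    walk_frac = max(0.05, 0.25 - 0.10 * profile.d)
    other_frac = max(0.05, 1.0 - profile.idle_fraction - walk_frac)
    probs = np.array([profile.idle_fraction, walk_frac, other_frac])
    probs = probs / probs.sum()
    labels = ["idle", "walking", "other"]

    schedule: list[tuple[str, float, float]] = []
    t0 = 0.0
    while t0 < day_minutes * 60.0 - 1.0:
        label = labels[int(rng.choice(3, p=probs))]
        dur = _BLOCK_MINUTES[label] * 60.0
        dur = min(dur, day_minutes * 60.0 - t0)
        schedule.append((label, t0, t0 + dur))
        t0 += dur
    # every monitored day contains at least some walking: without it the
    # day's gait medians are undefined and short test days become degenerate
    if not any(lab == "walking" for lab, _, _ in schedule) and schedule:
        mid = len(schedule) // 2
        lab, a, b = schedule[mid]
        schedule[mid] = ("walking", a, b)

    total = day_minutes * 60.0
    n = int(round(total * fs))
    t = np.arange(n) / fs
    a_sd = 0.02 * sensor_noise_scale

    def blank() -> tuple[np.ndarray, np.ndarray]:
        accel = np.zeros((n, 3))
        accel[:, 2] = GRAVITY_MS2
        if a_sd > 0:
            accel += rng.normal(0.0, a_sd, accel.shape)
        gyro = (rng.normal(0.0, 1.0 * sensor_noise_scale, (n, 3))
                if sensor_noise_scale > 0 else np.zeros((n, 3)))
        return accel, gyro

    wrist_accel, wrist_gyro = blank()
    ankle_accel, ankle_gyro = blank()
    chest_accel, chest_gyro = blank()

    period = 1.0 / profile.stride_rate_hz
    for label, s0, s1 in schedule:
        mask = (t >= s0) & (t < s1)
        if label == "walking":
            arm = 1.5 * np.sin(2.0 * np.pi * profile.stride_rate_hz * (t[mask] - s0))
            wrist_accel[mask, 2] += arm
            ankle_accel[mask, 2] += arm
            # gait pulses on the ankle sagittal axis
            k = 0
            while True:
                toe_off = s0 + profile.stance_time_s + k * period
                heel_strike = toe_off + profile.swing_time_s
                if heel_strike > s1:
                    break
                _raised_cosine_into(ankle_gyro[:, GYRO_SAGITTAL_AXIS], t,
                                    toe_off, profile.swing_time_s, 250.0)
                k += 1
            # one turn mid-block on the chest yaw axis
            angle = profile.turn_angle_deg * (1.0 + 0.05 * rng.standard_normal()) * 0.8
            duration = 2.0 * angle / max(profile.turn_peak_deg_s, 40.0)
            _raised_cosine_into(chest_gyro[:, GYRO_YAW_AXIS], t,
                                0.5 * (s0 + s1) - duration / 2.0, duration,
                                2.0 * angle / duration)
        elif label == "other" and mask.sum() > 30:
            # broadband, aperiodic arm motion (visible in the accel magnitude,
            # so it must perturb the gravity axis too)
            sos = sp_signal.butter(2, 4.0, "lowpass", fs=fs, output="sos")
            for axis in (0, 2):
                w = rng.normal(0.0, 1.0, mask.sum())
                wrist_accel[mask, axis] += 0.8 * sp_signal.sosfiltfilt(sos, w)

    recordings = {
        "left_wrist": SensorRecording(profile.subject_id, "left_wrist", fs, t,
                                      wrist_accel, wrist_gyro),
        "left_ankle": SensorRecording(profile.subject_id, "left_ankle", fs, t,
                                      ankle_accel, ankle_gyro),
        "chest": SensorRecording(profile.subject_id, "chest", fs, t,
                                 chest_accel, chest_gyro),
    }

    n_challenges = 30
    sigma = 0.15
    delays = profile.pvt_delay_ms * np.exp(
        sigma * rng.standard_normal(n_challenges) - sigma ** 2 / 2.0)
    pvt = PvtLog(profile.subject_id, f"day{day_index}", delays,
                 rng.random(n_challenges) < 0.02)
    return FreeLivingDay(profile.subject_id, day_index, recordings, schedule, pvt)


def simulate_night(profile: SubjectProfile, day_index: int,
                   seed: int | None = None, night_hours: float = 7.0,
                   ankle_fs: float = 25.0,
                   sensor_noise_scale: float = 1.0) -> Night:
    """A tagged sleep night: chest IBI stream with REM/NREM architecture in
    ~90-min cycles and an ankle accelerometer trace with planted leg
    movements at the subject's planted hourly rate."""
    rng = np.random.default_rng(seed)
    total_min = night_hours * 60.0
    schedule: list[tuple[str, float]] = []
    remaining = total_min
    while remaining > 1.0:
        cycle = min(90.0, remaining)
        nrem = cycle * (1.0 - profile.rem_fraction)
        rem = cycle - nrem
        if nrem > 0.5:
            schedule.append(("NREM", nrem))
        if rem > 0.5:
            schedule.append(("REM", rem))
        remaining -= cycle
    ibi_t, ibi_ms, truth = simulate_ibi_night(
        schedule, seed=int(rng.integers(0, 2 ** 31)))

    duration_s = total_min * 60.0
    n_moves = int(rng.poisson(profile.leg_move_rate_h * night_hours))
    times = np.sort(rng.uniform(0.0, duration_s - 2.0, n_moves))
    # planted movements honour the detector's refractory spacing
    kept: list[float] = []
    for tm in times:
        if not kept or tm - kept[-1] >= 8.0:
            kept.append(float(tm))
    ankle_t, ankle_accel = simulate_sleep_accel(
        duration_s, kept, fs=ankle_fs, seed=int(rng.integers(0, 2 ** 31)),
        noise_sd=0.01 * sensor_noise_scale)
    truth.movement_times = kept
    return Night(profile.subject_id, day_index, ibi_t, ibi_ms,
                 ankle_t, ankle_accel, ankle_fs, truth)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    profiles: list[SubjectProfile]
    clinical: "object"                       # pandas DataFrame (clinical table)
    sessions: dict[str, ClinicSession]
    days: dict[str, list[FreeLivingDay]]
    nights: dict[str, list[Night]]
    wear_hours_week: "object | None" = None  # DataFrame subject x week
    compliance_truth: dict[str, str] | None = None


def simulate_cohort(n_subjects: int = 23, effect: EffectConfig | None = None,
                    seed: int | None = None, clinic: bool = True,
                    free_living_days: int = 0, day_minutes: float = 120.0,
                    night_hours: float = 7.0, fs_clinic: float = 100.0,
                    fs_free: float = 30.0, sensor_noise_scale: float = 1.0,
                    walk_test_duration_s: float = 120.0,
                    n_weeks_compliance: int = 8,
                    target_wear_hours_per_week: float = 84.0) -> Cohort:
    """Generate a full synthetic cohort (default n = 23, the analyzed cohort
    size): subject profiles, the clinical-score table, one in-clinic session
    per subject, and optionally ``free_living_days`` day/night streams."""
    import pandas as pd

    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    effect = effect or EffectConfig()
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_subjects)
    profiles: list[SubjectProfile] = []
    sessions: dict[str, ClinicSession] = {}
    days: dict[str, list[FreeLivingDay]] = {}
    nights: dict[str, list[Night]] = {}
    rows = []
    wear_rows = []
    compliance_truth: dict[str, str] = {}
    d_values = np.random.default_rng(root.spawn(1)[0]).uniform(0.0, 1.0, n_subjects)
    for i, ss in enumerate(subject_seeds):
        rng = np.random.default_rng(ss)
        sid = f"S{i + 1:03d}"
        profile = simulate_subject_profile(sid, float(d_values[i]), effect, rng)
        profiles.append(profile)
        rows.append({
            "subject": sid, "visit": 2, "edss": profile.edss,
            "t25fw_s": profile.t25fw_s, "nhpt_s": profile.nhpt_s,
            "sdmt_correct": float(round(profile.sdmt_correct)),
            "lcva_correct": float(round(profile.lcva_correct)),
        })
        if clinic:
            sessions[sid] = simulate_clinic_session(
                profile, fs=fs_clinic, seed=int(rng.integers(0, 2 ** 31)),
                sensor_noise_scale=sensor_noise_scale,
                walk_test_duration_s=walk_test_duration_s)
        if free_living_days > 0:
            days[sid] = [simulate_free_living_day(
                profile, k, seed=int(rng.integers(0, 2 ** 31)), fs=fs_free,
                day_minutes=day_minutes,
                sensor_noise_scale=sensor_noise_scale)
                for k in range(free_living_days)]
            nights[sid] = [simulate_night(
                profile, k, seed=int(rng.integers(0, 2 ** 31)),
                night_hours=night_hours,
                sensor_noise_scale=sensor_noise_scale)
                for k in range(free_living_days)] if night_hours > 0 else []
        # weekly wear-hours with planted compliance behaviour
        u = rng.random()
        if u < 0.10:
            group, frac = "low", rng.uniform(0.02, 0.15, n_weeks_compliance)
        elif u < 0.25:
            group = "declining"
            frac = np.linspace(rng.uniform(0.85, 1.0), rng.uniform(0.3, 0.5),
                               n_weeks_compliance)
        else:
            group, frac = "high", rng.uniform(0.85, 1.0, n_weeks_compliance)
        compliance_truth[sid] = group
        for w, f in enumerate(frac):
            wear_rows.append({"subject": sid, "week": w + 1,
                              "worn_hours": f * target_wear_hours_per_week})
    clinical = pd.DataFrame(rows)
    wear = pd.DataFrame(wear_rows)
    return Cohort(profiles=profiles, clinical=clinical, sessions=sessions,
                  days=days, nights=nights, wear_hours_week=wear,
                  compliance_truth=compliance_truth)


def planted_population_spearman(effect: EffectConfig | None = None,
                                n_mc: int = 100_000,
                                seed: int = 12345) -> float:
    """Monte-Carlo population Spearman correlation between planted stance
    time and the MSFC-4 composite under the generator's own effect plan
    (the closed-form plan, no signal synthesis)."""
    from scipy import stats as sp_stats

    effect = effect or EffectConfig()
    rng = np.random.default_rng(seed)
    ns = effect.noise_scale
    d = rng.uniform(0.0, 1.0, n_mc)

    def draw(e: Effect) -> np.ndarray:
        return e.base + e.slope * d + rng.normal(0.0, e.sd * ns, n_mc)

    stance = np.clip(draw(effect.stance_time_s), 0.3, 1.2)
    t25 = np.clip(draw(effect.t25fw_s), 2.5, 60.0)
    nhpt = np.clip(draw(effect.nhpt_s), 10.0, 120.0)
    sdmt = np.clip(draw(effect.sdmt_correct), 5.0, 110.0)
    lcva = np.clip(draw(effect.lcva_correct), 5.0, 70.0)

    def z(x: np.ndarray) -> np.ndarray:
        return (x - x.mean()) / x.std(ddof=1)

    composite = (-z(t25) - z(nhpt) + z(sdmt) + z(lcva)) / 4.0
    rho, _ = sp_stats.spearmanr(stance, composite)
    return float(rho)
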