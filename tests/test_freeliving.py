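"""Free-living classification, daily aggregation and compliance rules."""

import numpy as np
import pytest

from mswear.freeliving import (classify_activity, compliance, extract_windows,
                               summarize_day)
from mswear.io_formats import SensorRecording
from mswear.synthetic_cohort import (GRAVITY_MS2, EffectConfig,
                                     simulate_free_living_day,
                                     simulate_subject_profile)


def _still_recording(duration=60.0, fs=30.0):
    n = int(duration * fs)
    accel = np.zeros((n, 3))
    accel[:, 2] = GRAVITY_MS2
    return SensorRecording("S", "left_wrist", fs, np.arange(n) / fs,
                           accel, np.zeros((n, 3)))


def _sinusoid_recording(freq, amp=1.5, duration=60.0, fs=30.0):
    n = int(duration * fs)
    t = np.arange(n) / fs
    accel = np.zeros((n, 3))
    accel[:, 2] = GRAVITY_MS2 + amp * np.sin(2 * np.pi * freq * t)
    return SensorRecording("S", "left_wrist", fs, t, accel, np.zeros((n, 3)))


def _day(d=0.5, seed=1, minutes=60.0):
    rng = np.random.default_rng(seed)
    profile = simulate_subject_profile("S", d, EffectConfig(), rng)
    return profile, simulate_free_living_day(profile, 0, seed=seed,
                                             day_minutes=minutes)


class TestWindows:
    def test_window_count(self):
        w = extract_windows(_still_recording(10.0), 5.0, 5.0)
        assert len(w) == 2

    def test_still_signal_features(self):
        w = extract_windows(_still_recording())
        assert (w["accel_var"] < 1e-6).all()
        assert (w["dom_freq_hz"] == 0.0).all()

    def test_dominant_frequency_oracle(self):
        """Pure 1.8 Hz sinusoid: dominant frequency within FFT resolution."""
        w = extract_windows(_sinusoid_recording(1.8))
        resolution = 1.0 / 5.0  # 5-s window
        assert np.allclose(w["dom_freq_hz"], 1.8, atol=resolution)

    def test_gap_yields_no_window(self):
        rec = _still_recording(20.0)
        keep = (rec.t < 8.0) | (rec.t >= 15.0)
        rec2 = SensorRecording("S", "left_wrist", rec.sample_rate_hz,
                               rec.t[keep], rec.accel_xyz[keep],
                               rec.gyro_xyz[keep])
        w = extract_windows(rec2)
        # 8 s + 5 s of contiguous data -> 1 + 1 windows
        assert len(w) == 2


class TestClassifier:
    def test_zero_motion_idle(self):
        bouts = classify_activity(extract_windows(_still_recording()))
        assert len(bouts) == 1 and bouts[0].label == "idle"

    def test_walking_band_classified_walking(self):
        bouts = classify_activity(extract_windows(_sinusoid_recording(1.0)))
        walking = sum(b.duration_s for b in bouts if b.label == "walking")
        assert walking >= 0.95 * 60.0

    def test_running_band_with_high_magnitude(self):
        bouts = classify_activity(extract_windows(_sinusoid_recording(2.5, amp=4.0)))
        running = sum(b.duration_s for b in bouts if b.label == "running")
        assert running >= 0.9 * 60.0

    def test_bouts_tile_time(self):
        _, day = _day()
        bouts = classify_activity(extract_windows(day.recordings["left_wrist"]))
        for a, b in zip(bouts, bouts[1:]):
            assert b.start_s == pytest.approx(a.end_s, abs=1e-6)
        total = sum(b.duration_s for b in bouts)
        assert total == pytest.approx(60.0 * 60.0, abs=5.0)

    def test_planted_schedule_window_accuracy(self):
        """>= 90% of windows carry the planted schedule label (20 seeds)."""
        for s in range(20):
            profile, day = _day(d=0.3 + 0.02 * s, seed=100 + s, minutes=30.0)
            windows = extract_windows(day.recordings["left_wrist"])
            bouts = classify_activity(windows)

            def truth(tm):
                for lab, a, b in day.schedule:
                    if a <= tm < b:
                        return lab
                return "other"

            hits = total = 0
            for _, row in windows.iterrows():
                mid = 0.5 * (row["t_start"] + row["t_end"])
                label = next((b.label for b in bouts
                              if b.start_s <= mid < b.end_s), None)
                total += 1
                hits += (label == truth(mid))
            assert hits / total >= 0.90

    def test_idle_minutes_schedule_oracle(self):
        profile, day = _day(d=0.6, seed=5, minutes=60.0)
        df = summarize_day("S", 0, day.recordings)
        idle_true = sum(b - a for lab, a, b in day.schedule
                        if lab == "idle") / 60.0
        assert abs(df.idle_minutes - idle_true) <= 5.0
        assert df.idle_minutes <= df.worn_hours * 60.0 + 1e-9


class TestDailyGait:
    def test_daily_median_stance_recovers_planted(self):
        profile, day = _day(d=0.5, seed=2, minutes=60.0)
        df = summarize_day("S", 0, day.recordings)
        assert df.n_strides >= 30
        assert abs(df.median_stance_time_s - profile.stance_time_s) <= 0.03

    def test_day_without_walking_flags_absent(self):
        rec = {"left_wrist": _still_recording(600.0)}
        df = summarize_day("S", 0, rec)
        assert np.isnan(df.median_stance_time_s)
        assert df.n_strides == 0


class TestCompliance:
    def test_full_wear_is_high(self):
        rep = compliance(np.full(8, 84.0), 84.0)
        assert rep.group == "high"

    def test_ten_percent_is_low(self):
        rep = compliance(np.full(8, 8.4), 84.0)
        assert rep.group == "low"

    def test_declining_pattern(self):
        weekly = np.array([90, 85, 70, 60, 55, 50, 45, 40]) / 100.0 * 84.0
        rep = compliance(weekly, 84.0)
        assert rep.group == "declining"

    def test_high_tolerates_two_weak_weeks(self):
        weekly = np.array([1.0, 1.0, 0.5, 1.0, 0.6, 1.0, 1.0, 1.0]) * 84.0
        assert compliance(weekly, 84.0).group == "high"

    def test_unclassified_falls_back_to_declining(self):
        weekly = np.array([0.5, 0.5, 0.9, 0.3, 0.9, 0.3, 0.9, 0.3]) * 84.0
        assert compliance(weekly, 84.0).group == "declining"

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError, match="target"):
            compliance(np.full(8, 10.0), 0.0)
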