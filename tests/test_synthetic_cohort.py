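"""Generator contracts: event schedules, analytic pulse properties,
planted monotone effects, and determinism under seed."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from mswear.stats import msfc4_scores, spearman_rho
from mswear.synthetic_cohort import (DEFAULT_STAGE_PARAMS, EffectConfig,
                                     StageParams, edss_from_latent,
                                     planted_population_spearman,
                                     simulate_cohort, simulate_gait_bout,
                                     simulate_ibi_night, simulate_sway_track,
                                     simulate_turn)


class TestGaitBout:
    def test_true_phase_times_by_construction(self):
        bout = simulate_gait_bout(1.0, 0.6, 10.0, fs=100, seed=0)
        assert bout.stance_time_s == pytest.approx(0.6)
        assert bout.swing_time_s == pytest.approx(0.4)
        for foot, events in bout.strides.items():
            for ev in events:
                assert ev.swing_time_s == pytest.approx(0.4)

    def test_pulse_count_matches_schedule_enumeration(self):
        """10 s at 1 stride/s and two feet -> 20 swing pulses; the oracle
        enumerates the schedule independently (one swing per foot per
        stride period that fits entirely in the bout)."""
        bout = simulate_gait_bout(1.0, 0.6, 10.0, fs=100, seed=1)
        period, stance, swing = 1.0, 0.6, 0.4
        expected = 0
        for offset in (0.0, -period / 2):
            k = 0
            while True:
                toe_off = offset + stance + k * period
                if toe_off < 0:
                    k += 1
                    continue
                if toe_off + swing > 10.0:
                    break
                expected += 1
                k += 1
        assert bout.n_swing_pulses == expected == 20

    def test_deterministic_under_seed(self):
        a = simulate_gait_bout(0.9, 0.62, 8.0, noise_sd=5.0, seed=3)
        b = simulate_gait_bout(0.9, 0.62, 8.0, noise_sd=5.0, seed=3)
        np.testing.assert_array_equal(a.traces["left"], b.traces["left"])

    def test_undersampled_fs_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            simulate_gait_bout(1.0, 0.6, 10.0, fs=10)

    def test_events_lie_inside_bout(self):
        bout = simulate_gait_bout(1.2, 0.55, 6.0, fs=50, seed=2)
        for events in bout.strides.values():
            for ev in events:
                assert 0.0 <= ev.toe_off_t < ev.heel_strike_t <= 6.0


class TestTurn:
    def test_analytic_pulse_properties(self):
        """Raised cosine: peak = 2 angle / T, mean = angle / T, and the
        trapezoid integral of the emitted trace recovers the angle."""
        t, yaw, truth = simulate_turn(180.0, 2.0, fs=100)
        assert truth.peak_deg_s == pytest.approx(180.0)
        assert truth.mean_deg_s == pytest.approx(90.0)
        assert yaw.max() == pytest.approx(180.0, abs=0.1)
        assert np.trapezoid(yaw, t) == pytest.approx(180.0, abs=0.2)

    def test_quadrature_within_tenth_percent(self):
        t, yaw, _ = simulate_turn(123.0, 1.7, fs=100)
        assert np.trapezoid(yaw, t) == pytest.approx(123.0, rel=1e-3)

    def test_zero_angle_gives_zero_trace(self):
        _, yaw, _ = simulate_turn(0.0, 2.0, fs=100)
        assert np.all(yaw == 0.0)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            simulate_turn(90.0, 0.0)


class TestSwayTrack:
    def test_sinusoid_path_length_analytic(self):
        """Each sinusoid cycle travels 4A, so path = 4 A f T."""
        tr = simulate_sway_track("sinusoid", 2.0, 3.0, 0.5, 30.0, 100)
        path_ml = np.sum(np.abs(np.diff(tr.xy_mm[:, 0])))
        assert path_ml == pytest.approx(4 * 2.0 * 0.5 * 30.0, rel=0.01)

    def test_zero_amplitude_zero_path(self):
        tr = simulate_sway_track("sinusoid", 0.0, 3.0, 0.5, 30.0, 100)
        assert np.sum(np.abs(np.diff(tr.xy_mm[:, 0]))) == 0.0

    def test_filtered_noise_deterministic(self):
        a = simulate_sway_track("filtered_noise", 2.0, 2.0, 0.4, 30.0, 100, seed=5)
        b = simulate_sway_track("filtered_noise", 2.0, 2.0, 0.4, 30.0, 100, seed=5)
        np.testing.assert_array_equal(a.xy_mm, b.xy_mm)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_sway_track("sinusoid", -1.0, 2.0)


class TestIbiNight:
    def test_rem_percent_arithmetic(self):
        _, _, truth = simulate_ibi_night([("REM", 90.0), ("NREM", 310.0)], seed=0)
        assert truth.rem_percent == pytest.approx(22.5)

    def test_all_nrem_zero_rem(self):
        _, _, truth = simulate_ibi_night([("NREM", 120.0)], seed=0)
        assert truth.rem_percent == 0.0

    def test_constant_ibi_degenerate_rmssd_zero(self):
        params = {"NREM": StageParams(mean_ibi_ms=800.0, rmssd_ms=0.0)}
        _, ibi, _ = simulate_ibi_night([("NREM", 30.0)], params, seed=0)
        assert np.sqrt(np.mean(np.diff(ibi) ** 2)) == 0.0

    def test_planted_rmssd_scale(self):
        """AR(1) innovation sd = rmssd sqrt((1+phi)/2) plants the RMSSD."""
        _, ibi, _ = simulate_ibi_night([("NREM", 240.0)], seed=1)
        rmssd = np.sqrt(np.mean(np.diff(ibi) ** 2))
        assert rmssd == pytest.approx(DEFAULT_STAGE_PARAMS["NREM"].rmssd_ms,
                                      rel=0.15)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            simulate_ibi_night([])


class TestCohort:
    def test_noise_free_monotone_effects(self):
        """With effect noise 0 every planted feature is a strictly monotone
        function of d with the documented sign."""
        cohort = simulate_cohort(n_subjects=12, seed=9,
                                 effect=EffectConfig(noise_scale=0.0),
                                 clinic=False)
        d = np.array([p.d for p in cohort.profiles])
        signs = {
            "stance_time_s": +1, "swing_time_s": +1, "turn_peak_deg_s": -1,
            "turn_angle_deg": -1, "sway_a_ml_mm": +1, "sway_a_ap_mm": +1,
            "pvt_delay_ms": +1, "hrv_rmssd_ms": -1, "rem_fraction": -1,
            "leg_move_rate_h": +1, "idle_fraction": +1,
            "tug_duration_s": +1,
        }
        for attr, sign in signs.items():
            values = np.array([getattr(p, attr) for p in cohort.profiles])
            rho = spearman_rho(values, d)
            assert rho == pytest.approx(sign), attr

    def test_edss_grid_and_range(self):
        cohort = simulate_cohort(n_subjects=23, seed=4, clinic=False)
        for p in cohort.profiles:
            assert p.edss in set(np.arange(1.0, 7.0, 0.5))
        assert edss_from_latent(0.0) == 1.0
        assert edss_from_latent(1.0) == 6.5

    def test_same_seed_identical_cohort(self):
        a = simulate_cohort(n_subjects=5, seed=11, clinic=False)
        b = simulate_cohort(n_subjects=5, seed=11, clinic=False)
        assert [p.stance_time_s for p in a.profiles] == \
               [p.stance_time_s for p in b.profiles]
        assert a.clinical.equals(b.clinical)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="n_subjects"):
            simulate_cohort(n_subjects=2, clinic=False)

    def test_monte_carlo_recovery_of_planted_rho(self):
        """Mean sample Spearman(stance, composite) over replicate cohorts of
        n = 23 matches the generator's own closed-form plan within 0.1."""
        planted = planted_population_spearman(n_mc=100_000, seed=0)
        rhos = []
        for s in range(200):
            cohort = simulate_cohort(n_subjects=23, seed=1000 + s, clinic=False)
            scored = msfc4_scores(cohort.clinical)
            stance = np.array([p.stance_time_s for p in cohort.profiles])
            rhos.append(spearman_rho(stance,
                                     scored["msfc4_composite"].to_numpy()))
        assert np.mean(rhos) == pytest.approx(planted, abs=0.1)
        assert planted == pytest.approx(-0.6, abs=0.05)
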