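"""Clinical scoring and correlation statistics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mswear.config import StatsConfig
from mswear.stats import (correlation_table, msfc4_scores, spearman_pvalue,
                          spearman_rho, storey_q, variability_vs_days)


def _clinical(rows):
    return pd.DataFrame([
        {"subject": f"S{i}", "visit": 2, "edss": 2.0, **row}
        for i, row in enumerate(rows)
    ])


class TestMsfc4:
    def test_subject_at_reference_mean_scores_zero(self):
        raw = _clinical([
            {"t25fw_s": 4.0, "nhpt_s": 18.0, "sdmt_correct": 60, "lcva_correct": 55},
            {"t25fw_s": 6.0, "nhpt_s": 22.0, "sdmt_correct": 50, "lcva_correct": 45},
            {"t25fw_s": 5.0, "nhpt_s": 20.0, "sdmt_correct": 55, "lcva_correct": 50},
        ])
        scored = msfc4_scores(raw)
        mid = scored.iloc[2]
        assert mid["z_25fw"] == pytest.approx(0.0)
        assert mid["msfc4_composite"] == pytest.approx(0.0)

    def test_one_sd_slower_walk(self):
        ref = _clinical([
            {"t25fw_s": 4.0, "nhpt_s": 18.0, "sdmt_correct": 45, "lcva_correct": 35},
            {"t25fw_s": 6.0, "nhpt_s": 22.0, "sdmt_correct": 55, "lcva_correct": 45},
        ])
        target = _clinical([
            {"t25fw_s": 5.0 + np.std([4.0, 6.0], ddof=1), "nhpt_s": 20.0,
             "sdmt_correct": 50, "lcva_correct": 40},
        ])
        scored = msfc4_scores(target, reference=ref)
        assert scored["z_25fw"].iloc[0] == pytest.approx(-1.0)
        assert scored["msfc4_composite"].iloc[0] == pytest.approx(-0.25)

    def test_symmetric_cohort_composites_sum_to_zero(self):
        raw = _clinical([
            {"t25fw_s": 4.0, "nhpt_s": 18.0, "sdmt_correct": 60, "lcva_correct": 50},
            {"t25fw_s": 6.0, "nhpt_s": 24.0, "sdmt_correct": 40, "lcva_correct": 30},
        ])
        scored = msfc4_scores(raw)
        assert scored["msfc4_composite"].sum() == pytest.approx(0.0)

    def test_reference_cohort_composite_mean_zero(self):
        rng = np.random.default_rng(0)
        raw = _clinical([
            {"t25fw_s": rng.uniform(4, 10), "nhpt_s": rng.uniform(18, 35),
             "sdmt_correct": rng.integers(30, 70),
             "lcva_correct": rng.integers(25, 60)} for _ in range(23)
        ])
        scored = msfc4_scores(raw)
        assert scored["msfc4_composite"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_reference_names_subscore(self):
        raw = _clinical([
            {"t25fw_s": 5.0, "nhpt_s": 20.0, "sdmt_correct": 50, "lcva_correct": 40},
            {"t25fw_s": 5.0, "nhpt_s": 21.0, "sdmt_correct": 51, "lcva_correct": 41},
        ])
        with pytest.raises(ValueError, match="t25fw_s"):
            msfc4_scores(raw)

    def test_inv_time_nhpt_convention(self):
        raw = _clinical([
            {"t25fw_s": 4.0, "nhpt_s": 18.0, "sdmt_correct": 60, "lcva_correct": 50},
            {"t25fw_s": 6.0, "nhpt_s": 24.0, "sdmt_correct": 40, "lcva_correct": 30},
            {"t25fw_s": 5.0, "nhpt_s": 20.0, "sdmt_correct": 50, "lcva_correct": 40},
        ])
        scored = msfc4_scores(raw, config=StatsConfig(nhpt_mode="inv_time"))
        # slower pegboard still means lower z under the 1/time convention
        assert scored["z_9hpt"].iloc[1] < scored["z_9hpt"].iloc[0]


def _brute_spearman(x, y):
    """Independent oracle: explicit midranks, then Pearson."""
    def midrank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks
    rx, ry = midrank(np.asarray(x, float)), midrank(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)

    def test_tied_example_matches_brute_force(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        assert spearman_rho(x, y) == pytest.approx(_brute_spearman(x, y))

    def test_random_vectors_match_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = int(rng.integers(4, 40))
            x = rng.integers(0, 8, n).astype(float)  # plenty of ties
            y = rng.normal(0, 1, n)
            if np.all(x == x[0]):
                continue
            assert spearman_rho(x, y) == pytest.approx(
                _brute_spearman(x, y), abs=1e-12)

    def test_constant_input_undefined(self):
        assert np.isnan(spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_pairwise_deletion(self):
        x = np.array([1.0, np.nan, 2.0, 3.0])
        y = np.array([5.0, 1.0, 6.0, 7.0])
        assert spearman_rho(x, y) == pytest.approx(1.0)

    def test_pvalue_worked_examples(self):
        assert round(spearman_pvalue(-0.546, 23), 4) == 0.0070
        assert round(spearman_pvalue(0.653, 23), 4) == 0.0007
        assert spearman_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_pvalue_limit_and_preconditions(self):
        assert spearman_pvalue(1.0, 23) == 0.0
        with pytest.raises(ValueError):
            spearman_pvalue(0.5, 3)

    def test_pvalue_matches_scipy_t_mode(self):
        from scipy import stats as sp_stats
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=23), rng.normal(size=23)
        res = sp_stats.spearmanr(x, y)
        assert spearman_pvalue(res.statistic, 23) == pytest.approx(
            res.pvalue, rel=1e-9)


def _brute_bh(p):
    """Textbook Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        prev = min(prev, p[i] * m / (rank_idx + 1))
        adj[i] = prev
    return adj


class TestStoreyQ:
    def test_bh_hand_example(self):
        q = storey_q([0.005, 0.01, 0.03, 0.03], pi0=1.0)
        np.testing.assert_allclose(q, [0.02, 0.02, 0.03, 0.03])

    def test_single_p(self):
        np.testing.assert_allclose(storey_q([0.04], pi0=1.0), [0.04])

    def test_pi0_one_equals_brute_force_bh(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, m)
            np.testing.assert_allclose(storey_q(p, pi0=1.0), _brute_bh(p),
                                       atol=1e-12)

    def test_pi0_one_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, 50)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(storey_q(p, pi0=1.0), q_sm, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_q_monotone_in_p(self, p):
        q = storey_q(np.array(p), pi0=1.0)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_storey_pi0_shrinks_q_under_signal(self):
        rng = np.random.default_rng(3)
        p = np.concatenate([rng.uniform(0, 0.001, 40), rng.uniform(0, 1, 10)])
        q_storey = storey_q(p)
        q_bh = storey_q(p, pi0=1.0)
        assert (q_storey <= q_bh + 1e-12).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            storey_q([0.5, 1.5])


class TestCorrelationTable:
    def _tables(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"S{i}" for i in range(n)]
        feats = pd.DataFrame({"f1": rng.normal(size=n),
                              "f2": rng.normal(size=n)}, index=idx)
        clin = pd.DataFrame({"m1": rng.normal(size=n),
                             "m2": rng.normal(size=n)}, index=idx)
        return feats, clin

    def test_monotone_planted_gives_minus_one(self):
        idx = [f"S{i}" for i in range(8)]
        feats = pd.DataFrame({"stance": np.arange(8.0)}, index=idx)
        clin = pd.DataFrame({"composite": -np.arange(8.0) ** 1.5}, index=idx)
        row = correlation_table(feats, clin).iloc[0]
        assert row["rho"] == pytest.approx(-1.0)

    def test_permutation_invariance(self):
        feats, clin = self._tables()
        base = correlation_table(feats, clin)
        perm = np.random.default_rng(1).permutation(feats.index)
        shuffled = correlation_table(feats.loc[perm], clin.loc[perm])
        pd.testing.assert_frame_equal(
            base.sort_values(["clinical_measure", "feature"]).reset_index(drop=True),
            shuffled.sort_values(["clinical_measure", "feature"]).reset_index(drop=True))

    def test_q_families_are_per_measure(self):
        feats, clin = self._tables(n=12, seed=2)
        table = correlation_table(feats, clin)
        for measure, grp in table.groupby("clinical_measure"):
            np.testing.assert_allclose(
                grp["q"].to_numpy(),
                storey_q(grp["p"].to_numpy()), atol=1e-12)

    def test_no_shared_subjects_rejected(self):
        feats, clin = self._tables()
        clin.index = [f"T{i}" for i in range(len(clin))]
        with pytest.raises(ValueError, match="shared"):
            correlation_table(feats, clin)

    def test_significance_flags_consistent(self):
        feats, clin = self._tables(n=16, seed=4)
        table = correlation_table(feats, clin)
        for _, r in table.iterrows():
            assert r["sig_p05"] == (r["p"] <= 0.05)
            assert r["sig_q01"] == (r["q"] <= 0.01)


class TestVariabilityVsDays:
    def _daily(self, values_by_subject):
        rows = []
        for sid, values in values_by_subject.items():
            for day, v in enumerate(values):
                rows.append({"subject": sid, "day_index": day, "value": v})
        return pd.DataFrame(rows)

    def test_constant_series_zero_curve(self):
        daily = self._daily({"A": [0.6] * 20})
        curves = variability_vs_days(daily, [1, 5], seed=0)
        assert (curves["se_median"] == 0.0).all()

    def test_concentration_of_k_day_median(self):
        """iid normal daily values: the 49-day median deviates less than the
        1-day value in every seeded replicate."""
        for s in range(20):
            rng = np.random.default_rng(s)
            daily = self._daily({"A": rng.normal(0, 1, 56)})
            curves = variability_vs_days(daily, [1, 49], n_resamples=200,
                                         seed=s)
            a = curves[curves["subject"] == "A"].set_index("k_days")
            assert a.loc[49, "se_median"] < a.loc[1, "se_median"]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        daily = self._daily({"A": rng.normal(0, 1, 30)})
        c1 = variability_vs_days(daily, [1, 7], seed=5)
        c2 = variability_vs_days(daily, [1, 7], seed=5)
        pd.testing.assert_frame_equal(c1, c2)

    def test_oversized_k_skipped(self):
        daily = self._daily({"A": [1.0, 2.0, 3.0]})
        curves = variability_vs_days(daily, [2, 10], seed=0)
        assert set(curves["k_days"]) == {2}
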