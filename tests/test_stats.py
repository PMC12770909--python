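import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dstacs.stats import (
    coefficient_of_variation,
    cv_by_montage,
    holm_correct,
    phase_modulation_test,
    whr_statistic,
)
from dstacs.superposition import default_phase_lags


def make_table(values: np.ndarray, lags=None) -> pd.DataFrame:
    lags = default_phase_lags() if lags is None else lags
    n_ind, n_lags = values.shape
    return pd.DataFrame([
        {"individual_id": f"i{i:02d}", "phase_lag": lags[j], "value": values[i, j],
         "metric": "rdm", "montage_id": "m1", "region_set": "M1s"}
        for i in range(n_ind) for j in range(n_lags)
    ])


class TestWhrStatistic:
    def test_two_point_hand_evaluation(self):
        # full double sum over theta = (0, pi), w = (1, 1): 2*k(0) + 2*k(pi)
        # with the second-form kernel k(d) = |pi - |d|| - pi/2
        # - 2.895*(|sin d| - 2/pi); sin vanishes at both differences, so
        # T = 2*(pi/2 + 5.79/pi) + 2*(-pi/2 + 5.79/pi) = 23.16/pi
        expected = 23.16 / np.pi
        assert whr_statistic(np.array([0.0, np.pi]), np.ones(2)) == pytest.approx(expected)
        assert expected == pytest.approx(7.372056964016592)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(rotation=st.floats(-10.0, 10.0), seed=st.integers(0, 50))
    def test_invariant_under_common_rotation(self, rotation, seed):
        rng = np.random.default_rng(seed)
        angles = rng.uniform(0, 2 * np.pi, size=12)
        weights = rng.uniform(0, 1, size=12)
        assert whr_statistic(angles + rotation, weights) == pytest.approx(
            whr_statistic(angles, weights), rel=1e-9
        )

    def test_invariant_under_joint_permutation(self):
        rng = np.random.default_rng(3)
        angles = rng.uniform(0, 2 * np.pi, size=16)
        weights = rng.uniform(0, 1, size=16)
        perm = rng.permutation(16)
        assert whr_statistic(angles[perm], weights[perm]) == pytest.approx(
            whr_statistic(angles, weights), rel=1e-12
        )

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            whr_statistic(np.array([1.0]), np.array([1.0]))


class TestPhaseModulationTest:
    def test_identical_values_give_p_one(self):
        table = make_table(np.ones((6, 8)))
        res = phase_modulation_test(table, n_perm=200, seed=0)
        assert res.p_raw == 1.0

    def test_strong_modulation_reaches_minimum_p(self):
        rng = np.random.default_rng(0)
        lags = default_phase_lags()
        values = 1.0 + 0.5 * np.cos(lags)[None, :] + rng.normal(0, 0.01, size=(18, 8))
        res = phase_modulation_test(make_table(values), n_perm=999, seed=1)
        assert res.p_raw == pytest.approx(1.0 / 1000.0)

    def test_p_bounded_below_by_permutation_count(self):
        rng = np.random.default_rng(2)
        res = phase_modulation_test(make_table(rng.normal(size=(5, 8))), n_perm=200, seed=0)
        assert res.p_raw >= 1.0 / 201.0

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(4)
        table = make_table(rng.normal(size=(6, 8)))
        r1 = phase_modulation_test(table, n_perm=500, seed=7)
        r2 = phase_modulation_test(table, n_perm=500, seed=7)
        assert r1.p_raw == r2.p_raw and r1.statistic == r2.statistic

    def test_missing_cell_rejected(self):
        table = make_table(np.ones((4, 8))).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            phase_modulation_test(table, n_perm=200, seed=0)

    def test_duplicate_cell_rejected(self):
        table = make_table(np.ones((4, 8)))
        table = pd.concat([table, table.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            phase_modulation_test(table, n_perm=200, seed=0)

    def test_few_permutations_warn(self):
        with pytest.warns(RuntimeWarning, match="permutations"):
            phase_modulation_test(make_table(np.ones((4, 8))), n_perm=50, seed=0)

    def test_null_rejection_rate_small_scale(self):
        # coarse type-I check (the full-scale calibration lives in the
        # acceptance suite)
        rej = 0
        n_tables = 400
        for k in range(n_tables):
            rng = np.random.default_rng(np.random.SeedSequence([77, k]))
            p = phase_modulation_test(
                make_table(rng.normal(size=(10, 8))), n_perm=199, seed=k
            ).p_raw
            rej += p <= 0.05
        assert abs(rej / n_tables - 0.05) < 0.03


class TestHolmCorrection:
    def test_single_p_unchanged(self):
        assert holm_correct([0.03]) == pytest.approx([0.03])

    def test_step_down_arithmetic(self):
        assert holm_correct([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_adjusted_dominates_raw_and_preserves_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.001, 1.0, size=10)
        adj = holm_correct(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rejections_between_bonferroni_and_raw(self):
        alpha = 0.05
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.uniform(0.0005, 0.5, size=8)
            holm_rej = (holm_correct(p) < alpha).sum()
            bonf_rej = (p < alpha / len(p)).sum()
            raw_rej = (p < alpha).sum()
            assert bonf_rej <= holm_rej <= raw_rej

    def test_empty_input(self):
        assert len(holm_correct([])) == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_correct([0.5, 1.5])


class TestCoefficientOfVariation:
    def test_constant_values_have_zero_cv(self):
        assert coefficient_of_variation([1.0, 1.0, 1.0]) == 0.0

    def test_two_point_example(self):
        # SD = sqrt(2), mean = 2 -> 70.71%
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(70.710678, abs=1e-5)

    def test_scale_invariant(self):
        values = np.random.default_rng(7).lognormal(0, 0.5, size=30)
        assert coefficient_of_variation(5.0 * values) == pytest.approx(
            coefficient_of_variation(values), rel=1e-12
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])

    def test_cv_by_montage_averages_over_lags(self):
        rng = np.random.default_rng(8)
        values = rng.lognormal(0, 0.3, size=(6, 8))
        table = make_table(values)
        cv = cv_by_montage(table, "rdm", "M1s")
        expected = np.mean([
            coefficient_of_variation(values[:, j]) for j in range(8)
        ])
        assert cv["m1"] == pytest.approx(expected)
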