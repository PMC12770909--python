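import numpy as np
import pytest

from dstacs.geometry import normal_component
from dstacs.metrics import (
    analyze_montage,
    delta_dotp,
    dotp,
    effective_area,
    ideal_dotp,
    peak_magnitude,
    peak_normal_component,
    rdm,
)
from dstacs.superposition import (
    TimeResolvedField,
    default_phase_lags,
    make_time_grid,
    superpose,
)
from dstacs.thresholding import ThresholdMask

from .conftest import random_basis


def trivial_mask(n):
    return ThresholdMask(
        excluded=np.zeros(n, dtype=bool), zeroed=np.zeros(n, dtype=bool),
        upper=np.inf, lower=0.0,
    )


def series_pair(seed, n_nodes=30, n_steps=8):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n_steps, n_nodes))


class TestPeaks:
    def test_peak_magnitude_is_vector_norm(self):
        field = TimeResolvedField(np.array([[[3.0, 4.0, 0.0]]]), np.array([0.0]), 0.0)
        value = peak_magnitude(field, trivial_mask(1), np.array([True]))
        assert value == pytest.approx(5.0)

    def test_zero_lag_peak_factorises(self, sheet):
        basis = random_basis(sheet, 11)
        times = make_time_grid(24, basis.f)
        field = superpose(basis, 0.0, times)
        region = np.ones(sheet.n_nodes, dtype=bool)
        expected = (
            np.abs(np.sin(2 * np.pi * basis.f * times)).max()
            * np.linalg.norm(basis.io_amp * (basis.e_r1 - basis.e_c1 + basis.e_r2), axis=1).max()
        )
        assert peak_magnitude(field, trivial_mask(sheet.n_nodes), region) == pytest.approx(expected)

    def test_peak_invariant_under_time_permutation(self, sheet):
        basis = random_basis(sheet, 12)
        field = superpose(basis, 1.0, make_time_grid(12, basis.f))
        region = np.ones(sheet.n_nodes, dtype=bool)
        ref = peak_magnitude(field, trivial_mask(sheet.n_nodes), region)
        field.vectors = field.vectors[::-1]
        assert peak_magnitude(field, trivial_mask(sheet.n_nodes), region) == ref

    def test_peak_normal_field_aligned_with_normals(self, sheet):
        vectors = np.broadcast_to(2.0 * sheet.normals, (1, sheet.n_nodes, 3))
        field = TimeResolvedField(np.array(vectors), np.array([0.0]), 0.0)
        abs_peak, inward = peak_normal_component(
            field, sheet.normals, trivial_mask(sheet.n_nodes),
            np.ones(sheet.n_nodes, dtype=bool),
        )
        assert abs_peak == pytest.approx(2.0)
        assert inward == pytest.approx(-2.0)  # purely outward field

    def test_peak_normal_sign_handling(self):
        normals = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        vectors = np.array([[[0.0, 0.0, 1.5], [0.0, 0.0, -2.0]]])
        field = TimeResolvedField(vectors, np.array([0.0]), 0.0)
        abs_peak, inward = peak_normal_component(
            field, normals, trivial_mask(2), np.array([True, True])
        )
        assert abs_peak == pytest.approx(2.0)
        assert inward == pytest.approx(2.0)

    def test_empty_region_after_masking_raises(self, sheet):
        basis = random_basis(sheet, 13)
        field = superpose(basis, 0.0, make_time_grid(4, basis.f))
        mask = trivial_mask(sheet.n_nodes)
        mask.excluded[:] = True
        with pytest.raises(ValueError, match="empty"):
            peak_magnitude(field, mask, np.ones(sheet.n_nodes, dtype=bool))

    def test_peaks_scale_linearly_with_current(self, sheet):
        basis = random_basis(sheet, 14)
        times = make_time_grid(8, basis.f)
        region = np.ones(sheet.n_nodes, dtype=bool)
        mask = trivial_mask(sheet.n_nodes)
        p1 = peak_magnitude(superpose(basis, 0.7, times), mask, region)
        basis.io_amp *= 3.0
        p3 = peak_magnitude(superpose(basis, 0.7, times), mask, region)
        assert p3 == pytest.approx(3 * p1)


class TestRdm:
    def test_identical_distributions_give_zero(self):
        s = series_pair(0)
        assert rdm(s, s) == 0.0
        assert rdm(s, s, mode="envelope") == 0.0

    def test_disjoint_supports_give_sqrt_two(self):
        s0 = np.zeros((4, 10))
        s1 = np.zeros((4, 10))
        s0[:, :5] = 1.0
        s1[:, 5:] = 2.0
        assert rdm(s0, s1) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_invariant_to_positive_scaling(self):
        x, y = series_pair(1), series_pair(2)
        assert rdm(3.7 * x, 0.01 * y) == pytest.approx(rdm(x, y), abs=1e-12)

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            rdm(np.ones((4, 5)), np.ones((4, 6)))

    def test_all_degenerate_steps_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            rdm(np.zeros((4, 5)), np.ones((4, 5)))

    def test_unknown_mode_rejected(self):
        s = series_pair(3)
        with pytest.raises(ValueError, match="mode"):
            rdm(s, s, mode="median")


class TestDotp:
    def test_global_negation_gives_minus_one(self):
        s = series_pair(4)
        assert dotp(s, -s) == -1.0

    def test_identical_series_give_plus_one(self):
        s = series_pair(5)
        assert dotp(s, s) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_give_zero(self):
        s0 = np.zeros((4, 10))
        s1 = np.zeros((4, 10))
        s0[:, :5] = 1.0
        s1[:, 5:] = 1.0
        assert dotp(s0, s1) == 0.0

    def test_bounded_in_unit_interval(self):
        for seed in range(5):
            val = dotp(series_pair(seed), series_pair(seed + 100))
            assert -1.0 <= val <= 1.0


class TestIdealDotp:
    def test_zero_lag_is_one_for_any_powers(self):
        times = make_time_grid(24, 20.0)
        for powers in ((1.0, 1.0), (5.0, 0.1), (0.0, 2.0)):
            assert ideal_dotp(powers, 0.0, times, f=20.0) == pytest.approx(1.0, abs=1e-12)

    def test_antiphase_balanced_powers_give_zero(self):
        # per-step cosine is (P1 - P2) / (P1 + P2) at lag pi
        times = make_time_grid(24, 20.0)
        assert ideal_dotp((2.0, 2.0), np.pi, times, f=20.0) == pytest.approx(0.0, abs=1e-12)

    def test_antiphase_matches_power_ratio_oracle(self):
        times = make_time_grid(24, 20.0)
        for p1, p2 in ((1.0, 3.0), (4.0, 1.0), (0.5, 0.5)):
            expected = (p1 - p2) / (p1 + p2)
            assert ideal_dotp((p1, p2), np.pi, times, f=20.0) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_about_pi(self):
        times = make_time_grid(24, 20.0)
        for phi in (np.pi / 4, np.pi / 2, 3 * np.pi / 4):
            a = ideal_dotp((1.0, 2.0), phi, times, f=20.0)
            b = ideal_dotp((1.0, 2.0), 2 * np.pi - phi, times, f=20.0)
            assert a == pytest.approx(b, abs=1e-9)

    def test_zero_total_power_rejected(self):
        with pytest.raises(ValueError):
            ideal_dotp((0.0, 0.0), 1.0, make_time_grid(4, 20.0), f=20.0)


class TestDeltaDotp:
    @pytest.mark.parametrize(
        "observed,ideal,expected",
        [(0.5, 0.5, 0.0), (0.7, 0.5, 0.2), (-1.0, 1.0, 2.0)],
    )
    def test_absolute_difference(self, observed, ideal, expected):
        assert delta_dotp(observed, ideal) == pytest.approx(expected)


class TestEffectiveArea:
    def test_uniform_field_covers_whole_target(self):
        series = np.ones((6, 20))
        target = np.zeros(20, dtype=bool)
        target[:8] = True
        areas = np.full(20, 2.0)
        assert effective_area(series, target, areas) == pytest.approx(16.0)

    def test_cold_target_has_zero_area(self):
        series = np.ones((3, 10))
        series[:, :4] = 0.1  # the target never reaches half the peak
        target = np.zeros(10, dtype=bool)
        target[:4] = True
        assert effective_area(series, target, np.ones(10)) == 0.0

    def test_three_node_half_peak_rule(self):
        series = np.array([[1.0, 0.6, 0.4]])
        target = np.array([True, True, True])
        assert effective_area(series, target, np.ones(3)) == pytest.approx(2.0)

    def test_monotone_nonincreasing_in_fraction(self):
        series = np.abs(series_pair(6, n_nodes=50))
        target = np.ones(50, dtype=bool)
        areas = np.ones(50)
        values = [effective_area(series, target, areas, frac=f) for f in (0.2, 0.5, 0.8)]
        assert values[0] >= values[1] >= values[2]
        assert values[0] <= areas.sum()

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            effective_area(np.zeros((2, 0)), np.zeros(0, dtype=bool), np.zeros(0))


class TestFullPipeline:
    def test_zero_lag_self_comparison(self, sheet, basis):
        table = analyze_montage(sheet, basis, phase_lags=np.array([0.0]), n_steps=8)
        by_metric = table.set_index(["metric", "region_set"])["value"]
        for region in ("M1s", "surrounding"):
            assert by_metric["rdm", region] == pytest.approx(0.0, abs=1e-12)
            assert by_metric["dotp", region] == pytest.approx(1.0, abs=1e-12)
            assert by_metric["delta_dotp", region] == pytest.approx(0.0, abs=1e-12)

    def test_phase_symmetry_of_comparison_metrics(self, sheet):
        # lag phi and 2*pi - phi differ only by time reversal of the cycle
        from dstacs.metrics import dotp as dotp_fn, rdm as rdm_fn

        times = make_time_grid(24, 20.0)
        for seed in range(20):
            b = random_basis(sheet, 200 + seed)
            s0 = normal_component(superpose(b, 0.0, times).vectors, sheet.normals)
            phi = float(np.random.default_rng(seed).uniform(0.1, np.pi - 0.1))
            sa = normal_component(superpose(b, phi, times).vectors, sheet.normals)
            sb = normal_component(superpose(b, 2 * np.pi - phi, times).vectors, sheet.normals)
            assert rdm_fn(s0, sa) == pytest.approx(rdm_fn(s0, sb), abs=1e-9)
            assert dotp_fn(s0, sa) == pytest.approx(dotp_fn(s0, sb), abs=1e-9)

    def test_all_families_reported_for_all_lags(self, sheet, basis):
        lags = default_phase_lags()
        table = analyze_montage(sheet, basis, phase_lags=lags)
        for metric, n_regions in [
            ("peak_magnitude", 2), ("peak_normal", 2), ("rdm", 2),
            ("dotp", 2), ("delta_dotp", 2), ("effective_area", 2),
        ]:
            sub = table[table["metric"] == metric]
            assert len(sub) == len(lags) * n_regions
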