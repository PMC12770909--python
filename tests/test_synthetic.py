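import numpy as np
import pytest

from dstacs.metrics import analyze_cohort, analyze_montage
from dstacs.stats import cv_by_montage
from dstacs.synthetic import (
    SyntheticCohort,
    SyntheticMontageSpec,
    default_montages,
    default_site_centres,
    make_basis_fields,
    make_cohort,
    make_sphere_sheet,
)


class TestSphereSheet:
    def test_total_area_matches_analytic_sphere(self, sheet):
        assert np.isclose(sheet.node_areas.sum(), 4 * np.pi * 80.0**2, rtol=1e-2)

    def test_labels_partition_without_overlap(self, sheet):
        m1 = sheet.nodes_in("M1_left", "M1_right")
        surr = sheet.nodes_in("surrounding")
        assert not (m1 & surr).any()
        assert m1.sum() > 5 and surr.sum() > m1.sum()

    def test_antipodal_sites_get_equal_caps(self):
        c1 = np.array([0.0, 0.0, 1.0])
        c2 = np.array([0.0, 0.0, -1.0])
        spec = SyntheticMontageSpec("sym", site_centres=(c1, c2))
        s = make_sphere_sheet(subdivisions=3, spec=spec)
        assert s.nodes_in("M1_right").sum() == s.nodes_in("M1_left").sum()

    def test_too_close_sites_rejected(self):
        c1, _ = default_site_centres()
        spec = SyntheticMontageSpec("bad", site_centres=(c1, c1 + 1e-9))
        with pytest.raises(ValueError, match="too close"):
            make_sphere_sheet(subdivisions=2, spec=spec)

    def test_mesh_is_closed_manifold(self, sheet):
        # every edge is shared by exactly two triangles
        edges = np.vstack([
            sheet.triangles[:, [0, 1]], sheet.triangles[:, [1, 2]],
            sheet.triangles[:, [2, 0]],
        ])
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert (counts == 2).all()


class TestBasisFields:
    def test_separated_mode_supports_are_disjoint(self, sheet, separated_basis):
        site1 = np.abs(separated_basis.e_r1 - separated_basis.e_c1).sum(axis=1) > 0
        site2 = np.abs(separated_basis.e_r2).sum(axis=1) > 0
        assert not (site1 & site2).any()
        assert site1.any() and site2.any()

    def test_construction_is_deterministic(self, sheet):
        spec = default_montages()[2]
        b1 = make_basis_fields(sheet, spec)
        b2 = make_basis_fields(sheet, spec)
        assert np.array_equal(b1.e_r1, b2.e_r1)
        assert np.array_equal(b1.e_c1, b2.e_c1)
        assert np.array_equal(b1.e_r2, b2.e_r2)

    def test_central_lobe_points_inward(self, sheet, basis):
        # the central electrode polarity: the site-1 combined pattern is
        # inward (negative normal component) at the M1_right cap centre
        comp = np.einsum("ij,ij->i", basis.site1_pattern, sheet.normals)
        cap = sheet.nodes_in("M1_right")
        assert comp[cap].min() < 0
        assert np.isfinite(comp).all()

    def test_amplitude_ratio_sets_site_power(self, sheet):
        from dataclasses import replace

        spec = replace(default_montages()[0], amplitude_ratio=4.0)
        b = make_basis_fields(sheet, spec)
        p1 = np.einsum("ij,ij->", b.e_r1 - b.e_c1, b.e_r1 - b.e_c1)
        p2 = np.einsum("ij,ij->", b.e_r2, b.e_r2)
        assert p2 / p1 == pytest.approx(4.0, rel=1e-9)

    def test_overlap_widens_fields_and_raises_rdm(self, sheet):
        # the central qualitative effect: more inter-site overlap means a
        # larger field redistribution at intermediate phase lags
        from dataclasses import replace

        lags = np.array([0.0, np.pi / 2])
        rdm_at = {}
        for ov in (0.0, 0.3):
            spec = replace(default_montages()[0], overlap=ov)
            table = analyze_montage(sheet, make_basis_fields(sheet, spec), phase_lags=lags)
            row = table[(table["metric"] == "rdm") & (table["phase_lag"] > 0)]
            rdm_at[ov] = row.set_index("region_set")["value"]
        assert rdm_at[0.3]["surrounding"] > rdm_at[0.0]["surrounding"]
        assert rdm_at[0.3]["M1s"] > rdm_at[0.0]["M1s"]


class TestCohort:
    def test_cohort_is_reproducible_and_distinct(self):
        specs = default_montages()[:2]
        cohort = SyntheticCohort(n_individuals=3, seed=1)
        c1 = make_cohort(specs, cohort, subdivisions=2)
        c2 = make_cohort(specs, cohort, subdivisions=2)
        assert len(c1) == 3
        for a, b in zip(c1, c2):
            assert np.array_equal(
                a.basis_by_montage["3x1a"].e_r2, b.basis_by_montage["3x1a"].e_r2
            )
        assert not np.array_equal(
            c1[0].basis_by_montage["3x1a"].e_r2, c1[1].basis_by_montage["3x1a"].e_r2
        )

    def test_zero_jitter_gives_zero_variability(self):
        specs = default_montages()[:1]
        cohort = SyntheticCohort(n_individuals=4, seed=2, site_jitter_sigma=0.0,
                                 amplitude_sigma=0.0)
        individuals = make_cohort(specs, cohort, subdivisions=3)
        table = analyze_cohort(individuals, n_steps=8)
        cv = cv_by_montage(table, "peak_magnitude", "M1s")
        assert cv["3x1a"] == pytest.approx(0.0, abs=1e-9)

    def test_jitter_produces_interindividual_variability(self):
        specs = default_montages()[:1]
        cohort = SyntheticCohort(n_individuals=4, seed=3)
        individuals = make_cohort(specs, cohort, subdivisions=3)
        table = analyze_cohort(individuals, n_steps=8)
        assert cv_by_montage(table, "peak_magnitude", "M1s")["3x1a"] > 1.0
        nonzero_lags = table[table["phase_lag"] > 0]
        assert cv_by_montage(nonzero_lags, "delta_dotp", "M1s")["3x1a"] > 0.0
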