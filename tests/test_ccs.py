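"""Projection-approximation CCS: analytic cases, oracle agreement, invariants."""

import numpy as np
import pytest

from abgas.ccs import (
    CCS_SCALE,
    CCSResult,
    CollisionRadiiTable,
    ccs_trajectory,
    final_window_stats,
    pa_to_ccs,
    projection_area,
)
from abgas.structure import AtomRecord, Structure

from conftest import random_cluster


def beads(coords, element="C"):
    coords = np.atleast_2d(coords)
    return Structure.from_records(
        [
            AtomRecord(i + 1, "X", element, "BEA", i + 1, "A", tuple(c))
            for i, c in enumerate(coords)
        ]
    )


class TestAnalyticCases:
    def test_single_sphere_exact_for_any_orientation_count(self):
        radii = CollisionRadiiTable({"C": 2.0}, probe_radius=1.0)
        for n in (1, 7, 300):
            r = projection_area(beads([(0.0, 0.0, 0.0)]), radii, n_orientations=n)
            assert r.pa_area == pytest.approx(np.pi * 9.0, abs=1e-12)
            assert r.ccs == pytest.approx(1.14 * np.pi * 9.0, abs=1e-12)
            assert r.mc_standard_error == 0.0

    def test_two_distant_spheres_additive(self):
        radii = CollisionRadiiTable({"C": 2.0}, probe_radius=1.0)
        r = projection_area(
            beads([(0.0, 0.0, 0.0), (100.0, 0.0, 0.0)]), radii,
            n_orientations=200, seed=5,
        )
        expected = 2 * np.pi * 9.0
        assert r.pa_area == pytest.approx(expected, rel=0.02)

    def test_fully_occluded_atom_adds_nothing(self):
        radii = CollisionRadiiTable({"C": 2.0, "H": 0.2}, probe_radius=0.0)
        lone = projection_area(beads([(0.0, 0.0, 0.0)]), radii, n_orientations=50, seed=2)
        buried = projection_area(
            beads([(0.0, 0.0, 0.0)]).from_records(
                [
                    AtomRecord(1, "X", "C", "BEA", 1, "A", (0.0, 0.0, 0.0)),
                    AtomRecord(2, "X", "H", "BEA", 2, "A", (0.5, 0.0, 0.0)),
                ]
            ),
            radii, n_orientations=50, seed=2,
        )
        assert buried.pa_area == pytest.approx(lone.pa_area, rel=0.02)


class TestScaleConvention:
    def test_ccs_is_exactly_1_14_times_pa(self, rng, std_radii):
        for seed in range(5):
            s = random_cluster(np.random.default_rng(seed), n=20)
            r = projection_area(s, n_orientations=10, seed=seed)
            assert r.ccs == 1.14 * r.pa_area  # bitwise, not approximate

    @pytest.mark.parametrize(
        "pa,expected", [(100.0, 114.0), (0.0, 0.0), (8361.4, 9532.0)]
    )
    def test_pa_to_ccs_values(self, pa, expected):
        assert pa_to_ccs(pa) == pytest.approx(expected, rel=1e-3)

    def test_negative_pa_rejected(self):
        with pytest.raises(ValueError):
            pa_to_ccs(-1.0)

    def test_result_scale_invariant_enforced(self):
        with pytest.raises(ValueError):
            CCSResult(pa_area=100.0, ccs=100.0, mc_standard_error=0.0, n_orientations=1, seed=0)


class TestOracleAgreement:
    def test_mc_within_one_percent_of_grid_on_seeded_fixtures(self):
        for seed in range(20):
            s = random_cluster(np.random.default_rng(seed), n=50)
            mc = projection_area(s, n_orientations=120, seed=seed, n_points=20000)
            grid = projection_area(
                s, n_orientations=120, sampler="grid", seed=seed, grid_cell=0.2
            )
            assert mc.pa_area == pytest.approx(grid.pa_area, rel=0.01)

    def test_mc_within_three_standard_errors_of_grid(self):
        s = random_cluster(np.random.default_rng(42), n=50)
        mc = projection_area(s, n_orientations=300, seed=7)
        grid = projection_area(s, n_orientations=300, sampler="grid", seed=7, grid_cell=0.2)
        assert abs(mc.pa_area - grid.pa_area) <= 3 * max(mc.mc_standard_error, 1e-9)


class TestInvariants:
    def test_rotation_invariance_within_mc_error(self, rng):
        s = random_cluster(rng, n=40)
        r0 = projection_area(s, n_orientations=200, seed=1)
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        r1 = projection_area(s.with_coord(s.coord @ rot.T), n_orientations=200, seed=2)
        tol = 2 * np.hypot(r0.mc_standard_error, r1.mc_standard_error)
        assert abs(r0.pa_area - r1.pa_area) <= max(tol, 0.01 * r0.pa_area)

    def test_adding_non_occluded_atom_increases_pa(self, rng):
        s = random_cluster(rng, n=30)
        coords = np.vstack([s.coord, [200.0, 0.0, 0.0]])
        bigger = beads(coords)
        r_small = projection_area(s, n_orientations=100, sampler="grid")
        r_big = projection_area(bigger, n_orientations=100, sampler="grid")
        assert r_big.pa_area > r_small.pa_area

    def test_pa_at_least_largest_disk(self, rng, std_radii):
        s = random_cluster(rng, n=25)
        r = projection_area(s, n_orientations=50, seed=3)
        disk = np.pi * (1.7 + 1.0) ** 2
        assert r.pa_area >= disk * 0.99

    def test_deterministic_for_fixed_seed(self, rng):
        s = random_cluster(rng, n=30)
        a = projection_area(s, n_orientations=40, seed=9)
        b = projection_area(s, n_orientations=40, seed=9)
        assert a == b


class TestErrors:
    def test_unknown_element_listed(self):
        s = beads([(0, 0, 0)], element="ZZ")
        with pytest.raises(KeyError, match="ZZ"):
            projection_area(s)

    def test_bad_orientation_count(self):
        with pytest.raises(ValueError):
            projection_area(beads([(0, 0, 0)]), n_orientations=0)

    def test_bad_sampler_name(self):
        with pytest.raises(ValueError, match="sampler"):
            projection_area(beads([(0, 0, 0)]), sampler="quantum")


class TestTrajectory:
    def test_single_frame(self, rng):
        s = random_cluster(rng, n=10)
        series = ccs_trajectory([s], n_orientations=20)
        assert len(series) == 1
        final, window = final_window_stats(series)
        assert final == series[0].ccs
        assert window == 0.0

    def test_identical_frames_identical_ccs(self, rng):
        s = random_cluster(rng, n=10)
        series = ccs_trajectory([s] * 7, n_orientations=20, seed=4)
        assert all(r == series[0] for r in series)

    def test_stride(self, rng):
        s = random_cluster(rng, n=10)
        series = ccs_trajectory([s] * 10, stride=3, n_orientations=5)
        assert len(series) == 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ccs_trajectory([])


class TestRadiiTable:
    def test_with_element_extends(self):
        t = CollisionRadiiTable.default().with_element("X", 1.9)
        assert t.radii["X"] == 1.9
        assert t.radii["C"] == 1.7

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ValueError):
            CollisionRadiiTable({"C": 0.0})
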