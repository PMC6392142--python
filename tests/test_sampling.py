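"""Hinge kinematics, clash detection and RRT ensemble properties."""

import numpy as np
import pytest

from abgas.sampling import (
    RRTParams,
    apply_dihedrals,
    clash_check,
    sample_ensemble,
    select_compact,
    summarise_ensemble,
    wrap_angles,
)
from abgas.sampling import _clash_groups, _exempt
from abgas.structure import AtomRecord, Structure

FAST_CCS = {"ccs_orientations": 20, "ccs_points": 800}


def rotation_about_axis(p, q, theta_deg):
    """Independent Rodrigues-rotation oracle about the axis q -> p."""
    axis = (p - q) / np.linalg.norm(p - q)
    t = np.deg2rad(theta_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)

    def apply(x):
        return (x - q) @ R.T + q

    return apply


class TestKinematics:
    def test_zero_change_vector_is_identity(self, std_antibody):
        s, topo = std_antibody
        out = apply_dihedrals(s, topo, np.zeros(2 * topo.n_flexible()))
        assert np.array_equal(out.coord, s.coord)

    def test_rotation_inverse_restores_coordinates(self, std_antibody):
        s, topo = std_antibody
        rng = np.random.default_rng(3)
        deltas = rng.uniform(-120, 120, 2 * topo.n_flexible())
        back = apply_dihedrals(apply_dihedrals(s, topo, deltas), topo, -deltas)
        assert np.abs(back.coord - s.coord).max() < 1e-9

    def test_fc_core_never_moves(self, std_antibody):
        s, topo = std_antibody
        deltas = np.full(2 * topo.n_flexible(), 45.0)
        out = apply_dihedrals(s, topo, deltas)
        fc = s.residue_mask(topo.rigid_bodies["Fc_core"])
        assert np.array_equal(out.coord[fc], s.coord[fc])

    def test_rigid_bodies_preserved_exactly(self, std_antibody):
        s, topo = std_antibody
        deltas = np.random.default_rng(11).uniform(-150, 150, 2 * topo.n_flexible())
        out = apply_dihedrals(s, topo, deltas)
        for body in ("Fab1", "Fab2"):
            m = s.residue_mask(topo.rigid_bodies[body])
            d0 = np.linalg.norm(s.coord[m][:, None] - s.coord[m][None, :], axis=-1)
            d1 = np.linalg.norm(out.coord[m][:, None] - out.coord[m][None, :], axis=-1)
            assert np.abs(d1 - d0).max() < 1e-9

    def test_single_psi_flip_matches_rotation_oracle(self, std_antibody):
        """Flipping one torsion must move the Fab exactly as an explicit
        Rodrigues rotation about that bond."""
        s, topo = std_antibody
        n_t = 2 * topo.n_flexible()
        # last hinge residue of arm1 = hinge-most = last (phi, psi) pair of arm1
        k_psi = 2 * len(topo.flexible_residues["arm1"]) - 1
        chain, res = topo.flexible_residues["arm1"][-1]
        deltas = np.zeros(n_t)
        deltas[k_psi] = 180.0
        out = apply_dihedrals(s, topo, deltas)

        ca = np.flatnonzero((s.chain_id == chain) & (s.res_id == res) & (s.name == "CA"))[0]
        c = np.flatnonzero((s.chain_id == chain) & (s.res_id == res) & (s.name == "C"))[0]
        oracle = rotation_about_axis(s.coord[ca], s.coord[c], 180.0)
        fab = s.residue_mask(topo.rigid_bodies["Fab1"])
        assert np.abs(out.coord[fab] - oracle(s.coord[fab])).max() < 1e-9

    def test_mismatched_vector_length_rejected(self, std_antibody):
        s, topo = std_antibody
        with pytest.raises(ValueError):
            apply_dihedrals(s, topo, np.zeros(3))

    def test_wrap_angles(self):
        assert wrap_angles(np.array([181.0]))[0] == pytest.approx(-179.0)
        assert wrap_angles(np.array([-180.0]))[0] == pytest.approx(180.0)
        assert wrap_angles(np.array([540.0]))[0] == pytest.approx(180.0)


class TestClashCheck:
    def test_distant_bodies_clash_free(self, std_antibody, std_radii):
        s, topo = std_antibody
        assert clash_check(s, std_radii, 0.7, topo) is False

    def test_coincident_atoms_from_different_bodies_clash(self, std_antibody, std_radii):
        s, topo = std_antibody
        coord = s.coord.copy()
        fab = np.flatnonzero(s.residue_mask(topo.rigid_bodies["Fab1"]))
        fc = np.flatnonzero(s.residue_mask(topo.rigid_bodies["Fc_core"]))
        coord[fab[0]] = coord[fc[-1]]
        assert clash_check(s.with_coord(coord), std_radii, 0.7, topo) is True

    def test_matches_all_pairs_oracle_across_poses(self, std_antibody, std_radii):
        """k-d-tree clash verdicts must equal the brute-force all-pairs scan
        on 50 seeded random poses."""
        s, topo = std_antibody
        r = std_radii.element_radii(s.element)
        group = _clash_groups(s, topo)
        rng = np.random.default_rng(17)
        n_t = 2 * topo.n_flexible()
        verdicts = []
        for _ in range(50):
            pose = apply_dihedrals(s, topo, rng.uniform(-180, 180, n_t))
            brute = False
            coord = pose.coord
            for i in range(len(s)):
                d = np.linalg.norm(coord[i + 1 :] - coord[i], axis=1)
                for off in np.flatnonzero(d < 0.7 * (r[i] + r[i + 1 :])):
                    j = i + 1 + int(off)
                    if not _exempt(s, topo, group, i, j):
                        brute = True
                        break
                if brute:
                    break
            fast = clash_check(pose, std_radii, 0.7, topo)
            assert fast == brute
            verdicts.append(brute)
        assert any(verdicts) and not all(verdicts)  # both outcomes exercised


class TestRRT:
    def test_seeded_determinism(self, std_antibody, std_radii):
        s, topo = std_antibody
        params = RRTParams(n_samples=40, seed=7, **FAST_CCS)
        a = sample_ensemble(s, topo, params, std_radii)
        b = sample_ensemble(s, topo, params, std_radii)
        assert len(a) == len(b) == 40
        assert all(
            np.array_equal(x.structure.coord, y.structure.coord) and x.ccs == y.ccs
            for x, y in zip(a, b)
        )

    def test_no_accepted_conformer_clashes(self, std_antibody, std_radii):
        s, topo = std_antibody
        ensemble = sample_ensemble(
            s, topo, RRTParams(n_samples=60, seed=2, **FAST_CCS), std_radii
        )
        assert not any(clash_check(c.structure, std_radii, 0.7, topo) for c in ensemble)

    def test_rigid_body_rmsd_below_tolerance(self, std_antibody, std_radii):
        s, topo = std_antibody
        ensemble = sample_ensemble(
            s, topo, RRTParams(n_samples=30, seed=4, **FAST_CCS), std_radii
        )
        for body in ("Fab1", "Fab2", "Fc_core"):
            m = s.residue_mask(topo.rigid_bodies[body])
            ref = s.coord[m]
            for c in ensemble[1:]:
                x = c.structure.coord[m]
                # optimal superposition via Kabsch
                rc, xc = ref - ref.mean(0), x - x.mean(0)
                u, sv, vt = np.linalg.svd(xc.T @ rc)
                d = np.sign(np.linalg.det(u @ vt))
                R = u @ np.diag([1, 1, d]) @ vt
                rmsd = np.sqrt(np.mean(np.sum((xc @ R - rc) ** 2, axis=1)))
                assert rmsd < 1e-6

    def test_min_ccs_non_increasing_with_more_samples(self, std_antibody, std_radii):
        s, topo = std_antibody
        params_small = RRTParams(n_samples=30, seed=9, **FAST_CCS)
        params_large = RRTParams(n_samples=120, seed=9, **FAST_CCS)
        small = sample_ensemble(s, topo, params_small, std_radii)
        large = sample_ensemble(s, topo, params_large, std_radii)
        # same seed: the first 30 accepted nodes coincide, so min can only drop
        assert min(c.ccs.ccs for c in large) <= min(c.ccs.ccs for c in small)


class TestSelectCompact:
    def _fake_ensemble(self, ccs_values, coords):
        from abgas.ccs import CCSResult

        out = []
        for v, xyz in zip(ccs_values, coords):
            s = Structure.from_records(
                [AtomRecord(1, "CA", "C", "GLY", 1, "A", tuple(xyz))]
            )
            out.append(
                type("C", (), {})()
            )
            out[-1].ccs = CCSResult(v / 1.14, v, 0.0, 1, 0)
            out[-1].structure = s
            out[-1].dihedrals = np.zeros(1)
            out[-1].fab_centroids = np.zeros((2, 3))
        return out

    def test_mutually_diverse_takes_lowest_k(self):
        coords = [(i * 100.0, 0, 0) for i in range(5)]
        ens = self._fake_ensemble([5, 4, 3, 2, 1], coords)
        picked = select_compact(ens, 3, diversity_rmsd=5.0)
        assert sorted(c.ccs.ccs for c in picked) == [1, 2, 3]

    def test_k1_returns_global_minimum(self):
        ens = self._fake_ensemble([5, 1, 3], [(0, 0, 0), (100, 0, 0), (200, 0, 0)])
        assert select_compact(ens, 1)[0].ccs.ccs == 1

    def test_near_duplicate_skipped_for_diversity(self):
        # two lowest nearly coincide (RMSD 0.1): pick ranks 1 and 3
        coords = [(0.0, 0, 0), (0.1, 0, 0), (100.0, 0, 0)]
        ens = self._fake_ensemble([1, 2, 3], coords)
        picked = select_compact(ens, 2, diversity_rmsd=5.0)
        assert [c.ccs.ccs for c in picked] == [1, 3]

    def test_relaxes_with_warning_when_exhausted(self):
        coords = [(0.0, 0, 0), (0.1, 0, 0)]
        ens = self._fake_ensemble([1, 2], coords)
        with pytest.warns(UserWarning, match="diversity"):
            picked = select_compact(ens, 2, diversity_rmsd=5.0)
        assert [c.ccs.ccs for c in picked] == [1, 2]

    def test_k_larger_than_ensemble_rejected(self):
        ens = self._fake_ensemble([1], [(0, 0, 0)])
        with pytest.raises(ValueError):
            select_compact(ens, 2)


class TestEnsembleSummary:
    def test_single_conformer_degenerate(self, std_antibody, std_radii):
        s, topo = std_antibody
        ens = sample_ensemble(s, topo, RRTParams(n_samples=1, seed=0, **FAST_CCS), std_radii)
        summary = summarise_ensemble(ens)
        assert summary.n == 1
        assert summary.delta_ccs == 0.0
        assert summary.overlap_fraction in (0.0, 1.0)

    def test_longer_hinge_larger_delta_and_overlap(self):
        """IgG3-like hinge (12 flexible residues) explores a wider CCS range
        and its Fab clouds share more space than an IgG1-like hinge (5)."""
        from abgas.fixtures import SyntheticAntibodyParams, make_synthetic_antibody

        summaries = {}
        for f in (5, 12):
            p = SyntheticAntibodyParams(flexible_residues_per_arm=f)
            s, topo = make_synthetic_antibody(p)
            ens = sample_ensemble(
                s, topo, RRTParams(n_samples=250, seed=11, **FAST_CCS), p.radii_table()
            )
            summaries[f] = summarise_ensemble(ens)
        assert summaries[12].delta_ccs > summaries[5].delta_ccs
        assert summaries[12].overlap_fraction > summaries[5].overlap_fraction
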