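"""Structure container, PDB round trips, disulfides and antibody partitioning."""

import numpy as np
import pytest

from abgas.structure import (
    AntibodyTopology,
    AtomRecord,
    DisulfideBond,
    FormatError,
    Structure,
    TopologyError,
    detect_disulfides,
    partition_antibody,
    read_pdb,
    write_pdb,
)


def tiny_structure():
    return Structure.from_records(
        [
            AtomRecord(1, "CA", "C", "GLY", 1, "A", (1.0, 2.0, 3.0)),
            AtomRecord(2, "CA", "C", "GLY", 2, "A", (4.5, -2.25, 0.125)),
            AtomRecord(3, "O", "O", "HOH", 1, "B", (-7.0, 0.0, 9.875), hetero=True),
        ]
    )


class TestPDBRoundTrip:
    def test_write_read_preserves_coordinates(self, tmp_path):
        s = tiny_structure()
        path = tmp_path / "tiny.pdb"
        write_pdb(s, path)
        back = read_pdb(path)
        assert len(back) == 3
        assert np.abs(back.coord - s.coord).max() <= 1e-3
        assert list(back.chain_id) == ["A", "A", "B"]
        assert back.metadata["has_hetatm"]

    def test_round_trip_idempotent(self, tmp_path, std_antibody):
        s, _ = std_antibody
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_pdb(s, p1)
        once = read_pdb(p1)
        write_pdb(once, p2)
        twice = read_pdb(p2)
        assert np.array_equal(once.coord, twice.coord)
        assert np.array_equal(once.res_id, twice.res_id)

    def test_altloc_keeps_a_only(self, tmp_path):
        text = (
            "ATOM      1  CA AGLY A   1       1.000   0.000   0.000  0.50 10.00           C\n"
            "ATOM      2  CA BGLY A   1       2.000   0.000   0.000  0.50 10.00           C\n"
            "ATOM      3  CA  GLY A   2       3.000   0.000   0.000  1.00 10.00           C\n"
        )
        path = tmp_path / "alt.pdb"
        path.write_text(text)
        s = read_pdb(path)
        assert len(s) == 2
        assert s.coord[0, 0] == pytest.approx(1.0)

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(FormatError):
            read_pdb(path)

    def test_long_chain_id_rejected_by_name(self, tmp_path):
        s = tiny_structure()
        s.chain_id = np.array(["AB", "AB", "B"])
        with pytest.raises(ValueError, match="AB"):
            write_pdb(s, tmp_path / "bad.pdb")


class TestStructureInvariants:
    def test_needs_at_least_one_atom(self):
        with pytest.raises(FormatError):
            Structure.from_records([])

    def test_duplicate_serials_rejected(self):
        records = [
            AtomRecord(1, "CA", "C", "GLY", 1, "A", (0, 0, 0)),
            AtomRecord(1, "CA", "C", "GLY", 2, "A", (1, 0, 0)),
        ]
        with pytest.raises(ValueError, match="serial"):
            Structure.from_records(records)

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            Structure.from_records(
                [AtomRecord(1, "CA", "C", "GLY", 1, "A", (np.nan, 0, 0))]
            )


def cys_pair(d, chains=("A", "B"), res=(10, 10)):
    return Structure.from_records(
        [
            AtomRecord(1, "SG", "S", "CYS", res[0], chains[0], (0.0, 0.0, 0.0)),
            AtomRecord(2, "SG", "S", "CYS", res[1], chains[1], (d, 0.0, 0.0)),
        ]
    )


class TestDisulfides:
    def test_bonded_pair_at_canonical_distance(self):
        bonds = detect_disulfides(cys_pair(2.05))
        assert len(bonds) == 1
        assert bonds[0].sg_distance == pytest.approx(2.05)

    def test_distant_pair_not_bonded(self):
        assert detect_disulfides(cys_pair(4.0)) == []

    def test_greedy_pairing_each_sg_used_once(self):
        # three SG in a row at 2.0 A spacing: only the closest pair bonds,
        # the leftover SG must not double-pair
        s = Structure.from_records(
            [
                AtomRecord(1, "SG", "S", "CYS", 1, "A", (0.0, 0.0, 0.0)),
                AtomRecord(2, "SG", "S", "CYS", 2, "A", (1.9, 0.0, 0.0)),
                AtomRecord(3, "SG", "S", "CYS", 3, "A", (4.0, 0.0, 0.0)),
            ]
        )
        bonds = detect_disulfides(s)
        assert len(bonds) == 1
        assert bonds[0].cys_a == ("A", 1) and bonds[0].cys_b == ("A", 2)

    def test_order_invariance(self, std_antibody):
        s, _ = std_antibody
        perm = np.random.default_rng(0).permutation(len(s))
        assert detect_disulfides(s) == detect_disulfides(s.select(perm))

    def test_fixture_has_one_inter_heavy_hinge_bond(self, std_antibody):
        s, _ = std_antibody
        bonds = detect_disulfides(s)
        assert len(bonds) == 1
        assert {bonds[0].cys_a[0], bonds[0].cys_b[0]} == {"A", "B"}


class TestPartition:
    def test_fixture_partition_matches_generator(self, std_antibody):
        s, topo = std_antibody
        derived = partition_antibody(
            s, s.metadata["chain_annotation"], s.metadata["hinge_span"]
        )
        for arm in ("arm1", "arm2"):
            assert derived.flexible_residues[arm] == topo.flexible_residues[arm]
            assert len(derived.flexible_residues[arm]) == 5
        for body in ("Fab1", "Fab2", "Fc_core"):
            assert sorted(derived.rigid_bodies[body]) == sorted(topo.rigid_bodies[body])

    def test_partition_is_complete(self, std_antibody):
        s, _ = std_antibody
        topo = partition_antibody(
            s, s.metadata["chain_annotation"], s.metadata["hinge_span"]
        )
        seen = []
        for body in topo.rigid_bodies.values():
            seen += body
        for arm in topo.flexible_residues.values():
            seen += arm
        seen += topo.unassigned
        keys = [(c, r) for c, r, _ in s.residue_keys()]
        assert sorted(seen) == sorted(set(seen))  # no residue twice
        assert sorted(seen) == sorted(keys)  # every residue somewhere

    def test_zero_length_upper_hinge_is_valid(self, std_antibody):
        s, _ = std_antibody
        # hinge span starting at the disulfide cysteine itself: empty flexible set
        span = s.metadata["hinge_span"]
        cys = span["A"][1]
        topo = partition_antibody(
            s, s.metadata["chain_annotation"], {"A": (cys, cys), "B": (cys, cys)}
        )
        assert topo.flexible_residues["arm1"] == []
        assert topo.flexible_residues["arm2"] == []

    def test_missing_hinge_disulfide_raises(self, std_antibody):
        s, _ = std_antibody
        with pytest.raises(TopologyError, match="disulfide"):
            partition_antibody(
                s, s.metadata["chain_annotation"], {"A": (2, 3), "B": (2, 3)}
            )

    def test_wrong_chain_count_raises(self, std_antibody):
        s, _ = std_antibody
        with pytest.raises(TopologyError, match="heavy"):
            partition_antibody(s, {"A": "heavy", "C": "light"}, s.metadata["hinge_span"])


class TestTopologyType:
    def test_overlapping_rigid_bodies_rejected(self):
        with pytest.raises(TopologyError):
            AntibodyTopology(
                rigid_bodies={"Fab1": [("A", 1)], "Fab2": [("A", 1)], "Fc_core": []},
                flexible_residues={"arm1": [], "arm2": []},
            )

    def test_flexible_inside_rigid_rejected(self):
        with pytest.raises(TopologyError):
            AntibodyTopology(
                rigid_bodies={"Fab1": [("A", 1)], "Fab2": [], "Fc_core": []},
                flexible_residues={"arm1": [("A", 1)], "arm2": []},
            )

    def test_json_round_trip(self, std_antibody):
        _, topo = std_antibody
        back = AntibodyTopology.from_json(topo.to_json())
        assert back.rigid_bodies == topo.rigid_bodies
        assert back.flexible_residues == topo.flexible_residues
        assert back.disulfides == topo.disulfides

    def test_disulfide_endpoints_must_differ(self):
        with pytest.raises(ValueError):
            DisulfideBond(("A", 1), ("A", 1), 2.0)
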