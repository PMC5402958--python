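"""Structure container, PDB I/O, superposition and scalar geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfdyn.errors import (
    DegenerateAlignmentError,
    DomainLookupError,
    EmptyStructureError,
    TopologyError,
)
from tfdyn.structures import (
    DomainMap,
    Transform,
    centroid_distance,
    neutralizing_ion_count,
    pairwise_rmsd,
    radius_of_gyration,
    read_pdb,
    read_pdb_models,
    superpose,
    tf_domain_map,
    write_pdb,
)

from conftest import make_structure, random_rotation, random_structure


MINIMAL_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  LYS A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AGLY A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BGLY A   1       9.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  LYS A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""


class TestPDBIO:
    def test_minimal_three_residue_file(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        s = read_pdb(path)
        assert s.n_nodes == 3
        assert s.residue_number.tolist() == [1, 2, 3]
        assert np.allclose(s.coords[1], [3.8, 0, 0])

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        s = read_pdb(path)
        assert s.n_nodes == 3
        assert np.allclose(s.coords[0], [1.0, 0.0, 0.0])  # altloc A, occ 0.6

    def test_round_trip_preserves_coords_and_metadata(self, tmp_path):
        s = random_structure(400, seed=3, scale=60.0)
        path = tmp_path / "rt.pdb"
        write_pdb(s, path)
        back = read_pdb(path)
        assert back.n_nodes == s.n_nodes
        assert np.allclose(back.coords, s.coords, atol=1e-3)  # PDB precision
        assert np.array_equal(back.residue_number, s.residue_number)
        assert np.array_equal(back.chain_id, s.chain_id)
        assert np.array_equal(back.residue_name, s.residue_name)

    def test_multi_model_write_and_read(self, tmp_path):
        s = random_structure(10, seed=1)
        frames = [s, s.with_coords(s.coords + 1.0)]
        path = tmp_path / "traj.pdb"
        write_pdb(frames, path)
        assert path.read_text().count("MODEL") == 2
        models = read_pdb_models(path)
        assert len(models) == 2
        assert np.allclose(models[1].coords, s.coords + 1.0, atol=1e-3)

    def test_single_node_single_atom_record(self, tmp_path):
        s = make_structure([[1.0, 2.0, 3.0]])
        path = tmp_path / "one.pdb"
        write_pdb(s, path)
        lines = [l for l in path.read_text().splitlines() if l.startswith("ATOM")]
        assert len(lines) == 1

    def test_unreadable_file_raises(self, tmp_path):
        with pytest.raises(Exception):
            read_pdb(tmp_path / "nope.pdb")


class TestStructureInvariants:
    def test_empty_structure_rejected(self):
        with pytest.raises(EmptyStructureError):
            make_structure(np.empty((0, 3)))

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ValueError):
            make_structure([[0, 0, np.nan]])

    def test_duplicate_residue_keys_rejected(self):
        with pytest.raises(ValueError):
            make_structure([[0, 0, 0], [1, 0, 0]], resnums=[1, 1])


class TestRadiusOfGyration:
    def test_single_node_zero(self):
        assert radius_of_gyration(make_structure([[5, 5, 5]])) == 0.0

    def test_two_nodes_two_angstrom_apart(self):
        s = make_structure([[0, 0, 0], [2, 0, 0]])
        assert radius_of_gyration(s) == pytest.approx(1.0)

    @given(st.integers(min_value=0, max_value=2 ** 31))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_definition(self, seed):
        s = random_structure(10, seed=seed)
        com = s.coords.mean(axis=0)
        expected = np.sqrt(sum(np.sum((r - com) ** 2) for r in s.coords) / 10)
        assert radius_of_gyration(s) == pytest.approx(expected, abs=1e-10)

    @given(st.integers(min_value=0, max_value=2 ** 31))
    @settings(max_examples=25, deadline=None)
    def test_rigid_transform_invariance(self, seed):
        s = random_structure(25, seed=seed)
        rot = random_rotation(seed)
        moved = s.with_coords(s.coords @ rot.T + np.array([3.0, -7.0, 1.0]))
        assert radius_of_gyration(moved) == pytest.approx(
            radius_of_gyration(s), abs=1e-8)


class TestCentroidDistance:
    def _two_cluster(self):
        coords = np.vstack([np.random.default_rng(0).normal(0, 1, (10, 3)),
                            np.random.default_rng(1).normal(0, 1, (10, 3))])
        coords[:10] -= coords[:10].mean(axis=0)
        coords[10:] -= coords[10:].mean(axis=0)
        coords[10:] += [10.0, 0.0, 0.0]
        s = make_structure(coords)
        dm = DomainMap()
        dm.add("a", "A", 1, 10)
        dm.add("b", "A", 11, 20)
        return s, dm

    def test_identity_is_zero(self):
        s, dm = self._two_cluster()
        assert centroid_distance(s, dm, "a", "a") == 0.0

    def test_constructed_ten_angstrom(self):
        s, dm = self._two_cluster()
        assert centroid_distance(s, dm, "a", "b") == pytest.approx(10.0, abs=1e-10)

    def test_unknown_name_raises(self):
        s, dm = self._two_cluster()
        with pytest.raises(DomainLookupError):
            centroid_distance(s, dm, "a", "zz")

    def test_matches_brute_force(self):
        s, dm = self._two_cluster()
        ca = np.mean([s.coords[i] for i in range(10)], axis=0)
        cb = np.mean([s.coords[i] for i in range(10, 20)], axis=0)
        assert centroid_distance(s, dm, "a", "b") == pytest.approx(
            float(np.linalg.norm(ca - cb)), abs=1e-10)


class TestSuperpose:
    def test_self_alignment_identity(self):
        s = random_structure(20, seed=5)
        t, rmsd = superpose(s, s)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-8)
        assert np.allclose(t.translation, 0.0, atol=1e-8)

    def test_recovers_known_rigid_motion(self):
        s = random_structure(30, seed=6)
        rot = random_rotation(6)
        trans = np.array([4.0, -2.0, 9.0])
        moved = s.with_coords(s.coords @ rot.T + trans)
        t, rmsd = superpose(moved, s)
        assert rmsd < 1e-8
        # the recovered transform inverts the applied motion
        assert np.allclose(t.rotation, rot.T, atol=1e-8)
        assert np.allclose(t.apply(moved.coords), s.coords, atol=1e-8)

    def test_rmsd_matches_exhaustive_formula(self):
        s = random_structure(40, seed=7)
        rng = np.random.default_rng(8)
        perturbed = s.with_coords(s.coords + rng.normal(0, 0.8, s.coords.shape))
        t, rmsd = superpose(perturbed, s)
        moved = t.apply(perturbed.coords)
        expected = np.sqrt(np.mean([np.sum((moved[i] - s.coords[i]) ** 2)
                                    for i in range(40)]))
        assert rmsd == pytest.approx(expected, abs=1e-10)

    def test_rmsd_symmetric(self):
        a = random_structure(25, seed=9)
        b = a.with_coords(a.coords + np.random.default_rng(10).normal(0, 1, (25, 3)))
        _, r_ab = superpose(a, b)
        _, r_ba = superpose(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-8)

    def test_no_reflection(self):
        s = random_structure(15, seed=11)
        mirrored = s.with_coords(s.coords * np.array([-1.0, 1.0, 1.0]))
        t, _ = superpose(mirrored, s)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_collinear_raises(self):
        coords = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        s = make_structure(coords)
        with pytest.raises(DegenerateAlignmentError):
            superpose(s, s.with_coords(coords + 1.0))

    def test_too_few_pairs_raises(self):
        a = make_structure([[0, 0, 0], [1, 1, 0]], resnums=[1, 2])
        b = make_structure([[0, 0, 0], [1, 1, 0]], resnums=[5, 6])
        with pytest.raises(DegenerateAlignmentError):
            superpose(a, b)


class TestPairwiseRMSD:
    def test_identity_zero(self):
        s = random_structure(20, seed=12)
        assert pairwise_rmsd(s, s) == pytest.approx(0.0, abs=1e-10)
        assert pairwise_rmsd(s, s, align=False) == 0.0

    def test_rigid_copy_zero_when_aligned(self):
        s = random_structure(20, seed=13)
        rot = random_rotation(13)
        moved = s.with_coords(s.coords @ rot.T + 5.0)
        assert pairwise_rmsd(s, moved, align=True) == pytest.approx(0.0, abs=1e-8)
        assert pairwise_rmsd(s, moved, align=False) > 1.0

    @given(st.integers(min_value=0, max_value=2 ** 31))
    @settings(max_examples=20, deadline=None)
    def test_aligned_never_exceeds_unaligned(self, seed):
        rng = np.random.default_rng(seed)
        a = random_structure(15, seed=seed)
        b = a.with_coords(a.coords + rng.normal(0, 2, (15, 3)))
        assert pairwise_rmsd(a, b, True) <= pairwise_rmsd(a, b, False) + 1e-12

    def test_topology_mismatch_raises(self):
        with pytest.raises(TopologyError):
            pairwise_rmsd(random_structure(10), random_structure(12))


class TestTransform:
    def test_inverse_recovers_input(self):
        rot = random_rotation(2)
        t = Transform(rot, np.array([1.0, 2.0, 3.0]))
        pts = np.random.default_rng(3).normal(0, 5, (10, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-8)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            Transform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestDomainMap:
    def test_tf_map_union_covers_1_to_432(self):
        dm = tf_domain_map()
        covered = dm.covered_residues(["BD", "CD", "HD"])
        assert covered == {("A", r) for r in range(1, 433)}

    def test_arms_inside_core(self):
        dm = tf_domain_map()
        cd = dm.covered_residues(["CD"])
        assert dm.covered_residues(["Arm1"]) <= cd
        assert dm.covered_residues(["Arm2"]) <= cd

    def test_file_round_trip(self, tmp_path):
        dm = tf_domain_map()
        path = tmp_path / "domains.txt"
        dm.to_file(path)
        back = DomainMap.from_file(path)
        assert back.ranges == dm.ranges

    def test_missing_residues_reported(self):
        s = random_structure(50)  # residues 1..50 only
        dm = tf_domain_map()
        report = dm.missing_residues(s)
        assert ("A", 200) in report["HD"]
        assert "BD" in report and len(report["BD"]) == 110 - 50


class TestNeutralizingIons:
    @pytest.mark.parametrize("names, count, ion", [
        (["LYS", "LYS", "ASP", "ASP"], 0, ""),
        (["ASP", "ASP", "GLU"], 3, "Na+"),
        (["ARG", "LYS", "HIS"], 2, "Cl-"),
        (["HIP", "GLY", "ASH"], 0, ""),      # +1 and -1 variants cancel
    ])
    def test_charge_bookkeeping(self, names, count, ion):
        s = make_structure(np.arange(len(names) * 3, dtype=float).reshape(-1, 3) * 5,
                           names=names)
        report = neutralizing_ion_count(s)
        assert report.count == count
        assert report.ion == ion

    def test_unknown_residues_counted_neutral_and_listed(self):
        s = make_structure([[0, 0, 0], [5, 0, 0]], names=["XYZ", "GLU"])
        report = neutralizing_ion_count(s)
        assert report.count == 1
        assert report.unknown_residues == ["XYZ"]

    def test_nucleotide_nodes_ignored(self):
        from tfdyn.structures import NUCLEOTIDE
        s = make_structure([[0, 0, 0], [5, 0, 0]], kind=NUCLEOTIDE,
                           names=["A", "G"])
        assert neutralizing_ion_count(s).count == 0
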