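"""PDB coordinate model and geometry primitives."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from coldzyme import (
    Atom,
    Residue,
    apply_rigid_transform,
    distance,
    make_random_structure,
    read_pdb,
    ring_centroid_normal,
    structure_sequence,
    write_pdb,
)

TWO_RESIDUE_PDB = "\n".join(
    [
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C",
        "ATOM      3  CB AALA A   1       1.000   1.000   0.000  0.40  0.00           C",
        "ATOM      4  CB BALA A   1       1.500   1.000   0.000  0.60  0.00           C",
        "ATOM      5  C   ALA A   1       2.000  -1.100   0.000  1.00  0.00           C",
        "ATOM      6  O   ALA A   1       1.900  -2.300   0.000  1.00  0.00           O",
        "ATOM      7  N   GLY A   2       3.800   0.000   0.000  1.00  0.00           N",
        "ATOM      8  CA  GLY A   2       5.258   0.000   0.000  1.00  0.00           C",
        "ATOM      9  C   GLY A   2       5.800  -1.100   0.000  1.00  0.00           C",
        "ATOM     10  O   GLY A   2       5.700  -2.300   0.000  1.00  0.00           O",
        "HETATM   11  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O",
        "TER",
        "END",
    ]
)


@pytest.fixture
def two_residue_pdb(tmp_path):
    path = tmp_path / "fixture.pdb"
    path.write_text(TWO_RESIDUE_PDB + "\n")
    return path


class TestReadPdb:
    def test_two_residue_fixture(self, two_residue_pdb):
        s = read_pdb(two_residue_pdb)
        assert s.n_residues() == 2  # water dropped
        seq, numbers = structure_sequence(s)
        assert seq == "AG"
        assert numbers == [1, 2]

    def test_altloc_keeps_highest_occupancy(self, two_residue_pdb):
        s = read_pdb(two_residue_pdb)
        ala = s.chains["A"][0]
        cbs = [a for a in ala.atoms if a.name == "CB"]
        assert len(cbs) == 1
        assert cbs[0].coords[0] == pytest.approx(1.5)  # altloc B, occupancy 0.6

    def test_altloc_tie_prefers_a(self, tmp_path):
        text = TWO_RESIDUE_PDB.replace("0.40  0.00", "0.50  0.00").replace(
            "0.60  0.00", "0.50  0.00"
        )
        path = tmp_path / "tie.pdb"
        path.write_text(text + "\n")
        cb = [a for a in read_pdb(path).chains["A"][0].atoms if a.name == "CB"][0]
        assert cb.coords[0] == pytest.approx(1.0)

    def test_unparseable_atom_line_raises(self, tmp_path):
        bad = TWO_RESIDUE_PDB.replace("   1.458", "   abcde")
        path = tmp_path / "bad.pdb"
        path.write_text(bad + "\n")
        with pytest.raises(ValueError, match="unparseable"):
            read_pdb(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(ValueError, match="no "):
            read_pdb(path)

    def test_write_read_roundtrip_to_milliangstrom(self, tmp_path):
        original = make_random_structure(20, seed=3)
        path = tmp_path / "rt.pdb"
        write_pdb(original, path)
        recovered = read_pdb(path)
        orig_atoms = list(original.atoms())
        rec_atoms = list(recovered.atoms())
        assert len(orig_atoms) == len(rec_atoms)
        for a, b in zip(orig_atoms, rec_atoms):
            assert a.name == b.name
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-3)


class TestDistance:
    def test_zero_and_345(self):
        a = Atom("X", "C", [0.0, 0.0, 0.0])
        b = Atom("Y", "C", [3.0, 4.0, 0.0])
        assert distance(a, a) == 0.0
        assert distance(a, b) == pytest.approx(5.0)

    def test_matches_independent_arithmetic_and_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            pa, pb = rng.normal(size=3), rng.normal(size=3)
            a, b = Atom("A", "C", pa), Atom("B", "C", pb)
            by_hand = math.sqrt(sum((x - y) ** 2 for x, y in zip(pa, pb)))
            assert distance(a, b) == pytest.approx(by_hand, rel=1e-12)
            assert distance(a, b) == distance(b, a)


def _hexagon_residue(center, normal_axis=2, radius=1.39):
    atoms = []
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    for k, name in enumerate(names):
        ang = math.pi * k / 3
        offset = np.zeros(3)
        offset[(normal_axis + 1) % 3] = radius * math.cos(ang)
        offset[(normal_axis + 2) % 3] = radius * math.sin(ang)
        atoms.append(Atom(name, "C", np.asarray(center) + offset))
    return Residue("A", 1, "", "PHE", atoms)


class TestRingCentroidNormal:
    def test_regular_hexagon(self):
        res = _hexagon_residue([2.0, -1.0, 5.0])
        centroid, normal = ring_centroid_normal(res)
        np.testing.assert_allclose(centroid, [2.0, -1.0, 5.0], atol=1e-12)
        assert abs(np.dot(normal, [0, 0, 1])) == pytest.approx(1.0, abs=1e-12)

    def test_translation_equivariance(self):
        c0, _ = ring_centroid_normal(_hexagon_residue([0, 0, 0]))
        c1, _ = ring_centroid_normal(_hexagon_residue([3, 4, 5]))
        np.testing.assert_allclose(c1 - c0, [3, 4, 5], atol=1e-12)

    def test_noisy_ring_normal_within_five_degrees(self):
        rng = np.random.default_rng(5)
        res = _hexagon_residue([0, 0, 0])
        for atom in res.atoms:
            atom.coords = atom.coords + rng.normal(0, 0.05, 3)
        _, normal = ring_centroid_normal(res)
        angle = math.degrees(math.acos(min(1.0, abs(normal[2]))))
        assert angle < 5.0

    def test_missing_ring_atom_returns_none(self):
        res = _hexagon_residue([0, 0, 0])
        res.atoms = res.atoms[:-1]
        assert ring_centroid_normal(res) is None


class TestRigidEquivariance:
    def test_distances_preserved_and_centroids_mapped(self):
        rng = np.random.default_rng(17)
        s = make_random_structure(15, seed=2)
        rot = Rotation.random(rng=rng).as_matrix()
        trans = rng.normal(0, 10, 3)
        moved = apply_rigid_transform(s, rot, trans)
        atoms_a = list(s.atoms())
        atoms_b = list(moved.atoms())
        for i in range(0, len(atoms_a) - 1, 7):
            assert distance(atoms_a[i], atoms_a[i + 1]) == pytest.approx(
                distance(atoms_b[i], atoms_b[i + 1]), abs=1e-9
            )
        for res_a, res_b in zip(s.residues(), moved.residues()):
            if res_a.name != "PHE":
                continue
            out_a = ring_centroid_normal(res_a)
            out_b = ring_centroid_normal(res_b)
            np.testing.assert_allclose(rot @ out_a[0] + trans, out_b[0], atol=1e-9)
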