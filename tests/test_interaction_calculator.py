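"""Geometric interaction detection against constructed and brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from coldzyme import (
    Atom,
    InteractionConfig,
    PlantedInteraction,
    PlantedStructureSpec,
    Residue,
    Structure,
    apply_rigid_transform,
    find_aromatic,
    find_cation_pi,
    find_hydrogen_bonds,
    find_hydrophobic,
    find_salt_bridges,
    make_random_structure,
    make_structure,
    sample_planted_spec,
    summarize,
    truth_counts,
)
from coldzyme.interaction_calculator import with_method


def planted(kind, d, seed=0):
    spec = PlantedStructureSpec([PlantedInteraction(kind, d)], seed=seed)
    structure, _ = make_structure(spec)
    return structure


class TestSaltBridgeWindow:
    @pytest.mark.parametrize(
        "d,expected", [(2.4, 0), (2.5, 1), (3.0, 1), (3.5, 1), (4.0, 1), (4.5, 0)]
    )
    def test_window_boundaries(self, d, expected):
        assert len(find_salt_bridges(planted("salt_bridge", d))) == expected


class TestHydrogenBond:
    @pytest.mark.parametrize("d,expected", [(2.9, 1), (3.3, 1), (3.4, 0)])
    def test_cutoff(self, d, expected):
        assert len(find_hydrogen_bonds(planted("hydrogen_bond", d))) == expected

    def _ser_pair(self, sep):
        # two serines with OG...OG at 2.9 A; backbones offset sideways so the
        # hydroxyl pair is the only donor-acceptor contact in range
        def ser(number, x, bb_x):
            return Residue("A", number, "", "SER", [
                Atom("N", "N", [bb_x - 1.2, 8.0, 0.0]),
                Atom("CA", "C", [bb_x, 8.0, 0.0]),
                Atom("C", "C", [bb_x + 0.7, 6.9, 0.0]),
                Atom("O", "O", [bb_x + 0.6, 5.7, 0.0]),
                Atom("OG", "O", [x, 0.0, 0.0]),
            ])
        return Structure("pair", {"A": [ser(5, 0.0, -6.0), ser(5 + sep, 2.9, 9.0)]})

    def test_adjacent_residues_excluded_by_separation_rule(self):
        assert len(find_hydrogen_bonds(self._ser_pair(1))) == 0

    def test_separation_two_included(self):
        # brute-force enumeration over all donor/acceptor atoms confirms the
        # only qualifying pair is OG...OG
        s = self._ser_pair(4)
        records = find_hydrogen_bonds(s)
        assert len(records) == 1
        assert {records[0].label_a, records[0].label_b} == {"OG"}


class TestCationPi:
    @pytest.mark.parametrize("d,expected", [(4.0, 1), (6.0, 1), (7.0, 0)])
    def test_centroid_window(self, d, expected):
        assert len(find_cation_pi(planted("cation_pi", d))) == expected


class TestAromatic:
    @pytest.mark.parametrize("d,expected", [(5.5, 1), (4.5, 1), (7.0, 1), (8.0, 0), (4.0, 0)])
    def test_centroid_window(self, d, expected):
        assert len(find_aromatic(planted("aromatic", d))) == expected


class TestHydrophobic:
    @pytest.mark.parametrize("d,expected", [(4.0, 1), (5.0, 1), (5.5, 0)])
    def test_cutoff(self, d, expected):
        assert len(find_hydrophobic(planted("hydrophobic", d))) == expected

    def test_glycine_only_structure_has_none(self):
        residues = [
            Residue("A", i, "", "GLY", [
                Atom("N", "N", [4.0 * i - 1.2, 0.8, 0.0]),
                Atom("CA", "C", [4.0 * i, 0.0, 0.0]),
                Atom("C", "C", [4.0 * i + 0.7, -1.1, 0.0]),
                Atom("O", "O", [4.0 * i + 0.6, -2.3, 0.0]),
            ])
            for i in range(1, 6)
        ]
        assert len(find_hydrophobic(Structure("gly", {"A": residues}))) == 0


class TestSummarize:
    def test_out_of_window_plants_give_all_zeros(self):
        plants = [PlantedInteraction(k, 7.5) for k in
                  ("salt_bridge", "hydrogen_bond", "cation_pi", "aromatic", "hydrophobic")]
        structure, truth = make_structure(PlantedStructureSpec(plants, seed=4))
        assert truth == []
        assert all(v == 0 for v in summarize(structure).counts.values())

    def test_counts_match_construction(self):
        plants = (
            [PlantedInteraction("hydrogen_bond", 2.8)] * 0
            + [PlantedInteraction("hydrogen_bond", d) for d in (2.7, 3.0, 3.2)]
            + [PlantedInteraction("hydrophobic", d) for d in (3.5, 4.5)]
            + [PlantedInteraction("cation_pi", 5.0)]
        )
        structure, truth = make_structure(PlantedStructureSpec(plants, seed=9))
        counts = summarize(structure).counts
        assert counts["hydrogen_bond"] == 3
        assert counts["hydrophobic"] == 2
        assert counts["cation_pi"] == 1
        assert counts == truth_counts(truth)

    def test_counts_invariant_under_rigid_transform(self):
        structure, _ = make_structure(sample_planted_spec(12))
        rng = np.random.default_rng(12)
        moved = apply_rigid_transform(
            structure, Rotation.random(rng=rng).as_matrix(), rng.normal(0, 30, 3)
        )
        assert summarize(moved).counts == summarize(structure).counts

    def test_counts_invariant_under_reversed_residue_order(self):
        structure, _ = make_structure(sample_planted_spec(13))
        reversed_structure = Structure(
            structure.id, {"A": list(reversed(structure.chains["A"]))}
        )
        assert summarize(reversed_structure).counts == summarize(structure).counts


# ---------------------------------------------------------------------------
# Independent all-pairs oracles (definitions re-implemented from scratch)

_CATIONS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
_ANIONS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_GREASY = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "TYR", "PRO"}


def _oracle_salt_bridge_pairs(structure, lo=2.5, hi=4.0, minsep=2):
    pairs = set()
    residues = list(structure.residues())
    for ra, rb in itertools.product(residues, residues):
        if ra.key == rb.key or abs(ra.number - rb.number) < minsep:
            continue
        for na in _CATIONS.get(ra.name, ()):
            for nb in _ANIONS.get(rb.name, ()):
                aa, ab = ra.atom(na), rb.atom(nb)
                if aa is None or ab is None:
                    continue
                if lo <= np.linalg.norm(aa.coords - ab.coords) <= hi:
                    pairs.add(frozenset([(ra.key, na), (rb.key, nb)]))
    return pairs


def _oracle_hydrophobic_pairs(structure, hi=5.0, minsep=2):
    pairs = set()
    residues = [r for r in structure.residues() if r.name in _GREASY]
    for ra, rb in itertools.combinations(residues, 2):
        if abs(ra.number - rb.number) < minsep:
            continue
        close = any(
            np.linalg.norm(x.coords - y.coords) <= hi
            for x in ra.atoms if x.element == "C" and x.name not in ("CA", "C")
            for y in rb.atoms if y.element == "C" and y.name not in ("CA", "C")
        )
        if close:
            pairs.add(frozenset([ra.key, rb.key]))
    return pairs


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_salt_bridges_equal_independent_enumeration(seed):
    structure = make_random_structure(60, seed=seed)
    assert len(find_salt_bridges(structure)) == len(_oracle_salt_bridge_pairs(structure))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_hydrophobic_equals_independent_enumeration(seed):
    structure = make_random_structure(60, seed=seed)
    assert len(find_hydrophobic(structure)) == len(_oracle_hydrophobic_pairs(structure))


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_grid_backend_equals_brute_force(seed):
    structure = make_random_structure(100, seed=seed)
    cfg = InteractionConfig()
    grid = summarize(structure, with_method(cfg, "grid"))
    brute = summarize(structure, with_method(cfg, "brute"))
    assert grid.counts == brute.counts
    assert grid.records == brute.records


@pytest.mark.parametrize("field,wide", [
    ("hydrophobic_max", 6.0),
    ("hydrogen_bond_max", 3.8),
    ("ionic_max", 8.0),
    ("cation_pi_max", 7.5),
])
def test_widening_window_never_decreases_count(field, wide):
    structure = make_random_structure(60, seed=5)
    base_cfg = InteractionConfig()
    wide_cfg = InteractionConfig(**{field: wide})
    cls = field.rsplit("_", 1)[0]
    assert summarize(structure, wide_cfg).counts[cls] >= summarize(structure, base_cfg).counts[cls]


def test_summary_records_tagged_with_counting_convention():
    summary = summarize(make_random_structure(20, seed=1))
    assert summary.counting["salt_bridge"] == "atom_pair"
    assert summary.counting["hydrophobic"] == "residue_pair"
    assert summary.counts == {cls: len(r) for cls, r in summary.records.items()}
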