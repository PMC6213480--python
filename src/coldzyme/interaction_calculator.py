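"""Geometric enumeration of intramolecular interactions.

Six classes are counted, in the style of the Protein Interactions Calculator
(PIC) family of criteria, from heavy-atom geometry only (homology models
carry no hydrogens, so no angular term is applied anywhere):

==============  =======================================================  ==============
class           criterion                                                default window
==============  =======================================================  ==============
salt_bridge     side-chain N⁺ (Lys NZ; Arg NH1/NH2/NE) to side-chain     2.5–4.0 Å
                O⁻ (Asp OD1/OD2; Glu OE1/OE2)
hydrogen_bond   N/O donor to N/O acceptor, backbone + side chain,        ≤ 3.3 Å
                sequence separation ≥ 2
cation_pi       cation charge center (Lys NZ, Arg CZ) to Phe/Tyr/Trp     ≤ 6.0 Å
                ring centroid
aromatic        ring centroid to ring centroid, Phe/Tyr/Trp              4.5–7.0 Å
hydrophobic     side-chain carbon pairs of AVLIMFWYP                     ≤ 5.0 Å
ionic           any charged-group atom pair (looser electrostatic        ≤ 6.0 Å
                contact, reported separately from salt_bridge)
==============  =======================================================  ==============

The salt-bridge window and the hydrogen-bond cutoff are the two criteria the
source analysis fixes explicitly; the remaining windows are PIC-convention
defaults and every one is a config key.  Counting convention is atom-pair for
salt bridges and hydrogen bonds, residue-pair (deduplicated) for the rest;
the convention is recorded in the summary because absolute counts are only
comparable under a stated convention.

Candidate pairs come from a k-d tree (scipy.spatial.cKDTree); ``method="brute"``
switches to all-pairs enumeration, which the property tests use to pin the
tree path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import (
    RING_ATOMS,
    Atom,
    Residue,
    Structure,
    ring_centroid_normal,
)

logger = logging.getLogger(__name__)

# windows are closed intervals; edge comparisons tolerate float round-off
_EPS = 1e-9

CLASSES = ("salt_bridge", "hydrogen_bond", "cation_pi", "aromatic", "hydrophobic", "ionic")

SALT_CATION_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
SALT_ANION_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
HIS_CATION_ATOMS = ("ND1", "NE2")

#: Cation charge centers for cation-π detection (PIC measures Lys from NZ and
#: Arg from the guanidinium carbon CZ).
CATION_PI_ATOMS = {"LYS": ("NZ",), "ARG": ("CZ",)}

#: Heavy-atom hydrogen-bond donors (N/O bearing a proton).  Backbone N is a
#: donor for every residue except proline; backbone O is always an acceptor.
SIDECHAIN_DONORS = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
}
SIDECHAIN_ACCEPTORS = {
    "ASN": ("OD1",),
    "ASP": ("OD1", "OD2"),
    "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

HYDROPHOBIC_RESIDUES = ("ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "TYR", "PRO")
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class InteractionConfig:
    """Distance windows (Å), membership toggles and counting conventions.

    ``min_seq_sep`` excludes trivially adjacent contacts: residues in the same
    chain interact only when their author numbers differ by at least this
    much (different chains always qualify).
    """

    salt_bridge_min: float = 2.5
    salt_bridge_max: float = 4.0
    hydrogen_bond_max: float = 3.3
    cation_pi_max: float = 6.0
    aromatic_min: float = 4.5
    aromatic_max: float = 7.0
    hydrophobic_max: float = 5.0
    ionic_max: float = 6.0
    min_seq_sep: int = 2
    his_cationic: bool = False
    his_aromatic: bool = False
    method: str = "grid"  # "grid" (k-d tree) or "brute"
    counting: dict[str, str] = field(
        default_factory=lambda: {
            "salt_bridge": "atom_pair",
            "hydrogen_bond": "atom_pair",
            "cation_pi": "residue_pair",
            "aromatic": "residue_pair",
            "hydrophobic": "residue_pair",
            "ionic": "residue_pair",
        }
    )

    def __post_init__(self) -> None:
        if self.salt_bridge_min > self.salt_bridge_max:
            raise ValueError("salt bridge window lower bound exceeds upper bound")
        if self.aromatic_min > self.aromatic_max:
            raise ValueError("aromatic window lower bound exceeds upper bound")

    def window(self, cls: str) -> tuple[float, float]:
        return {
            "salt_bridge": (self.salt_bridge_min, self.salt_bridge_max),
            "hydrogen_bond": (0.0, self.hydrogen_bond_max),
            "cation_pi": (0.0, self.cation_pi_max),
            "aromatic": (self.aromatic_min, self.aromatic_max),
            "hydrophobic": (0.0, self.hydrophobic_max),
            "ionic": (0.0, self.ionic_max),
        }[cls]


@dataclass(frozen=True)
class InteractionRecord:
    """One detected interaction, canonically ordered (key_a < key_b)."""

    cls: str
    res_a: tuple[str, int, str]   # (chain, author number, icode)
    name_a: str                   # residue 3-letter code
    label_a: str                  # atom name or "ring"
    res_b: tuple[str, int, str]
    name_b: str
    label_b: str
    distance: float


@dataclass
class InteractionSummary:
    records: dict[str, list[InteractionRecord]]
    counting: dict[str, str]

    @property
    def counts(self) -> dict[str, int]:
        return {cls: len(self.records.get(cls, [])) for cls in CLASSES}

    def to_json(self) -> str:
        return json.dumps({"counts": self.counts, "counting": self.counting}, indent=2)


# ---------------------------------------------------------------------------
# Pair generation


def _seq_separation(ra: Residue, rb: Residue) -> int:
    if ra.chain_id != rb.chain_id:
        return 10**9
    return abs(ra.number - rb.number)


def _candidate_pairs(coords_a, coords_b, rmax: float, method: str, same: bool):
    """Index pairs (i, j) with d(a_i, b_j) ≤ rmax.  When ``same`` the two
    point sets are identical and only i < j is yielded."""
    na, nb = len(coords_a), len(coords_b)
    if na == 0 or nb == 0:
        return
    if method == "brute":
        for i in range(na):
            for j in range(i + 1 if same else 0, nb):
                if np.linalg.norm(coords_a[i] - coords_b[j]) <= rmax + _EPS:
                    yield i, j
        return
    if same:
        tree = cKDTree(coords_a)
        for i, j in sorted(tree.query_pairs(rmax + _EPS)):
            yield i, j
        return
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    for i, neighbors in enumerate(tree_a.query_ball_tree(tree_b, rmax + _EPS)):
        for j in sorted(neighbors):
            yield i, j


def _emit(cls, ra, la, rb, lb, d) -> InteractionRecord:
    a = (ra.key, ra.name, la)
    b = (rb.key, rb.name, lb)
    if b < a:
        a, b = b, a
    return InteractionRecord(
        cls=cls,
        res_a=a[0], name_a=a[1], label_a=a[2],
        res_b=b[0], name_b=b[1], label_b=b[2],
        distance=float(d),
    )


def _dedup(records: list[InteractionRecord], convention: str) -> list[InteractionRecord]:
    """Canonical deduplication.  atom_pair keeps one record per (residue pair,
    atom pair); residue_pair keeps the shortest contact per residue pair."""
    best: dict[tuple, InteractionRecord] = {}
    for rec in records:
        if convention == "residue_pair":
            key = (rec.res_a, rec.res_b)
        else:
            key = (rec.res_a, rec.label_a, rec.res_b, rec.label_b)
        prev = best.get(key)
        if prev is None or rec.distance < prev.distance:
            best[key] = rec
    return sorted(
        best.values(), key=lambda r: (r.res_a, r.res_b, r.label_a, r.label_b)
    )


def _collect_atoms(structure: Structure, membership: dict[str, tuple[str, ...]]):
    """(residue, atom) list for atoms named in a per-residue-type table."""
    out: list[tuple[Residue, Atom]] = []
    for res in structure.residues():
        names = membership.get(res.name)
        if not names:
            continue
        for n in names:
            atom = res.atom(n)
            if atom is None:
                logger.warning("residue %s %s: missing atom %s", res.name, res.key, n)
                continue
            out.append((res, atom))
    return out


def _charged_group_atoms(structure: Structure, cfg: InteractionConfig):
    cation_table = dict(SALT_CATION_ATOMS)
    if cfg.his_cationic:
        cation_table["HIS"] = HIS_CATION_ATOMS
    cations = _collect_atoms(structure, cation_table)
    anions = _collect_atoms(structure, SALT_ANION_ATOMS)
    return cations, anions


def _pairs_between(group_a, group_b, lo, hi, cfg, cls, same=False):
    coords_a = np.array([a.coords for _, a in group_a]) if group_a else np.empty((0, 3))
    coords_b = np.array([a.coords for _, a in group_b]) if group_b else np.empty((0, 3))
    records = []
    for i, j in _candidate_pairs(coords_a, coords_b, hi, cfg.method, same):
        ra, aa = group_a[i]
        rb, ab = group_b[j]
        if ra.key == rb.key:
            continue
        if _seq_separation(ra, rb) < cfg.min_seq_sep:
            continue
        d = float(np.linalg.norm(aa.coords - ab.coords))
        if d < lo - _EPS or d > hi + _EPS:
            continue
        records.append(_emit(cls, ra, aa.name, rb, ab.name, d))
    return _dedup(records, cfg.counting[cls])


# ---------------------------------------------------------------------------
# Interaction classes


def find_salt_bridges(structure: Structure, cfg: InteractionConfig | None = None):
    """Side-chain nitrogen/oxygen electrostatic pairs within the salt-bridge
    window (default 2.5–4.0 Å)."""
    cfg = cfg or InteractionConfig()
    cations, anions = _charged_group_atoms(structure, cfg)
    return _pairs_between(
        cations, anions, cfg.salt_bridge_min, cfg.salt_bridge_max, cfg, "salt_bridge"
    )


def find_ionic(structure: Structure, cfg: InteractionConfig | None = None):
    """Looser charged-group contacts (default ≤ 6 Å), reported separately from
    the tighter salt-bridge class."""
    cfg = cfg or InteractionConfig()
    cations, anions = _charged_group_atoms(structure, cfg)
    return _pairs_between(cations, anions, 0.0, cfg.ionic_max, cfg, "ionic")


def find_hydrogen_bonds(structure: Structure, cfg: InteractionConfig | None = None):
    """Heavy-atom N/O donor–acceptor pairs within the cutoff (default 3.3 Å),
    sequence separation ≥ cfg.min_seq_sep.  Distance-only criterion."""
    cfg = cfg or InteractionConfig()
    donors: list[tuple[Residue, Atom]] = []
    acceptors: list[tuple[Residue, Atom]] = []
    for res in structure.residues():
        if res.one_letter is None:
            continue
        bb_n = res.atom("N")
        if bb_n is not None and res.name != "PRO":
            donors.append((res, bb_n))
        bb_o = res.atom("O")
        if bb_o is not None:
            acceptors.append((res, bb_o))
        oxt = res.atom("OXT")
        if oxt is not None:
            acceptors.append((res, oxt))
        for n in SIDECHAIN_DONORS.get(res.name, ()):
            atom = res.atom(n)
            if atom is not None:
                donors.append((res, atom))
        for n in SIDECHAIN_ACCEPTORS.get(res.name, ()):
            atom = res.atom(n)
            if atom is not None:
                acceptors.append((res, atom))
    records = _pairs_between(
        donors, acceptors, 0.0, cfg.hydrogen_bond_max, cfg, "hydrogen_bond"
    )
    # A pair like Ser OG···Ser OG qualifies in both donor→acceptor directions;
    # canonical ordering in _emit plus _dedup already collapses it to one.
    return records


def _ring_centroids(structure: Structure, cfg: InteractionConfig):
    aromatic_types = {"PHE", "TYR", "TRP"}
    if cfg.his_aromatic:
        aromatic_types.add("HIS")
    out = []
    for res in structure.residues():
        if res.name not in aromatic_types:
            continue
        cn = ring_centroid_normal(res, RING_ATOMS.get(res.name))
        if cn is None:
            continue
        out.append((res, cn[0]))
    return out


def find_cation_pi(structure: Structure, cfg: InteractionConfig | None = None):
    """Cation charge centers within cfg.cation_pi_max of an aromatic ring
    centroid (default 6.0 Å)."""
    cfg = cfg or InteractionConfig()
    cation_table = dict(CATION_PI_ATOMS)
    if cfg.his_cationic:
        cation_table["HIS"] = ("CE1",)
    cations = _collect_atoms(structure, cation_table)
    rings = _ring_centroids(structure, cfg)
    coords_c = np.array([a.coords for _, a in cations]) if cations else np.empty((0, 3))
    coords_r = np.array([c for _, c in rings]) if rings else np.empty((0, 3))
    records = []
    for i, j in _candidate_pairs(coords_c, coords_r, cfg.cation_pi_max, cfg.method, False):
        res_c, atom = cations[i]
        res_r, centroid = rings[j]
        if res_c.key == res_r.key:
            continue
        if _seq_separation(res_c, res_r) < cfg.min_seq_sep:
            continue
        d = float(np.linalg.norm(atom.coords - centroid))
        if d > cfg.cation_pi_max + _EPS:
            continue
        records.append(_emit("cation_pi", res_c, atom.name, res_r, "ring", d))
    return _dedup(records, cfg.counting["cation_pi"])


def find_aromatic(structure: Structure, cfg: InteractionConfig | None = None):
    """Aromatic ring-centroid pairs within the window (default 4.5–7.0 Å)."""
    cfg = cfg or InteractionConfig()
    rings = _ring_centroids(structure, cfg)
    coords = np.array([c for _, c in rings]) if rings else np.empty((0, 3))
    records = []
    for i, j in _candidate_pairs(coords, coords, cfg.aromatic_max, cfg.method, True):
        ra, ca = rings[i]
        rb, cb = rings[j]
        if ra.key == rb.key or _seq_separation(ra, rb) < cfg.min_seq_sep:
            continue
        d = float(np.linalg.norm(ca - cb))
        if d < cfg.aromatic_min - _EPS or d > cfg.aromatic_max + _EPS:
            continue
        records.append(_emit("aromatic", ra, "ring", rb, "ring", d))
    return _dedup(records, cfg.counting["aromatic"])


def find_hydrophobic(structure: Structure, cfg: InteractionConfig | None = None):
    """Side-chain carbon contacts between hydrophobic residues (default
    ≤ 5.0 Å), deduplicated to residue pairs by default."""
    cfg = cfg or InteractionConfig()
    group: list[tuple[Residue, Atom]] = []
    for res in structure.residues():
        if res.name not in HYDROPHOBIC_RESIDUES:
            continue
        for atom in res.atoms:
            if atom.element == "C" and atom.name not in BACKBONE_ATOMS:
                group.append((res, atom))
    return _pairs_between(group, group, 0.0, cfg.hydrophobic_max, cfg, "hydrophobic", same=True)


FINDERS = {
    "salt_bridge": find_salt_bridges,
    "hydrogen_bond": find_hydrogen_bonds,
    "cation_pi": find_cation_pi,
    "aromatic": find_aromatic,
    "hydrophobic": find_hydrophobic,
    "ionic": find_ionic,
}


def summarize(structure: Structure, cfg: InteractionConfig | None = None) -> InteractionSummary:
    """Run every interaction class and aggregate counts.  Deterministic for a
    fixed structure and config."""
    cfg = cfg or InteractionConfig()
    records = {cls: finder(structure, cfg) for cls, finder in FINDERS.items()}
    return InteractionSummary(records=records, counting=dict(cfg.counting))


def records_to_tsv(records: list[InteractionRecord]) -> str:
    """TSV rendering: class, chainA, resA, atomA, chainB, resB, atomB, distance."""
    lines = ["class\tchain_a\tres_a\tatom_a\tchain_b\tres_b\tatom_b\tdistance"]
    for r in records:
        lines.append(
            f"{r.cls}\t{r.res_a[0]}\t{r.name_a}{r.res_a[1]}{r.res_a[2]}\t{r.label_a}\t"
            f"{r.res_b[0]}\t{r.name_b}{r.res_b[1]}{r.res_b[2]}\t{r.label_b}\t{r.distance:.3f}"
        )
    return "\n".join(lines) + "\n"


def with_method(cfg: InteractionConfig, method: str) -> InteractionConfig:
    """Copy of a config with the candidate-pair backend swapped."""
    return replace(cfg, method=method, counting=dict(cfg.counting))
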