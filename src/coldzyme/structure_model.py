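"""Typed atom/residue/chain coordinate model and geometry primitives.

PDB files are parsed through Bio.PDB and converted into a small, explicit
hierarchy (`Structure` → chains → `Residue` → `Atom`) that keeps author
residue numbering untouched — homolog comparisons are expressed in author
numbers, so no renumbering ever happens here.  A minimal PDB writer exists so
synthetic fixtures can round-trip through the same reader as real files.

Geometry helpers (`distance`, `ring_centroid_normal`) are deliberately dumb:
Euclidean norm and a least-squares plane via SVD.  All of them are rigid-body
equivariant, which the interaction calculator's invariants rely on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD"}

#: Atom names defining the aromatic ring plane per residue type.  For Trp the
#: six-membered benzene ring is used as the π face.
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) in Å
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} not in [0,1]")


@dataclass
class Residue:
    chain_id: str
    number: int          # author numbering, preserved verbatim
    icode: str
    name: str            # 3-letter code
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def one_letter(self) -> str | None:
        return THREE_TO_ONE.get(self.name)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, names) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    source: str | None = None

    def residues(self, chain: str | None = None):
        if chain is not None:
            yield from self.chains.get(chain, [])
            return
        for residues in self.chains.values():
            yield from residues

    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def atoms(self):
        for res in self.residues():
            yield from res.atoms


# ---------------------------------------------------------------------------
# PDB I/O


def read_pdb(
    path,
    model_index: int = 0,
    altloc_policy: str = "max_occupancy",
    keep_waters: bool = False,
    structure_id: str | None = None,
) -> Structure:
    """Parse a PDB file into a Structure.

    The requested model (first by default) is kept.  Disordered atoms are
    collapsed to one location: highest occupancy, ties broken by alphabetical
    altloc ('A' wins), unless ``altloc_policy`` names an explicit altloc
    character to prefer.  Waters are dropped by default; other heteroatoms
    are retained (the interaction calculator ignores non-protein residues).

    Raises ``ValueError`` with the parser's line diagnostic on malformed
    ATOM/HETATM records, and on files containing no residues.
    """
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    sid = structure_id or "structure"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            bio_structure = parser.get_structure(sid, str(path))
    except PDBConstructionException as exc:
        raise ValueError(f"{path}: unparseable PDB record ({exc})") from exc

    models = list(bio_structure)
    if not models:
        raise ValueError(f"{path}: no models in file")
    model = models[model_index]

    structure = Structure(id=sid, source=str(path))
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, number, icode = bio_res.id
            name = bio_res.get_resname().strip()
            if not keep_waters and (hetflag == "W" or name in WATER_NAMES):
                continue
            atoms: list[Atom] = []
            for bio_atom in bio_res:
                if bio_atom.is_disordered():
                    alts = bio_atom.disordered_get_list()
                    if altloc_policy == "max_occupancy":
                        chosen = sorted(
                            alts, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc())
                        )[0]
                    else:
                        named = [a for a in alts if a.get_altloc() == altloc_policy]
                        chosen = named[0] if named else alts[0]
                else:
                    chosen = bio_atom
                atoms.append(
                    Atom(
                        name=chosen.get_name(),
                        element=(chosen.element or "").strip().upper(),
                        coords=np.array(chosen.get_coord(), dtype=float),
                        altloc=(chosen.get_altloc() or "").strip(),
                        occupancy=min(max(chosen.get_occupancy() or 1.0, 0.0), 1.0),
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=bio_chain.id,
                        number=number,
                        icode=icode.strip(),
                        name=name,
                        atoms=atoms,
                    )
                )
        if residues:
            keys = [r.key for r in residues]
            if len(keys) != len(set(keys)):
                raise ValueError(f"{path}: duplicate residue keys in chain {bio_chain.id}")
            structure.chains[bio_chain.id] = residues
    if structure.n_residues() == 0:
        raise ValueError(f"{path}: no residues parsed (empty structure)")
    return structure


def write_pdb(structure: Structure, path) -> None:
    """Write a minimal but standards-conforming set of ATOM records.

    Coordinates are printed with three decimals (%8.3f), so write→read
    round-trips agree to 1e-3 Å.
    """
    serial = 1
    with open(path, "w") as fh:
        for chain_id, residues in structure.chains.items():
            for res in residues:
                for atom in res.atoms:
                    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                    fh.write(
                        "ATOM  {serial:5d} {name:4s}{alt:1s}{res:>3s} {chain:1s}"
                        "{num:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
                        "          {el:>2s}\n".format(
                            serial=serial,
                            name=name,
                            alt=atom.altloc or " ",
                            res=res.name,
                            chain=chain_id,
                            num=res.number,
                            icode=res.icode or " ",
                            x=atom.coords[0],
                            y=atom.coords[1],
                            z=atom.coords[2],
                            occ=atom.occupancy,
                            b=0.0,
                            el=atom.element,
                        )
                    )
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")


def structure_sequence(
    structure: Structure, chain: str | None = None
) -> tuple[str, list[int]]:
    """One-letter sequence and parallel author-number list for a chain
    (or all chains in order).  Non-standard residues are skipped with a
    logged warning."""
    seq: list[str] = []
    numbers: list[int] = []
    for res in structure.residues(chain):
        one = res.one_letter
        if one is None:
            logger.warning("skipping non-standard residue %s %s", res.name, res.key)
            continue
        seq.append(one)
        numbers.append(res.number)
    return "".join(seq), numbers


# ---------------------------------------------------------------------------
# Geometry primitives


def distance(a: Atom, b: Atom) -> float:
    """Euclidean distance in Å."""
    return float(np.linalg.norm(a.coords - b.coords))


def ring_centroid_normal(
    res: Residue, ring: tuple[str, ...] | None = None
) -> tuple[np.ndarray, np.ndarray] | None:
    """Centroid and unit normal of an aromatic ring.

    The centroid is the mean of the ring-atom coordinates; the normal is the
    least-squares plane normal (smallest-variance right singular vector of
    the centered coordinates), sign-normalized so its largest-magnitude
    component is positive.  Returns ``None`` (with a logged warning) when a
    ring atom is missing — the caller skips the residue.
    """
    if ring is None:
        ring = RING_ATOMS.get(res.name)
        if ring is None:
            return None
    atoms = [res.atom(n) for n in ring]
    if any(a is None for a in atoms):
        logger.warning("residue %s %s: incomplete aromatic ring, skipped", res.name, res.key)
        return None
    coords = np.array([a.coords for a in atoms])
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    normal = vt[-1]
    pivot = int(np.argmax(np.abs(normal)))
    if normal[pivot] < 0:
        normal = -normal
    return centroid, normal / np.linalg.norm(normal)


def apply_rigid_transform(
    structure: Structure, rotation: np.ndarray, translation: np.ndarray
) -> Structure:
    """Return a copy of the structure with every coordinate mapped through
    x ↦ R·x + t.  Used by equivariance tests and fixture placement."""
    rotation = np.asarray(rotation, float)
    translation = np.asarray(translation, float)
    out = Structure(id=structure.id, source=structure.source)
    for chain_id, residues in structure.chains.items():
        out.chains[chain_id] = [
            Residue(
                chain_id=res.chain_id,
                number=res.number,
                icode=res.icode,
                name=res.name,
                atoms=[
                    Atom(
                        name=a.name,
                        element=a.element,
                        coords=rotation @ a.coords + translation,
                        altloc=a.altloc,
                        occupancy=a.occupancy,
                    )
                    for a in res.atoms
                ],
            )
            for res in residues
        ]
    return out
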