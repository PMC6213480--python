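"""Seed-deterministic generators for every fixture class the pipeline needs.

Three families:

* **Planted-interaction structures** — chemically idealized but geometrically
  exact residue pairs placed on isolated "islands" (50 Å apart, far beyond
  every interaction window) so each planted contact is the only cross-residue
  geometry in play.  The generator returns the ground-truth interaction
  records alongside the structure; ground truth is derived from the class
  definitions (distance windows and membership), never by running the
  detector, so detector tests against it are genuine round trips.
* **Michaelis–Menten rate curves** — v = Vm·S/(Km+S) with multiplicative
  Gaussian noise (relative noise reflects photometric rate assays).
* **Arrhenius rate–temperature series** — kcat = A·exp(−Ea/RT) with optional
  log-normal noise.

Every generator is a pure function of (spec, seed): identical inputs give
byte-identical outputs.

Geometry notes for the planted structures.  Each island holds two residues
whose interacting atoms sit on the island axis at exactly the requested
separation; carboxylate twin oxygens are placed 2.2 Å *beyond* the engaged
oxygen so they never slip into a tighter window; aromatic ring pairs are
stacked face-to-face and eclipsed, so their closest atom-atom distance
equals the centroid distance (which is what couples a planted aromatic
contact into the hydrophobic class only when the centroid distance itself is
inside the hydrophobic window).  A seeded random rigid rotation is applied
per island, so fixtures are not axis-aligned but all distances are preserved
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .activation_thermo import CELSIUS_OFFSET, CONSTANTS, RateTemperaturePoint
from .enzyme_kinetics import KineticPoint
from .interaction_calculator import InteractionConfig, InteractionRecord
from .structure_model import Atom, Residue, Structure

PLANT_KINDS = ("salt_bridge", "hydrogen_bond", "cation_pi", "aromatic", "hydrophobic", "ionic")

_BACKBONE_OFFSETS = {
    "N": np.array([-1.2, 0.8, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.7, -1.1, 0.0]),
    "O": np.array([0.6, -2.3, 0.0]),
}
_RING_RADIUS = 1.39  # benzene C-C ring circumradius, Å
_CARBOXYL_SPLIT = 2.2  # engaged O to twin O along the island axis, Å

_ISLAND_SPACING = 50.0
_CA_SEPARATION = 10.0
_MAX_PLANT_DISTANCE = 8.0


@dataclass(frozen=True)
class PlantedInteraction:
    """One requested contact: interaction class and exact distance in Å."""

    kind: str
    distance: float

    def __post_init__(self) -> None:
        if self.kind not in PLANT_KINDS:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if not 0.5 <= self.distance <= _MAX_PLANT_DISTANCE:
            raise ValueError(
                f"infeasible placement: distance {self.distance} Å outside "
                f"[0.5, {_MAX_PLANT_DISTANCE}] Å island capacity"
            )


@dataclass
class PlantedStructureSpec:
    interactions: list[PlantedInteraction]
    seed: int = 0
    config: InteractionConfig = field(default_factory=InteractionConfig)


@dataclass
class SimulatedKineticsSpec:
    """Km (mM), Vm (μmol·min⁻¹·mg⁻¹), concentration grid and relative noise."""

    km_mm: float = 0.33
    vm: float = 15.24
    s_grid_mm: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.05, 2.0, 8)
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.s_grid_mm = np.asarray(self.s_grid_mm, float)
        if np.any(self.s_grid_mm <= 0):
            raise ValueError("substrate grid must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass
class SimulatedArrheniusSpec:
    """Ea (J/mol), pre-exponential A (s⁻¹), temperature list (°C), log-scale
    noise sd."""

    ea_j_mol: float = 20544.8
    a: float = 98150.0
    temps_c: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ea_j_mol <= 0 or self.a <= 0:
            raise ValueError("Ea and A must be positive")
        if len(set(self.temps_c)) != len(self.temps_c):
            raise ValueError("temperatures must be distinct")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


# ---------------------------------------------------------------------------
# Planted structures


def _hexagon(center: np.ndarray) -> list[np.ndarray]:
    """Regular ring of 6 atoms in the plane normal to x, centered at center."""
    pts = []
    for k in range(6):
        ang = math.pi * k / 3.0
        pts.append(center + _RING_RADIUS * np.array([0.0, math.cos(ang), math.sin(ang)]))
    return pts


def _residue(chain: str, number: int, name: str, named_atoms: dict[str, np.ndarray]) -> Residue:
    atoms = []
    for atom_name, pos in named_atoms.items():
        element = atom_name[0] if atom_name[0] in ("N", "O", "C", "S") else "C"
        atoms.append(Atom(name=atom_name, element=element, coords=pos))
    return Residue(chain_id=chain, number=number, icode="", name=name, atoms=atoms)


def _island_residues(kind: str, d: float, num_a: int, num_b: int):
    """Two residues realizing one planted contact on the local island frame
    (A's CA at origin, B's CA at (10, 0, 0), contact along +x)."""
    ax = 0.5 * (_CA_SEPARATION - d)      # A's interacting site x
    bx = 0.5 * (_CA_SEPARATION + d)      # B's interacting site x
    a_backbone = dict(_BACKBONE_OFFSETS)
    b_backbone = {k: v + np.array([_CA_SEPARATION, 0.0, 0.0]) for k, v in _BACKBONE_OFFSETS.items()}

    if kind in ("salt_bridge", "ionic"):
        a = _residue("A", num_a, "LYS", {**a_backbone, "NZ": np.array([ax, 0.0, 0.0])})
        b = _residue(
            "A", num_b, "ASP",
            {
                **b_backbone,
                "OD1": np.array([bx, 0.0, 0.0]),
                "OD2": np.array([bx + _CARBOXYL_SPLIT, 0.0, 0.0]),
            },
        )
        labels = ("NZ", "OD1")
    elif kind == "hydrogen_bond":
        a = _residue("A", num_a, "SER", {**a_backbone, "OG": np.array([ax, 0.0, 0.0])})
        b = _residue("A", num_b, "SER", {**b_backbone, "OG": np.array([bx, 0.0, 0.0])})
        labels = ("OG", "OG")
    elif kind == "cation_pi":
        ring = _hexagon(np.array([bx, 0.0, 0.0]))
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        a = _residue("A", num_a, "LYS", {**a_backbone, "NZ": np.array([ax, 0.0, 0.0])})
        b = _residue("A", num_b, "PHE", {**b_backbone, **dict(zip(names, ring))})
        labels = ("NZ", "ring")
    elif kind == "aromatic":
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        ring_a = _hexagon(np.array([ax, 0.0, 0.0]))
        ring_b = _hexagon(np.array([bx, 0.0, 0.0]))
        a = _residue("A", num_a, "PHE", {**a_backbone, **dict(zip(names, ring_a))})
        b = _residue("A", num_b, "PHE", {**b_backbone, **dict(zip(names, ring_b))})
        labels = ("ring", "ring")
    elif kind == "hydrophobic":
        a = _residue("A", num_a, "LEU", {**a_backbone, "CD1": np.array([ax, 0.0, 0.0])})
        b = _residue("A", num_b, "VAL", {**b_backbone, "CG1": np.array([bx, 0.0, 0.0])})
        labels = ("CD1", "CG1")
    else:  # pragma: no cover - guarded by PlantedInteraction
        raise ValueError(kind)
    return a, b, labels


def _expected_records(
    plant: PlantedInteraction,
    res_a: Residue,
    res_b: Residue,
    labels: tuple[str, str],
    cfg: InteractionConfig,
) -> list[InteractionRecord]:
    """Ground truth from the class *definitions* alone.

    A charged pair is simultaneously a salt bridge / H-bond / ionic contact
    whenever its distance falls in the respective window; a stacked aromatic
    pair is also a hydrophobic contact when the centroid distance is inside
    the hydrophobic window (eclipsed stacking makes the nearest carbon pair
    exactly the centroid distance).
    """
    d = plant.distance
    hits: list[tuple[str, str, str]] = []
    if plant.kind in ("salt_bridge", "ionic"):
        if cfg.salt_bridge_min <= d <= cfg.salt_bridge_max:
            hits.append(("salt_bridge", "NZ", "OD1"))
        if d <= cfg.hydrogen_bond_max:
            hits.append(("hydrogen_bond", "NZ", "OD1"))
        if d <= cfg.ionic_max:
            hits.append(("ionic", "NZ", "OD1"))
    elif plant.kind == "hydrogen_bond":
        if d <= cfg.hydrogen_bond_max:
            hits.append(("hydrogen_bond", "OG", "OG"))
    elif plant.kind == "cation_pi":
        if d <= cfg.cation_pi_max:
            hits.append(("cation_pi", "NZ", "ring"))
    elif plant.kind == "aromatic":
        if cfg.aromatic_min <= d <= cfg.aromatic_max:
            hits.append(("aromatic", "ring", "ring"))
        if d <= cfg.hydrophobic_max:
            hits.append(("hydrophobic", "CG", "CG"))
    elif plant.kind == "hydrophobic":
        if d <= cfg.hydrophobic_max:
            hits.append(("hydrophobic", "CD1", "CG1"))
    records = []
    for cls, la, lb in hits:
        a = (res_a.key, res_a.name, la)
        b = (res_b.key, res_b.name, lb)
        if b < a:
            a, b = b, a
        records.append(
            InteractionRecord(
                cls=cls,
                res_a=a[0], name_a=a[1], label_a=a[2],
                res_b=b[0], name_b=b[1], label_b=b[2],
                distance=d,
            )
        )
    return records


def make_structure(
    spec: PlantedStructureSpec,
) -> tuple[Structure, list[InteractionRecord]]:
    """Build a PDB-writable structure realizing the requested contacts, plus
    the ground-truth interaction records derived from the class definitions.

    Each planted distance is realized exactly (within 0.01 Å after PDB
    round-trip); islands sit 50 Å apart and are randomly rotated with the
    spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    structure = Structure(id=f"planted-{spec.seed}", chains={"A": []})
    truth: list[InteractionRecord] = []
    for k, plant in enumerate(spec.interactions):
        num_a, num_b = 10 * k + 1, 10 * k + 4
        res_a, res_b, labels = _island_residues(plant.kind, plant.distance, num_a, num_b)
        rot = Rotation.random(rng=rng).as_matrix()
        offset = np.array([0.0, 0.0, _ISLAND_SPACING * k])
        for res in (res_a, res_b):
            for atom in res.atoms:
                atom.coords = rot @ atom.coords + offset
        structure.chains["A"].extend([res_a, res_b])
        truth.extend(_expected_records(plant, res_a, res_b, labels, spec.config))
    if not structure.chains["A"]:
        raise ValueError("spec plants no interactions")
    return structure, truth


def truth_counts(truth: list[InteractionRecord]) -> dict[str, int]:
    counts = {cls: 0 for cls in PLANT_KINDS}
    for rec in truth:
        counts[rec.cls] += 1
    return counts


def sample_planted_spec(
    seed: int, cfg: InteractionConfig | None = None, max_per_class: int = 3
) -> PlantedStructureSpec:
    """Random mixture of in-window and out-of-window plants for one seed.

    Aromatic in-window distances are drawn above the hydrophobic cutoff so
    each in-window plant contributes to exactly the classes its ground-truth
    rules say; out-of-window distances are drawn beyond every window.
    """
    cfg = cfg or InteractionConfig()
    rng = np.random.default_rng(seed)
    windows = {
        "salt_bridge": (cfg.salt_bridge_min, cfg.salt_bridge_max),
        "hydrogen_bond": (1.8, cfg.hydrogen_bond_max),
        "cation_pi": (2.5, cfg.cation_pi_max),
        "aromatic": (max(cfg.aromatic_min, cfg.hydrophobic_max + 0.2), cfg.aromatic_max),
        "hydrophobic": (2.5, cfg.hydrophobic_max),
        "ionic": (cfg.salt_bridge_max + 0.1, cfg.ionic_max),
    }
    plants: list[PlantedInteraction] = []
    for kind in PLANT_KINDS:
        lo, hi = windows[kind]
        for _ in range(int(rng.integers(1, max_per_class + 1))):
            plants.append(PlantedInteraction(kind, float(np.round(rng.uniform(lo, hi), 3))))
        # one decoy placed past every window
        plants.append(PlantedInteraction(kind, float(np.round(rng.uniform(7.2, 7.9), 3))))
    return PlantedStructureSpec(interactions=plants, seed=seed, config=cfg)


# ---------------------------------------------------------------------------
# Random (unplanted) structures for brute-force-vs-grid checks

_RANDOM_SIDECHAINS = {
    "LYS": ("NZ",),
    "ARG": ("CZ", "NE", "NH1", "NH2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "SER": ("OG",),
    "LEU": ("CD1", "CD2"),
    "VAL": ("CG1", "CG2"),
    "ALA": ("CB",),
    "GLY": (),
}


def make_random_structure(n_residues: int, seed: int, box: float = 28.0) -> Structure:
    """Residues of mixed types thrown uniformly into a box, with backbone and
    a few side-chain atoms at random short offsets.  No ground truth — this
    fixture exists to compare detector backends against each other."""
    rng = np.random.default_rng(seed)
    names = list(_RANDOM_SIDECHAINS) + ["PHE"]
    residues = []
    for i in range(n_residues):
        name = names[int(rng.integers(len(names)))]
        ca = rng.uniform(0.0, box, 3)
        named = {k: ca + v for k, v in _BACKBONE_OFFSETS.items()}
        if name == "PHE":
            center = ca + rng.normal(0.0, 1.5, 3)
            ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
            for rn, pos in zip(ring_names, _hexagon(center)):
                named[rn] = pos
        else:
            for rn in _RANDOM_SIDECHAINS[name]:
                named[rn] = ca + rng.normal(0.0, 2.0, 3)
        residues.append(_residue("A", i + 1, name, named))
    return Structure(id=f"random-{seed}", chains={"A": residues})


# ---------------------------------------------------------------------------
# Kinetic and Arrhenius series


def make_kinetics(spec: SimulatedKineticsSpec) -> tuple[list[KineticPoint], dict]:
    """Michaelis–Menten rates with multiplicative Gaussian noise:
    v = Vm·S/(Km+S) · (1 + ε), ε ~ N(0, sd)."""
    rng = np.random.default_rng(spec.seed)
    s = spec.s_grid_mm
    v_true = spec.vm * s / (spec.km_mm + s)
    eps = rng.normal(0.0, spec.noise_sd, len(s)) if spec.noise_sd > 0 else np.zeros(len(s))
    v = np.maximum(v_true * (1.0 + eps), 1e-12)
    points = [KineticPoint(s_mm=float(si), v=float(vi)) for si, vi in zip(s, v)]
    return points, {"km_mm": spec.km_mm, "vm": spec.vm}


def make_arrhenius(spec: SimulatedArrheniusSpec) -> tuple[list[RateTemperaturePoint], dict]:
    """kcat(T) = A·exp(−Ea/RT), optionally with log-normal multiplicative
    noise (Gaussian on ln kcat)."""
    rng = np.random.default_rng(spec.seed)
    points = []
    for tc in spec.temps_c:
        t = tc + CELSIUS_OFFSET
        kcat = spec.a * math.exp(-spec.ea_j_mol / (CONSTANTS.R * t))
        if spec.noise_sd > 0:
            kcat *= math.exp(rng.normal(0.0, spec.noise_sd))
        points.append(RateTemperaturePoint(temp_c=float(tc), kcat=float(kcat)))
    truth = {"ea_j_mol": spec.ea_j_mol, "a": spec.a}
    return points, truth


def arrhenius_prefactor_through(
    ea_j_mol: float, temp_c: float, kcat: float
) -> float:
    """Pre-exponential A making the Arrhenius curve pass through one
    (temperature, kcat) anchor point."""
    t = temp_c + CELSIUS_OFFSET
    return kcat / math.exp(-ea_j_mol / (CONSTANTS.R * t))


def kinetics_to_csv(points: list[KineticPoint], substrate: str = "substrate") -> str:
    lines = ["substrate,S_mM,v"]
    lines += [f"{substrate},{p.s_mm:.6g},{p.v:.6g}" for p in points]
    return "\n".join(lines) + "\n"


def arrhenius_to_csv(points: list[RateTemperaturePoint]) -> str:
    lines = ["temp_C,kcat"]
    lines += [f"{p.temp_c:.6g},{p.kcat:.6g}" for p in points]
    return "\n".join(lines) + "\n"
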