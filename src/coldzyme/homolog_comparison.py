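"""Two-enzyme cold-adaptation comparison.

Combines interaction summaries, Gly/Pro/Arg composition and alignment-based
substitution mapping into one report, the way psychrophilic enzymes are
compared against a mesophilic homolog: fewer electrostatic and hydrophobic
contacts plus a Gly-up / Pro-down / Arg-down composition shift are read as
flexibility (cold-adaptation) signatures.

Positions are always expressed in author numbering — the numbering each
input's coordinate file (or an explicit numbering map) carries — because
that is the currency in which substitutions are cited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .interaction_calculator import CLASSES, InteractionConfig, summarize
from .sequence_profile import ProteinSequence, composition, pairwise_identity
from .structure_model import Structure, structure_sequence

FOCUS_CODES = {"G": "Gly", "P": "Pro", "R": "Arg", "A": "Ala", "S": "Ser"}


@dataclass(frozen=True)
class SubstitutionRecord:
    """One alignment column where the focus residue differs between homologs.

    Rendered as ``X<numA> → Y<numB>`` with both author numbers.
    """

    res_a: str
    number_a: int
    res_b: str
    number_b: int

    def __post_init__(self) -> None:
        if self.res_a == self.res_b:
            raise ValueError("substitution record requires differing residue types")

    def __str__(self) -> str:
        return f"{self.res_a}{self.number_a} → {self.res_b}{self.number_b}"


@dataclass
class NumberedSequence:
    """A protein sequence with a parallel author-number list."""

    sequence: ProteinSequence
    numbers: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.numbers:
            self.numbers = list(range(1, len(self.sequence) + 1))
        if len(self.numbers) != len(self.sequence):
            raise ValueError("numbering map length differs from sequence length")

    @classmethod
    def from_structure(cls, structure: Structure, chain: str | None = None):
        seq, numbers = structure_sequence(structure, chain)
        return cls(ProteinSequence(id=structure.id, residues=seq), numbers)


@dataclass
class ComparisonReport:
    id_a: str
    id_b: str
    percent_identity: float
    interactions_a: dict[str, int]
    interactions_b: dict[str, int]
    composition_a: dict[str, int]
    composition_b: dict[str, int]
    substitutions: dict[str, list[SubstitutionRecord]]
    flags: dict[str, bool]

    @property
    def interaction_deltas(self) -> dict[str, int]:
        return {c: self.interactions_a[c] - self.interactions_b[c] for c in CLASSES}

    def to_json(self) -> str:
        payload = {
            "a": self.id_a,
            "b": self.id_b,
            "percent_identity": round(self.percent_identity, 1),
            "interactions": {"a": self.interactions_a, "b": self.interactions_b},
            "composition": {"a": self.composition_a, "b": self.composition_b},
            "substitutions": {
                label: [str(rec) for rec in recs]
                for label, recs in self.substitutions.items()
            },
            "flags": self.flags,
        }
        return json.dumps(payload, indent=2, ensure_ascii=False)

    def to_markdown(self) -> str:
        rows = [
            f"| Parameter | {self.id_a} | {self.id_b} |",
            "|---|---|---|",
        ]
        labels = {
            "salt_bridge": "Salt bridges",
            "hydrogen_bond": "Hydrogen bonds",
            "cation_pi": "Cation-π interactions",
            "aromatic": "Aromatic interactions",
            "hydrophobic": "Hydrophobic interactions",
            "ionic": "Ionic interactions",
        }
        for cls in CLASSES:
            rows.append(
                f"| {labels[cls]} | {self.interactions_a[cls]} | {self.interactions_b[cls]} |"
            )
        for aa, name in (("G", "Glycine"), ("P", "Proline"), ("R", "Arginine")):
            rows.append(
                f"| {name} residues | {self.composition_a[aa]} | {self.composition_b[aa]} |"
            )
        for label, recs in self.substitutions.items():
            rendered = ", ".join(str(r) for r in recs) or "—"
            rows.append(f"| {label} | {rendered} | |")
        flags = ", ".join(k for k, v in self.flags.items() if v) or "none"
        rows.append(f"| Flags | {flags} | |")
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------


def map_substitutions(
    a: NumberedSequence,
    b: NumberedSequence,
    focus: str,
    focus_in: str = "a",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> list[SubstitutionRecord]:
    """Alignment columns where the focus residue is substituted.

    With ``focus_in="a"`` every column where A carries the focus residue and
    B carries a *different*, non-gap residue yields one record; with
    ``focus_in="b"`` the focus is sought in B instead.  Records are always
    rendered A-position → B-position.  Gap-opposite columns never produce
    records (there is no aligned partner to cite).
    """
    focus = focus.upper()
    if focus_in not in ("a", "b"):
        raise ValueError("focus_in must be 'a' or 'b'")
    aln = pairwise_identity(a.sequence, b.sequence, gap_open, gap_extend)
    ia = ib = 0
    records: list[SubstitutionRecord] = []
    for col_a, col_b in zip(aln.aligned_a, aln.aligned_b):
        if col_a != "-" and col_b != "-" and col_a != col_b:
            carrier = col_a if focus_in == "a" else col_b
            if carrier == focus:
                records.append(
                    SubstitutionRecord(
                        res_a=col_a,
                        number_a=a.numbers[ia],
                        res_b=col_b,
                        number_b=b.numbers[ib],
                    )
                )
        if col_a != "-":
            ia += 1
        if col_b != "-":
            ib += 1
    return records


def _counts(seq: ProteinSequence) -> dict[str, int]:
    return composition(seq).counts


def compare(
    a: Structure,
    b: Structure,
    cfg: InteractionConfig | None = None,
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> ComparisonReport:
    """Full two-homolog report: per-class interaction counts, Gly/Pro/Arg
    composition, substitution lists and qualitative sign-test flags.

    Substitution lists emitted (both proline directions are reported with
    explicit labels rather than a single ambiguous heading):

    - ``gly_in_a``: Gly in A aligned to a different residue in B,
    - ``pro_gained_in_a``: Pro in B aligned to non-Pro in A,
    - ``pro_lost_from_a``: Pro in A aligned to non-Pro in B,
    - ``arg_in_a``: Arg in A aligned to a different residue in B.

    Flags are sign tests only, no thermodynamic claim:

    - ``flexibility``: A has strictly more Gly AND strictly fewer Pro AND
      fewer Arg than B,
    - ``reduced_electrostatic_stability``: A has fewer electrostatic
      contacts (salt bridges + H-bonds + ionic + cation-π + aromatic),
    - ``thermolability``: A has fewer hydrophobic contacts.
    """
    cfg = cfg or InteractionConfig()
    num_a = NumberedSequence.from_structure(a, chain_a)
    num_b = NumberedSequence.from_structure(b, chain_b)

    summary_a = summarize(a, cfg)
    summary_b = summarize(b, cfg)
    counts_a, counts_b = summary_a.counts, summary_b.counts

    comp_a = _counts(num_a.sequence)
    comp_b = _counts(num_b.sequence)

    aln = pairwise_identity(num_a.sequence, num_b.sequence)
    substitutions = {
        "gly_in_a": map_substitutions(num_a, num_b, "G", focus_in="a"),
        "pro_gained_in_a": map_substitutions(num_a, num_b, "P", focus_in="b"),
        "pro_lost_from_a": map_substitutions(num_a, num_b, "P", focus_in="a"),
        "arg_in_a": map_substitutions(num_a, num_b, "R", focus_in="a"),
    }

    electro = ("salt_bridge", "hydrogen_bond", "ionic", "cation_pi", "aromatic")
    flags = {
        "flexibility": (
            comp_a["G"] > comp_b["G"]
            and comp_a["P"] < comp_b["P"]
            and comp_a["R"] < comp_b["R"]
        ),
        "reduced_electrostatic_stability": (
            sum(counts_a[c] for c in electro) < sum(counts_b[c] for c in electro)
        ),
        "thermolability": counts_a["hydrophobic"] < counts_b["hydrophobic"],
    }

    return ComparisonReport(
        id_a=a.id,
        id_b=b.id,
        percent_identity=aln.percent_identity,
        interactions_a=counts_a,
        interactions_b=counts_b,
        composition_a=comp_a,
        composition_b=comp_b,
        substitutions=substitutions,
        flags=flags,
    )
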