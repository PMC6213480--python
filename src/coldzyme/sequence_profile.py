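"""Protein and nucleotide sequence utilities.

ORF translation, average molecular weight, isoelectric point, residue
composition and global pairwise identity — the sequence-level half of a
cold-adaptation comparison between an enzyme and its mesophilic homolog.

Standard formats and algorithms are delegated to Biopython (genetic-code
tables, average residue masses, Needleman–Wunsch with BLOSUM62).  The
isoelectric-point solver is implemented here because its contract — a named,
swappable pKa table and a Henderson–Hasselbalch charge bisection — is part of
the package surface; reported pI values are pKa-set dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

#: Ionizable-group pKa tables.  "bjellqvist" is the set used by the ExPASy
#: Compute pI/Mw tool; "emboss" is the EMBOSS iep default.  pI values shift by
#: a few tenths of a pH unit between sets — always report which set was used.
PKA_SETS: dict[str, dict[str, dict[str, float]]] = {
    "bjellqvist": {
        "positive": {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
        "negative": {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    },
    "emboss": {
        "positive": {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5},
        "negative": {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    },
}
PKA_SETS["expasy"] = PKA_SETS["bjellqvist"]

DEFAULT_PKA_SET = "bjellqvist"
DEFAULT_GENETIC_CODE = 11  # bacterial/archaeal/plastid table


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA sequence over {A, C, G, T}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty nucleotide sequence")
        bad = set(self.residues) - set(NUCLEOTIDES)
        if bad:
            raise ValueError(
                f"{self.id}: non-ACGT symbols {sorted(bad)} in nucleotide sequence"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 standard one-letter codes."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty protein sequence")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"{self.id}: unknown residue symbols {sorted(bad)} in protein sequence"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CompositionProfile:
    """Per-amino-acid counts and fractions for one protein."""

    length: int
    counts: dict[str, int]
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.length:
            raise ValueError("composition counts do not sum to sequence length")


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise alignment with gap-inclusive percent identity."""

    percent_identity: float
    aligned_a: str
    aligned_b: str
    score: float

    def __len__(self) -> int:
        return len(self.aligned_a)


# ---------------------------------------------------------------------------
# ORF translation


def translate_orf(
    orf: NucleotideSequence, table: int = DEFAULT_GENETIC_CODE
) -> ProteinSequence:
    """Translate a complete ORF (start codon .. stop codon) to protein.

    The terminal stop codon is dropped, so an ORF of 3(n+1) nt yields n
    residues; the initiator codon is translated as Met regardless of which
    start codon the genetic code permits (CDS convention).

    Raises
    ------
    ValueError
        If the length is not divisible by 3, the first codon is not a start
        codon, the last codon is not a stop codon, or an internal stop codon
        occurs (the error names the offending codon index).
    """
    seq = orf.residues
    if len(seq) % 3 != 0:
        raise ValueError(
            f"{orf.id}: ORF length {len(seq)} is not divisible by 3"
        )
    code = CodonTable.unambiguous_dna_by_id[table]
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons[0] not in code.start_codons:
        raise ValueError(
            f"{orf.id}: first codon {codons[0]} is not a start codon of table {table}"
        )
    if codons[-1] not in code.stop_codons:
        raise ValueError(
            f"{orf.id}: last codon {codons[-1]} is not a stop codon of table {table}"
        )
    for i, codon in enumerate(codons[:-1]):
        if codon in code.stop_codons:
            raise ValueError(
                f"{orf.id}: internal stop codon {codon} at codon index {i}"
            )
    protein = str(Seq(seq).translate(table=table, cds=True))
    return ProteinSequence(id=orf.id, residues=protein)


# ---------------------------------------------------------------------------
# Physicochemical profile


def molecular_weight(p: ProteinSequence) -> float:
    """Average (not monoisotopic) molecular weight in Da, ExPASy convention:
    sum of average residue masses plus one water."""
    return ProteinAnalysis(p.residues).molecular_weight()


def net_charge(p: ProteinSequence, ph: float, pka_set: str = DEFAULT_PKA_SET) -> float:
    """Henderson–Hasselbalch net charge of the protein at a given pH.

    One N-terminal and one C-terminal group plus the ionizable side chains
    (K, R, H positive; D, E, C, Y negative).  Monotone decreasing in pH.
    """
    pka = PKA_SETS[pka_set]
    counts = {aa: p.residues.count(aa) for aa in AMINO_ACIDS}
    q = 0.0
    for group, pk in pka["positive"].items():
        n = 1 if group == "Nterm" else counts.get(group, 0)
        q += n / (1.0 + 10.0 ** (ph - pk))
    for group, pk in pka["negative"].items():
        n = 1 if group == "Cterm" else counts.get(group, 0)
        q -= n / (1.0 + 10.0 ** (pk - ph))
    return q


def isoelectric_point(
    p: ProteinSequence,
    pka_set: str = DEFAULT_PKA_SET,
    tol: float = 1e-4,
) -> float:
    """pH at which the net Henderson–Hasselbalch charge vanishes.

    Found by bisection on [0, 14]; the charge function is strictly decreasing
    in pH so the root is unique.  Terminates when |charge| < ``tol``.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(p, mid, pka_set)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def composition(p: ProteinSequence) -> CompositionProfile:
    """Exact per-residue counts and fractions."""
    counts = {aa: p.residues.count(aa) for aa in AMINO_ACIDS}
    n = len(p)
    fractions = {aa: c / n for aa, c in counts.items()}
    return CompositionProfile(length=n, counts=counts, fractions=fractions)


# ---------------------------------------------------------------------------
# Pairwise identity

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


def _make_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # Biopython scores gaps as open + (len-1)*extend via these two knobs.
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_identity(
    a: ProteinSequence,
    b: ProteinSequence,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Global (Needleman–Wunsch) alignment and gap-inclusive percent identity.

    Scoring: BLOSUM62, gap open 10, gap extend 0.5.  Identity is the number
    of identical columns divided by the total alignment length *including*
    gap columns, as a percentage.  The highest-scoring alignment is used;
    Biopython's enumeration order makes the choice deterministic.
    """
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(a.residues, b.residues)[0]
    ga, gb = str(aln[0]), str(aln[1])
    identical = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    percent = 100.0 * identical / len(ga)
    return AlignmentResult(
        percent_identity=percent, aligned_a=ga, aligned_b=gb, score=aln.score
    )


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly multi-record, wrapped or unwrapped) FASTA file as
    (id, sequence) pairs, uppercased."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: list[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def sequence_report(p: ProteinSequence, pka_set: str = DEFAULT_PKA_SET) -> dict:
    """MW / pI / composition summary for one protein, as a JSON-ready dict."""
    comp = composition(p)
    return {
        "id": p.id,
        "length": len(p),
        "molecular_weight_da": round(molecular_weight(p), 2),
        "isoelectric_point": round(isoelectric_point(p, pka_set), 2),
        "pka_set": pka_set,
        "composition": comp.counts,
    }
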