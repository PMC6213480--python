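# Methods

This note documents the models, defaults and numerical choices behind
`coldzyme`, and what the synthetic fixtures do and do not establish about
real data.

## Sequence profile

Translation uses Biopython's genetic-code tables, bacterial table 11 by
default, under the CDS convention: the ORF must begin with a start codon
(translated as Met even for GTG/TTG), end with a stop codon, contain no
internal stop, and have length divisible by 3; the terminal stop is dropped,
so 3(n+1) nt yield n residues.

Molecular weight uses average (not monoisotopic) residue masses plus one
water, the ExPASy convention, via Biopython's `ProteinAnalysis`.

The isoelectric point is the unique root of the Henderson–Hasselbalch net
charge (N-terminus, Lys, Arg, His positive; C-terminus, Asp, Glu, Cys, Tyr
negative), found by bisection on pH ∈ [0, 14] to |Q| < 1e-4. Two named pKa
sets ship: `bjellqvist` (the ExPASy table; default) and `emboss`. pI values
are pKa-set dependent — typically by a few tenths of a pH unit — so reports
record the set used. The base Bjellqvist table is applied uniformly; the
residue-specific *terminal* pKa corrections of the full Bjellqvist method
are not, which shifts pI for proteins whose termini carry those corrections
(e.g. N-terminal Met) by up to ~0.2 pH units.

Percent identity comes from a global Needleman–Wunsch alignment, BLOSUM62,
gap open 10, gap extend 0.5, with the gap-inclusive denominator: identical
columns divided by total alignment length. Identity is therefore symmetric
but not an evolutionary distance.

## Structure model

PDB files are parsed with Bio.PDB in strict mode (malformed records raise,
with the parser's line diagnostic). The first model is used unless another
is requested; disordered atoms collapse to the highest-occupancy altloc,
ties preferring 'A'; waters are dropped. Author residue numbering is
preserved verbatim because substitutions and interaction records are cited
in author numbers. Hydrogens, when present, are ignored by all interaction
kernels: the criteria are heavy-atom based, since homology models carry no
hydrogens. Ring planes (Phe/Tyr/Trp benzene ring, His imidazole) are fitted
by SVD; the centroid is the ring-atom mean. If a multi-chain model is
supplied, all chains are analyzed unless a chain is selected in the config;
for oligomeric enzymes analyzed per protomer, select chain A.

## Interaction calculator

Distance windows (Å), all configurable:

| class | window | membership |
|---|---|---|
| salt_bridge | 2.5–4.0 | Lys NZ, Arg NH1/NH2/NE vs Asp OD1/OD2, Glu OE1/OE2 |
| hydrogen_bond | ≤ 3.3 | N/O donors vs N/O acceptors, backbone + side chain |
| cation_pi | ≤ 6.0 | Lys NZ, Arg CZ vs Phe/Tyr/Trp ring centroid |
| aromatic | 4.5–7.0 | ring centroid pairs |
| hydrophobic | ≤ 5.0 | side-chain carbons of Ala/Val/Leu/Ile/Met/Phe/Trp/Tyr/Pro |
| ionic | ≤ 6.0 | same charged-group atoms as salt_bridge, looser contact |

The salt-bridge window and hydrogen-bond cutoff are the two externally fixed
criteria; the others follow Protein Interactions Calculator conventions.
Histidine is counted as neither cationic nor aromatic by default (both
toggles exist): its protonation state is unknowable from coordinates alone.

Hydrogen bonds are distance-only (no angular term — deliberate, since the
intended inputs are hydrogen-free models) with a minimum sequence separation
of 2 author numbers within a chain, which excludes trivial adjacent-backbone
contacts; proline backbone N is not a donor.

Counting conventions: atom-pair for salt bridges and hydrogen bonds (one
record per qualifying atom pair), residue-pair with shortest-contact
deduplication for cation-π, aromatic, hydrophobic and ionic. The convention
is recorded in every summary because absolute counts are meaningless without
it — different published tools disagree by factors of 2–3 on the same
structure purely through this choice. For the same reason, absolute counts
from other programs on other coordinate sets are treated as context, not as
targets this package should reproduce.

Candidate pairs come from a k-d tree (`scipy.spatial.cKDTree`); a brute-force
all-pairs backend exists and the test suite pins the two against each other.
Window membership is evaluated on closed intervals with a 1e-9 Å tolerance,
so a contact engineered exactly at a cutoff is counted inside it regardless
of floating-point round-off in coordinate transforms.

## Homolog comparison

The comparison of a cold-adapted enzyme (A) against a mesophilic homolog (B)
reports per-class interaction counts for both, Gly/Pro/Arg composition, and
substitution lists from the global alignment: Gly in A substituted in B,
Pro gained in A's positions (Pro present in B), Pro lost from A (Pro in A
replaced in B), and Arg in A substituted in B. Both proline directions are
reported under explicit labels because the conventional table layout for
this comparison is ambiguous about which direction its second proline row
means. Gap-opposite columns yield no records.

The qualitative flags are sign tests only: `flexibility` (more Gly, fewer
Pro, fewer Arg in A), `reduced_electrostatic_stability` (fewer salt bridges
+ H-bonds + ionic + cation-π + aromatic in A), `thermolability` (fewer
hydrophobic contacts in A). No thermodynamic quantity is computed from them.

## Enzyme kinetics

The reported estimator is the Lineweaver–Burk double-reciprocal fit:
unweighted OLS of 1/v on 1/S, Vm = 1/intercept, Km = slope/intercept. The
linearization's variance distortion (low-S points dominate) is a known
property of the method; a direct nonlinear least-squares fit of
v = Vm·S/(Km+S) is provided as a diagnostic and agrees to 1e-6 relative on
noise-free data, but is never silently substituted for the reciprocal
estimate. Zero-rate points are excluded (with a warning) from the reciprocal
transform; a non-positive intercept ("no saturating behaviour") is an error.

kcat is stored as an explicit input when supplied; otherwise
kcat = Vm·M(kDa)/60 converts specific activity with the enzyme molar mass.
The explicit path is preferred because the stoichiometric basis of a
published turnover number (per subunit vs per oligomer, active-site
titration) is an experimental convention the rate data cannot reveal; this
is recorded as a limitation, not guessed. The specificity table ranks by
descending kcat/Km, ties broken alphabetically.

## Activation thermodynamics

Ea comes from OLS of ln kcat on 1/T over **all** supplied points (an
endpoint-only slope is not equivalent and is not used). Temperatures convert
as T(K) = T(°C) + 273.15. Then per measured temperature:

- ΔH‡ = Ea − RT (so ΔH decreases by exactly R per kelvin),
- ΔS‡ = R(ln kcat − C − ln T + Ea/RT) with C = ln(k_B/h) + 1,
- ΔG‡ = ΔH‡ − TΔS‡.

C is derived from k_B and h (CODATA values) rather than hard-coded; it
equals 24.76 to two decimals. The "+1" absorbs the Ea = ΔH‡ + RT
substitution inside the Eyring logarithm. ΔS uses the *measured* kcat, so
fit residuals propagate into ΔS and ΔG; on exact Arrhenius data ΔS reduces
to the closed form R(ln A − C − ln T). `eyring_roundtrip` inverts the ΔS
equation and reproduces the measured kcat to floating-point precision.

Full precision is carried internally; two-decimal rounding happens only in
table renderers. On the published four-point LeuDH series this pipeline
reproduces the published ΔH/ΔS/ΔG table within one unit in the last printed
decimal for eleven of twelve cells; the ΔG cell at 10 °C differs by 0.04
kJ/mol, consistent with a rounding artifact in the published table, and is
excluded from the reproduction checks.

## Synthetic data

*Planted structures.* Each requested contact occupies its own two-residue
"island": interacting atoms exactly at the requested separation, islands
50 Å apart (beyond every window), a seeded random rigid rotation per island.
Side-chain chemistry is idealized — the geometry, not the chemistry, is what
the detector tests. Ground truth is derived from the class definitions, not
by running the detector: a charged pair inside 3.3 Å is simultaneously a
salt bridge, a hydrogen bond and an ionic contact; a stacked aromatic pair
whose centroid distance is inside the hydrophobic window is also a
hydrophobic contact (eclipsed stacking makes the closest carbon pair equal
the centroid distance). Carboxylate twin oxygens are placed 2.2 Å beyond the
engaged oxygen so they cannot slip into a tighter window.

*Kinetics.* v = Vm·S/(Km+S)·(1+ε), ε ~ N(0, sd) — multiplicative noise,
reflecting the roughly constant relative error of photometric rate assays.
Defaults are the study conditions of the LeuDH/l-leucine system: Km 0.33 mM,
Vm 15.24 μmol·min⁻¹·mg⁻¹, 8 log-spaced concentrations spanning the assayed
0.05–2 mM range, 5% relative noise for the recovery experiment (a typical
initial-rate assay precision; the source reports none).

*Arrhenius.* kcat = A·exp(−Ea/RT) with optional log-normal noise.

All generators are pure functions of (spec, seed).

What the fixtures do **not** emulate: real side-chain rotamers, crowded
interiors where one atom participates in many contacts, alternate
conformations, or assay artifacts such as substrate inhibition. Passing the
planted-structure suite shows the detector implements its geometric criteria
exactly; it does not validate the criteria themselves against experimental
contact definitions, nor reproduce absolute interaction counts of any
particular published model.

## Problem sizes and runtime

The test suite and the acceptance script run in seconds: four-point
Arrhenius fits, 200-replicate kinetic simulations, 50 planted structures,
and 100-residue random structures for backend cross-checks — sizes chosen
because every check is already exact or statistically stable there.

## Known limitations

- Absolute interaction counts depend on the coordinate model and the
  counting convention; only like-for-like comparisons (same config, both
  structures) are meaningful.
- The pI solver omits Bjellqvist's residue-specific terminal corrections.
- The sequence-separation rule uses author-number differences, which is
  undefined across insertion codes (insertion-coded residues compare by
  their base number).
- No angular criteria anywhere in interaction detection.
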