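# coldzyme

Computational characterization of cold-adapted enzymes, built around the
standard workflow for a psychrophilic leucine dehydrogenase (LeuDH,
EC 1.4.1.9) compared against its mesophilic homolog:

1. **Sequence profile** — ORF translation, average molecular weight,
   isoelectric point (Henderson–Hasselbalch bisection over a named pKa set),
   residue composition and global (Needleman–Wunsch, BLOSUM62) percent
   identity.
2. **Interaction counting** — six geometric interaction classes from PDB
   coordinates (salt bridges 2.5–4.0 Å, hydrogen bonds ≤ 3.3 Å, cation-π
   ≤ 6 Å to ring centroid, aromatic 4.5–7 Å, hydrophobic ≤ 5 Å, ionic ≤ 6 Å),
   heavy-atom only, every cutoff a config key.
3. **Homolog comparison** — per-class interaction deltas, Gly/Pro/Arg
   composition shifts, alignment-based substitution lists in author
   numbering (e.g. `G163 → N107`), and qualitative sign-test flags
   (flexibility, reduced electrostatic stability, thermolability).
4. **Michaelis–Menten kinetics** — Km and Vm by the Lineweaver–Burk
   double-reciprocal OLS (1/v on 1/S; Vm = 1/intercept, Km =
   slope/intercept), kcat and the specificity constant kcat/Km, and the
   substrate ranking; a direct nonlinear fit serves as a diagnostic.
5. **Activation thermodynamics** — Ea from the Arrhenius fit of kcat(T)
   (ln kcat vs 1/T), then per temperature
   ΔH‡ = Ea − RT, ΔS‡ = R(ln kcat − C − ln T + Ea/RT) with
   C = ln(k_B/h) + 1 ≈ 24.76, and ΔG‡ = ΔH‡ − TΔS‡.

A seed-deterministic synthetic-data module generates every fixture the test
surface needs: structures with interactions planted at exact distances
(ground truth returned alongside), Michaelis–Menten curves with known Km/Vm,
and exact Arrhenius series.

## Worked example

Activation thermodynamics from a measured turnover series (the published
four-point series of the cold-adapted LeuDH):

```python
from coldzyme import (RateTemperaturePoint, fit_arrhenius,
                      activation_profile, activation_frame)

points = [RateTemperaturePoint(t, k)
          for t, k in [(0, 12.25), (10, 14.96), (20, 20.20), (30, 30.13)]]
fit = fit_arrhenius(points)
frame = activation_frame(activation_profile(points, fit), fit)
print(f"Ea = {frame.attrs['ea_kj_mol']:.2f} kJ/mol")
print(frame.to_string(index=False))
```

prints

```
Ea = 20.54 kJ/mol
 temp_C  dH_kJ_mol  dS_J_mol_K  dG_kJ_mol  kcat_per_s
    0.0      18.27     -156.45      61.01       12.25
   10.0      18.19     -157.74      62.86       14.96
   20.0      18.11     -158.01      64.43       20.20
   30.0      18.02     -157.28      65.70       30.13
```

The low activation enthalpy and the strongly negative activation entropy are
the classic signature of a cold-adapted enzyme: the rate is maintained at low
temperature by lowering the enthalpic barrier at an entropic cost.

The same stages are available from the shell:

```sh
coldzyme thermo --data kcat_vs_T.csv --out table.tsv
coldzyme kinetics --data rates.csv --kcat-file kcat.csv --out specificity.tsv
coldzyme compare --pdb-a cold.pdb --pdb-b warm.pdb --out report.json
coldzyme report --kinetics-data rates.csv --thermo-data kcat_vs_T.csv --out bundle/
coldzyme simulate structure --plant salt_bridge:3.0 --out fixture.pdb
```

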