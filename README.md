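# legscan

Tools for profiling the substrate specificity of legumain (asparaginyl
endopeptidase) acting as a transpeptidase — the activity that cyclizes
peptides such as the sunflower trypsin inhibitor (SFTI) precursor — and for
screening candidate substrates and covalent inhibitors in silico.

The package is aimed at enzymologists and peptide designers working with
ligase-competent cysteine proteases. It covers four connected analyses:

1. **Positional-scanning libraries and species masses.** On a scaffold such
   as `G1RCTRSIPPICFPN14GLA17` (P1 = Asn14, Cys3–Cys11 disulfide), seven
   substrate positions (P2″, P1″, P3, P2, P1′, P2′, P3′) are varied across
   the 20 proteinogenic residues (140 variants), and every reaction species
   — precursor, linear product (residues 1–P1), cyclic product (−H₂O), and
   their Δ14 demethylated satellites — gets monoisotopic/average masses and
   [M+H]⁺ m/z.
2. **MALDI-TOF quantification.** Peak areas of the three species are
   integrated (±1 Da windows, local linear baseline), converted to
   fractions, and assembled into alanine-normalized specificity matrices for
   cyclization, total-lytic (cyclic + linear), and hydrolysis-only readouts.
3. **Enzyme kinetics.** Initial-rate extraction from progress curves,
   bounded least-squares fits of Michaelis–Menten
   v = Vmax·S/(Km+S), allosteric sigmoidal (Hill)
   v = Vmax·S^h/(Khalf^h+S^h), and substrate-inhibition
   v = Vmax·S/(Km+S(1+S/Ki)) models, AICc model comparison, Eadie–Hofstee
   diagnostics, and competition-assay residual activities.
4. **In-silico screening and structure checks.** Combinatorial
   enzyme–peptide prediction jobs (e.g. `YVANXX`: 400 complexes), parsing of
   predictor confidence output (ipTM, peptide pLDDT, PAE), ranking and 20×20
   ipTM heatmaps with the 0.6/0.8 confidence bands, detection of
   P1′-Cys–catalytic-Cys disulfides (Sγ–Sγ ≤ 2.5 Å), an S1-pocket engagement
   proxy, and Cα RMSD after Kabsch superposition. A deterministic mock
   predictor emits the same file dialect so the pipeline runs without GPUs.

Because raw spectra and predictor outputs for this kind of study are not
publicly deposited, a first-class synthetic-data module generates every
input with planted ground truth, and the test suite verifies that each
analysis stage recovers what was planted.

## Worked example

Simulate the fluorogenic Z-VAN-AMC assay on human legumain at its published
constants (substrate inhibition: Vmax 7800 RFU/s, Km 20 µM, Ki 16 µM;
two-fold dilutions 75→0.29 µM, triplicate, 2% CV) and fit the model:

```python
from legscan import simulate as sim

fit, ds = sim.fit_reference_assay("hLEG:Z-VAN-AMC", seed=1)
print(f"model: {fit.model}")
for name in ("Vmax", "Km", "Ki"):
    print(f"  {name:4s} = {fit[name]:8.2f} +/- {fit.stderr[name]:.2f}")
```

prints

```
model: substrate_inhibition
  Vmax =  7930.86 +/- 302.74
  Km   =    20.46 +/- 0.87
  Ki   =    15.69 +/- 0.83
```

i.e. the fitted Michaelis constant, inhibition constant and maximal velocity
recover the planted values within a few percent at realistic assay noise.

The same round trip from the command line, for the positional scan:

```
legscan simulate scan --seed 3 --out scan/
legscan quantify --spectra scan/ --variants scan/variants.tsv \
                 --scaffold scan/scaffold.yaml --out quants.tsv
legscan scan-heatmap --quants quants.tsv --variants scan/variants.tsv \
                     --readout cyclic --out matrix.tsv --plot matrix.svg
```

```
wrote 140 spectra + truth tables to scan
quantified 140 reactions -> quants.tsv
cyclic matrix -> matrix.tsv
```

`matrix.tsv` holds the 7×20 alanine-normalized cyclization matrix (the
alanine column is 1.0 by construction; cells above 1 mark residues that
enhance cyclic-product formation at that position); `scan/truth.tsv` holds
the planted fractions for comparison. `legscan screen`, `legscan structure`
and `legscan kinetics-*` expose the remaining stages; see `legscan --help`.

See `docs/methods.md` for the models, parameter defaults, and the design
decisions behind the synthetic generators.

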