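# Methods

`legscan` re-implements, as a tested pipeline, an integrated analysis of
legumain (asparaginyl endopeptidase, AEP) transpeptidase specificity:
positional-scanning library design with MALDI-based cyclization
quantification, cooperative and substrate-inhibition kinetic modelling, and a
combinatorial structure-prediction screen ranked by inter-chain predicted
TM-score (ipTM) with disulfide-geometry and superposition checks. This note
records the models, the tunable parameters, and the design choices made where
the procedure was genuinely open.

## The chemistry being modelled

Legumain cleaves after a P1 asparagine. On the 17-residue sunflower trypsin
inhibitor (SFTI) precursor scaffold `G1RCTRSIPPICFPN14GLA17` (P1 fixed as
Asn14, Cys3–Cys11 disulfide), cleavage of the prime-side tripeptide produces
a thioester acyl-enzyme intermediate that is resolved either by water
(hydrolysis, the linear product L-SFTI: residues 1–14, free termini) or by
the peptide's own N-terminus (transpeptidation, the head-to-tail cyclic
product C-SFTI: residues 1–14, −H₂O). The scan varies seven positions —
P2″, P1″ (the incoming nucleophile's N-terminal residues, template indices 2
and 1), P3, P2 (indices 12, 13) and P1′–P3′ (15–17) — across the 20
proteinogenic residues, giving 7 × 20 = 140 variants. Wild-type-coincident
sequences are kept once per site, matching how such crude libraries are
synthesized; P1 can never be varied.

Mass bookkeeping uses monoisotopic residue masses (pyteomics) plus a small
modification table: cyclization −18.010565 Da, disulfide −2.015650 Da per
bond, demethylation −14.015650 Da (the Δ14 satellite routinely seen next to
these peptides in MALDI spectra, nominally a CH₂ loss at Thr or Leu).
Ionization is modelled as singly protonated [M+H]⁺ only (proton
1.007276 Da); average masses are available behind a flag, monoisotopic is
the default.

## MALDI quantification

Each reaction spectrum is reduced to three trapezoidal peak areas
(precursor, linear, cyclic) in windows of ±1.0 Da around the computed
[M+H]⁺ (crude peptides, broad TOF peaks; configurable). A local linear
baseline through the interpolated window-edge intensities is subtracted by
default; it is exact for a flat baseline, and its small tail-clipping bias
is proportional to each peak's own height, so area *fractions* are
unaffected. Areas are clamped at zero; a window outside the spectrum yields
area 0 with a warning. Fractions are computed over the three-parent total;
Δ14 satellite areas are excluded from parents by default and added behind a
flag, since whether satellites contributed to the original quantification is
ambiguous. Specificity matrices divide each variant's readout (cyclic,
linear, or total-lytic = linear + cyclic) by the alanine variant of the same
site; a zero alanine readout flags the cell undefined (never infinity, never
zero). Single-replicate semantics throughout: no error bars are synthesized.

mzML input is decoded directly (base64 arrays, 32/64-bit float, optional
zlib) rather than through a heavier ecosystem reader; only the first
spectrum of a file is read, which is all the pipeline consumes.

## Kinetic models

Three velocity models are fitted by bounded least squares (lmfit), all
parameters positive:

- Michaelis–Menten: v = Vmax·S/(Km+S)
- allosteric sigmoidal (Hill): v = Vmax·S^h/(Khalf^h+S^h), reducing to
  Michaelis–Menten at h = 1
- substrate inhibition: v = Vmax·S/(Km + S(1+S/Ki)), converging to
  Michaelis–Menten as Ki → ∞

Initialization is Vmax₀ = max v, Km₀/Khalf₀ = S at half-max, h₀ = 1,
Ki₀ = max S, plus five deterministically log-jittered restarts; the lowest
SSR wins. Standard errors come from the fit covariance; model comparison
uses AICc (residual variance counted as a parameter), with ties (|ΔAICc| < 2)
going to the model with fewer parameters. The default fit is unweighted;
for the simulated fluorogenic reference assays, whose noise is a constant
coefficient of variation, the bundled `fit_reference_assay` workflow uses
relative (1/v) weighting — the appropriate likelihood when velocities span
more than two orders of magnitude.

Initial rates are the slope of the longest initial window (≥3 points) whose
linear fit reaches R² ≥ 0.98; traces with no qualifying window are flagged
not-fittable but still report their best slope, so a fully inhibited (flat)
trace yields a residual activity near zero rather than an error. Residual
activity in competition assays is the treated/control slope ratio. The
Eadie–Hofstee transform plots v against v/S (a line with slope −Km and
intercept Vmax under Michaelis–Menten); the curvature statistic is the
quadratic coefficient of a least-squares parabola with its SE. Note that
v/S is double-valued in S above Khalf under cooperativity, so the diagnostic
is meaningful on the rising branch (S ≲ Khalf).

## In-silico screen

A screen is a placeholder template (e.g. `YVANXX` varying P1′/P2′) expanded
combinatorially (20^k peptides), one prediction job per unique peptide:
enzyme chain with a precomputed MSA, peptide chain with MSAs and structural
templates disabled. The predictor always runs out of process; the module
writes job files (stable JSON) and parses output directories containing a
summary confidence file (ipTM), a full confidence file (per-atom pLDDTs in
model atom order, PAE matrix over residue tokens) and an mmCIF model.
Peptide pLDDT is averaged per residue via the model's atom table; the PAE
summary is the mean over inter-chain entries (the aggregation is a package
choice; the original statistic is unstated). Ranking is by descending ipTM,
ties broken by descending peptide mean pLDDT, then lexicographic sequence;
ipTM is the affinity proxy throughout, with >0.8 high confidence and <0.6
low. Heatmaps project the screen onto two placeholder positions; any extra
placeholder must be pinned to a residue.

The deterministic mock predictor pins the output dialect and gives every
downstream stage planted truth: ipTM = clip(0.55 + Σ preference
contributions + optional noise, 0, 1) — the 0.55 base is chosen so planted
preferences cross both classification bands — with peptide pLDDTs tracking
ipTM and, for peptides carrying Cys at the designated P1′ position, a
2.05 Å Sγ–Sγ contact to the enzyme's catalytic Cys written into the model,
so disulfide detection exercises real geometry.

## Structure checks

Disulfide detection reports every Cys–Cys Sγ pair with its distance and a
bonded flag at a 2.5 Å default cutoff (typical S–S bond ≈ 2.05 Å). The
S1-engagement proxy measures the distance from the P1 side-chain reference
atom (Cγ for Asn) to the catalytic Sγ, engaged at ≤5 Å by default, and
separately reports which peptide residue sits nearest the catalytic Sγ —
a coarse stand-in for the qualitative "P1 in the S1 pocket" judgement;
missing atoms flag the report incomplete rather than raising. Superposition
uses the proper-rotation Kabsch solution (scipy `align_vectors`; the RMSD is
recomputed from the transform because scipy floors its residual at √ε);
Cα RMSD between structures pairs atoms by chain + residue-number
intersection, with no sequence alignment. Fewer than 3 points or a
collinear set is an error. Reproducing the published RMSD values against
crystal structures requires real predictor output and PDB entries and is out
of scope.

## Synthetic data: what it emulates and what it does not

Spectra are sums of Gaussian peaks (σ 0.3 Da default) at the computed
[M+H]⁺ of each species, with planted area fractions, a flat baseline (1% of
the tallest peak) and signal-proportional noise (per-point CV 0.5% default —
TOF detector noise grows with counts, and this is what makes small-peak
areas recoverable at realistic levels; an additive, max-height-relative
noise of the same nominal level would dominate minor species). Satellites
take a configurable fraction of each parent's area at −14.0157 Da.
Generators warn when species would sit closer than 3σ. Not modelled:
isotope envelopes, ionization-efficiency differences between species,
detector saturation, calibration drift — so passing recovery tests shows the
quantification logic is correct, not that real crude-library spectra are
this clean.

Kinetic data carry multiplicative Gaussian noise (CV 2% default, emulating
triplicate fluorogenic plate assays). The reference conditions bundle the
published constants with their dilution series: Z-AAN-AMC on human legumain
(Michaelis–Menten, Vmax 400 RFU/s, Km 55 µM, two-fold series 100→0.78 µM),
Z-VAN-AMC (substrate inhibition, Vmax 7800 RFU/s, Km 20 µM, Ki 16 µM,
two-fold 75→0.29 µM), and Z-AAN-AMC on *A. thaliana* legumain β
(Km 337 µM, two-fold 1000→7.8 µM; the maximal velocity is not published, so
400 RFU/s is used — Km recovery does not depend on it). Under these
conditions the Ki of the substrate-inhibition fit is the least determined
quantity (relative SD ≈ 6% across seeds): the series only reaches ~4.7 × Ki,
so the inhibition limb is short.

Toy structures are minimal two-chain mmCIF files with exact requested
Sγ–Sγ and Cγ–Sγ distances on a helical-ish (never collinear) peptide trace;
gemmi stores coordinates in single precision, so file round trips are exact
to ~10⁻⁷ relative, not to machine precision.

## Problem sizes and determinism

Every generator is reproducible from its seed (per-variant and per-job
streams are derived from the master seed). The test suite runs the full
140-variant scan recovery and a full 400-job screen round trip; kinetic
recovery tests use three seeds and medians. These sizes match the study's
own designs and keep the whole suite in the tens of seconds.

## Known limitations

- The Hill/cooperativity analysis treats the 2-minute cyclization readout as
  an initial velocity; enzyme-stability deconvolution and integrated
  progress-curve fitting are out of scope.
- The screen adapter targets one confidence-file dialect (the one the mock
  pins); other predictor versions may need key mapping.
- The engagement proxy is geometric only; no solvent accessibility or
  energetics.
- Succinimide at the oxyanion-hole aspartate cannot be represented in the
  modelled structures and is not attempted.
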