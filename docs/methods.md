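# Methods

This note records the model the package implements, the choices made
where the design was genuinely open, and what the synthetic benchmark
does and does not demonstrate.

## Featurization model

A peak list is a set of (m/z, intensity) pairs from a singly-charged
negative-ESI measurement, exported over m/z 150–750 at S/N > 2. The
window filter is inclusive at both endpoints; the S/N threshold is
strict (`snr > 2`), and peaks without an S/N value pass. Each sample is
split into even- and odd-nominal-mass halves — parity taken from the
nearest integer of the *measured* m/z (configurable to Kendrick-nominal
parity) — and each half becomes one independent data point.

Each (sample, parity) peak list maps to a 32 × 32 × 5 tensor indexed by
(mass bin *i*, abundance bin *j*, KMD bin *k*):

1. **Abundance coordinate.** y = (ln a − ⟨ln a⟩ + 0.5)/9.2, with ⟨ln a⟩
   the arithmetic mean of natural-log intensities over the peaks of the
   half-spectrum being featurized — i.e., computed *after* windowing,
   S/N filtering and the parity split, so every data point is
   self-calibrated. The offset 0.5 and scale 9.2 place the instrument's
   dynamic range (noise floor to strongest peaks, roughly e^8.7 ≈ 6000:1)
   inside [0, 1]. Peaks with y outside [0, 1] are **dropped**, not
   clipped (a `clip_abundance` switch exists for sensitivity analysis).
   Because the mean-log subtraction cancels any global intensity factor
   exactly, the feature image is invariant under rescaling all
   intensities — an assertable, not merely approximate, property.
2. **Kendrick axis.** KM = m/z × 14.00000/14.01565; nominal mass =
   nearest integer of KM, ties rounded half away from zero, which
   confines KMD = (nominal − KM)·10³ to (−500, 500] mDa so no peak can
   fall off the axis. Five 200-mDa bins.
3. **Binning.** All three axes use half-open [lo, hi) bins with the
   final bin closed, so the exact top-of-range values (m/z 750, y = 1,
   KMD +500) are retained.
4. **Normalization.** N_ijk = n_ijk / (Σ_i n_ijk + ε), ε = 10⁻⁸; the
   sum runs over the 32 mass bins for each fixed (abundance, KMD)
   column. ε only matters for empty columns, which stay exactly zero.
5. **Truncated log transform.** X = 0.5 ln(0.1 + N) + 1.25. The
   logarithm is **natural**: at N = 0 this gives 0.5 ln 0.1 + 1.25 ≈
   0.0987 and at N = 1 it gives 0.5 ln 1.1 + 1.25 ≈ 1.2977, matching
   the intended output range of roughly [0.1, 1.3]; a base-10 reading
   would give a floor of 0.75 and is therefore rejected.

Flattening is mass-major (C order over (i, j, k)), length 5120 at the
default geometry. The order is irrelevant to PCA (a fixed coordinate
permutation) but is frozen for reproducibility.

## Classification protocol

Data points (two per sample) are split into five stratified folds with
a seeded shuffle; the seed is a required, logged parameter. Within each
fold an N-component PCA (centered, no per-feature scaling, full SVD) is
fitted on the training rows only; train and test rows are projected and
a multinomial logistic regression (scikit-learn defaults: L2 penalty,
C = 1, lbfgs, iteration cap raised to 5000 to guarantee convergence on
low-dimensional score inputs) is fitted and scored. Accuracy is
micro-averaged over each fold's test points. A component sweep reuses
one set of fold assignments across the grid so the curve varies only
with dimensionality.

Parity halves of one sample are near-duplicates, so ungrouped
stratification can place one half in train and the other in test. The
default remains ungrouped (matching the original protocol); passing
`grouped=True` switches to a stratified *group* k-fold that keeps both
halves of a sample in the same fold, which is the conservative choice
when leakage matters. The published study this protocol mirrors
reports 56 spectra yet fold sizes of 48 + 12 = 60; the implementation
takes any dataset size and leaves that arithmetic to its source. Its
"50 % chance" baseline is likewise not reproduced: the negative control
here is label permutation, whose expected accuracy is the
majority-class rate.

## Reconstruction and rendering

Model images at a (PC1, PC2) score coordinate are mean + s₁·c₁ + s₂·c₂,
raw and unclipped (reconstructions may legitimately leave the transform
range); an 8 × 8 grid spans the per-component min–max of the observed
scores independently (not the convex hull of score pairs — extremes are
read per axis). RGB rendering maps three chosen KMD slices — default
0-based bins (2, 3, 4), i.e. the central and high-defect bins — to
red/green/blue, rescaled linearly from [0.0987, 1.2977] to [0, 1] and
clipped at render time only. Van Krevelen coordinates are O/C and H/C
atomic ratios of pre-assigned CHNOS formulas; formula assignment itself
is out of scope and formulas are consumed from the input peak list.

## Biomarker enumeration

Residue masses of the 20 coded amino acids are computed from embedded
monoisotopic elemental masses (H 1.00782503207, C 12, N 14.0030740048,
O 15.9949146196, S 31.97207100). A diketopiperazine's neutral mass is
the **sum of the two residue masses**: cyclization of a dipeptide
removes one water and a dipeptide is two residues plus one water, so the
residue sum accounts for both condensation waters without further
correction. All 210 unordered pairs are enumerated and masses within
10⁻⁴ Da merged — a tolerance that unifies exact elemental-formula
coincidences (Leu/Ile; CH₂ swaps such as Gly+Glu = Ala+Asp) while
keeping near-isobars ~36 mDa apart (Lys vs Gln pairs) distinct.

The exhaustive count is **177 unique masses** (149 singletons, 23
doublets, 5 triplets). The figure of 179 sometimes quoted for this
enumeration misses two exact coincidences outside the CH₂-swap family:
Ala+Met = Cys+Val (an S-atom swap between the Ala/Cys and Val/Met
pairs) and Asn+Trp = His+Tyr. The package reports
the computed 177 and does not special-case the quoted value.

SFA targets are CnH2nO2, n from 2 to 30 by default. Targets are
converted to [M−H]⁻ m/z by subtracting the proton mass (1.00727647 Da,
electron mass included). Matching accepts a peak within a ppm tolerance
(default 1 ppm, appropriate to FT-ICR accuracy) and reports the nearest
peak per target; targets whose [M−H]⁻ m/z falls below the export
window's lower bound (the detection cutoff, default 150) are flagged
"below cutoff" and excluded from the measurable denominator. Direct
computation places four DKPs below m/z 150 — cGlyGly (113.036),
cGlyAla (127.051), cAlaAla (141.067), cGlySer (143.046) — so the
measurable DKP count is 173. A match is an m/z coincidence, not an
identification: the isomer space at these formulas is enormous.

## Synthetic-data generator

The generator emulates the four classes' *relational* structure, not
their chemistry:

* **Petroleum** — 25 CH₂ homologous series of 15–40 peaks, KMD drawn
  from a narrow band (mean −20, SD 30 mDa), each series followed by an
  "echo" copy offset +200 mDa in KMD at e^−2.5 ≈ 8 % relative
  intensity; 250 noise peaks.
* **Synthetic** (iterative abiotic reactions) — 18 mass ladders on
  HCN (27.01090), CH₂O (30.01057) or C₂H₄O (44.02621) repeat units
  starting at random masses, with slowly decaying intensity; ladder
  KMD drifts steadily (e.g., +19.3 mDa per HCN step), spreading ordered
  progressions across KMD bins; 250 noise peaks.
* **Biological** — 180 isolated masses with high log-intensity contrast
  (SD 2.5 natural-log units) plus 6 short lipid-like CH₂ series in a
  +50 ± 15 mDa KMD band; 150 noise peaks.
* **Meteorite** — 4500 uniformly scattered masses (KMD effectively
  uniform over the full axis) with moderate contrast; 400 noise peaks.

Intensities are log-normal per series/population so the featurizer's
log-abundance axis sees class-specific contrast. All peaks receive
0.2 ppm RMS seeded mass jitter — realistic FT-ICR accuracy, small
enough not to break 1-ppm biomarker matching. Child seeds come from a
seed sequence over one master seed, so a single integer reproduces the
whole dataset. A `difficulty` knob in [0, 1] interpolates every class
toward one shared random model (1500 common peaks + 250 noise peaks);
at 1 the classes are statistically identical and cross-validated
accuracy collapses to the 25 % chance rate, which is the generator's
own negative control.

What passing the end-to-end benchmark (mean accuracy ≥ 0.9 at 15
components on 40 samples/class, seed 0) shows: the full pipeline —
I/O, filtering, parity split, featurization, fold construction, PCA,
regression — preserves and recovers class structure of the kind these
sample types exhibit. What it does not show: performance on real
spectra, whose within-class diversity (instrument response, matrix
effects, chemical overlap between classes) the caricature generator
deliberately does not model.

## Numerical choices and degenerate inputs

* Empty spectra featurize to the constant floor image (X ≈ 0.0987
  everywhere), not an error; empty *files* are an error.
* Duplicate m/z values are kept as distinct peaks; peak lists are
  sorted ascending on construction.
* Nearest-integer operations round ties half away from zero.
* The brute-force oracle used in tests recomputes the whole transform
  with per-peak linear scans over explicit bin-edge lists and plain
  `math` arithmetic; implementation and oracle agree element-wise to
  10⁻¹² on random spectra (integer count tensors agree exactly).
* Benchmark problem sizes (40 samples/class; 100 oracle spectra of up
  to 2000 peaks) were chosen to exercise the pipeline at realistic peak
  densities while keeping the suite quick to run.

## Known limitations

* The generator is a caricature; none of its accuracy figures transfer
  to real instruments or samples.
* Only the [M−H]⁻ adduct is implemented; multiply-charged species and
  isotopologue patterns are out of scope.
* Formula assignment is consumed, never performed.
* Vendor binary formats are not read; peak lists are delimited text.
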