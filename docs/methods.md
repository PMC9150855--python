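# Methods

## Scope and model of the data

The package analyzes centroided (processed-mode) MALDI-MSI data of in-situ
released plant *N*-glycans, acquired in positive mode over m/z 1000–5000 and
annotated as sodiated ions. A dataset is a set of tissue sections, each a
pixel grid of centroid lists with a genotype label (WT or MUT, the latter
standing for nodules infected by a nitrogen-fixation-deficient symbiont).
All statistics run on raw centroid intensities; no normalization is applied
to data that feeds scores, AUC or ratios (TIC-style normalization is
deliberately absent, matching how such data are exported for annotation).
The 99th-percentile hot-spot clipping used when rendering PNGs is cosmetic
and never touches statistics.

## Composition chemistry

Glycans are identified at composition level: integer counts of hexose,
*N*-acetylhexosamine, deoxyhexose (fucose) and pentose (xylose). Residue
monoisotopic masses (Hex 162.052824, HexNAc 203.079373, dHex 146.057909,
Pent 132.042259, water 18.010565, all Da) are fixed 6-decimal constants;
they reproduce the three reference sodiated m/z values (2233.797, 1925.687,
1722.607 for Hex₅HexNAc₄dHex₃Pent₁, Hex₄HexNAc₄dHex₂Pent₁,
Hex₄HexNAc₃dHex₂Pent₁) to three decimals, which requires the electron-mass
correction in the sodium adduct delta (+Na = 22.989218 Da).

Structural classes are count rules, with two documented caveats:

* **Lewis-a capacity** = max(0, min(Hex−3, HexNAc−2, dHex−1)). One dHex is
  reserved as putative core fucose, so a composition is called Lewis-a
  capable only if a second fucose plus an antennal GlcNAc and Gal are
  available. This is a composition-level inference; linkage isomers cannot
  be distinguished.
* **Core-fucosylated** is flagged on dHex ≥ 1 even though a lone dHex might
  be an antennal fucose; the label is explicit rather than isomer-inferred.

Paucimannose is bounded at Hex ≤ 4 with HexNAc = 2 (core modifications
allowed); oligomannose requires HexNAc = 2, Hex ≥ 5 and no Fuc/Xyl; complex
requires HexNAc ≥ 3. These three backbone classes are mutually exclusive by
construction.

The searchable database is enumerated combinatorially (defaults
Hex ≤ 9, HexNAc ∈ [2, 6], dHex ≤ 3, Pent ≤ 1, sodiated m/z within
1000–5000). A curated plant *N*-glycan database would differ in membership;
the enumeration is a superset adequate for annotation scoring and synthetic
studies, and its bounds are configuration.

## Isotope envelopes

Envelopes are aggregated isotopologue distributions computed by per-element
polynomial convolution (exponentiation by squaring, truncated to k peaks and
renormalized). Element distributions: ¹³C 1.07%, ²H 0.0115%, ¹⁵N 0.364%,
¹⁷O 0.038% at +1 and ¹⁸O 0.205% at +2. Peak mass offsets use the ¹³C
spacing (1.0033548 Da), which dominates CHNO envelopes at glycan size; the
sub-mDa aggregation error is far below the ±3 ppm extraction window.

## MSM annotation score

The metabolite-signal-match score is the product of three components, each
in [0, 1], computed per (section, composition, adduct):

* **spectral** = 1 − ½·Σ|pᵢ − qᵢ| where p is the theoretical envelope and q
  the observed per-isotopologue total intensities, both normalized over the
  first k peaks (default k = 3 for simulation, 4 for annotation of real
  data; configurable). An absent principal ion scores 0 and is flagged.
* **spatial** = Σ wᵢ·max(0, ρᵢ) where ρᵢ is the Pearson correlation between
  the principal ion image and the i-th subsequent isotopologue image over
  occupied pixels, weighted by theoretical abundances w. Undefined
  correlations (constant images) score 0 with a flag rather than raising,
  so absent glycans cannot crash batch runs.
* **chaos**: the principal image is binarized at 30 upper-quantile levels of
  its positive values; 4-connected components are counted at each level and
  the score is 1 − (mean count − 1)/(N/2 − 1) clipped to [0, 1], N being
  the occupied pixel count. A single coherent anatomical blob scores near
  1; salt-and-pepper noise scores near 0.

These concrete formulas preserve the published score's structure (envelope
agreement × isotopologue colocalization × spatial coherence, multiplied
into one [0, 1] score) while being exactly testable; they are not intended
to reproduce any server implementation's numbers.

**Decoy FDR.** For every target annotation, d (default 3) implausible
adducts (Cr, B, Ti, Mn, Co, Ni, Cu, Zn, Ag, Sn deltas) are sampled with a
fixed seed and scored through the identical pipeline. For a target score s,
FDR(s) = (#decoys ≥ s / d) / (#targets ≥ s), monotonized to be
non-increasing in score and capped at 1. Conventional reporting levels are
0.05/0.1/0.2/0.5. Annotation is per section, not pooled, because section-
level annotation counts are the natural reporting unit for serial sections.

## Genotype discrimination

AUC is computed by the midrank Mann–Whitney formula, oriented so AUC > 0.5
means higher intensity in the mutant; ties count one half. Calls use
AUC > 0.6 (up), < 0.4 (down), boundaries inclusive to non-significant.
Quality bands are assigned on max(AUC, 1−AUC): [0.6, 0.7) poor, [0.7, 0.8)
fair, [0.8, 0.9) good, ≥ 0.9 excellent — the folding means down-regulated
glycans receive bands too. The comparison unit defaults to pooled occupied
pixels across each group's sections (mirroring ROC over all spectra);
a section-mean mode exists because aggregation level is a genuine free
choice with serial sections. No multiple-testing correction is applied to
AUC calls, matching field practice for this analysis. Note that pooled
pixels are spatially autocorrelated, so pixel-level AUC should be read as a
descriptive effect size, not an inferential p-value surrogate.

## Pathway ratios

For a (product, precursor) pair the statistic is mean product pixel
intensity / mean precursor pixel intensity over the occupied (optionally
masked) pixels of the chosen sections, per genotype, plus the WT/MUT fold of
the two ratios. Mean (not median) is the default reading of "intensity
ratio"; median is available. A zero-signal precursor yields NaN with a
flag. Because planted abundance is spread over k isotopologue peaks, ratios
of raw principal-ion images carry a small envelope correction
(first-peak abundance ratio of the two compositions); genotype folds cancel
this factor exactly, which is why fold recovery is the primary planted
check. Default pairs cover both late-maturation branches: truncation
(paucimannose product over a HexNAc₃ precursor sharing core modifications)
and Lewis-a conversion (capacity-bearing product over its same-antenna
precursor); the pair set is configuration, not hard-coded.

## Differential proteomics

The chain is log2 transform → row filter (≥ 3 observed values in at least
one group) → per-column imputation from Normal(mean − 1.8·sd, (0.3·sd)²)
using observed column moments → median normalization → paired two-tailed
t-test. Stage order is enforced; calling a stage on a table in the wrong
state raises. Significance: |log2FC| > 0.5 and p < 0.05; rows with zero
within-pair variance are flagged degenerate (p undefined, never
significant). Median normalization subtracts each sample's median and adds
back the grand median of the input table; this equalizes sample (hence
group) medians to machine precision. One consequence worth knowing: adding
a constant to one sample is undone in every between-sample contrast, but
the data-dependent grand median can shift all values by one global
constant — location *contrasts* are exactly invariant, absolute location is
not. The "scaled for global abundance variation" step of the original
workflow is under-specified upstream; group-median equalization is this
package's documented interpretation.

The Lewis-a join returns accessions having at least one glycopeptide whose
composition has Lewis-a capacity ≥ 1, with supporting compositions listed;
unparseable composition rows are skipped with a log message.

## Synthetic nodule phantoms

`make_phantom` draws a near-circular nodule (boundary at 0.46·min(w, h)
pixels) with, inward: outer cortex, a sclerenchyma ring of thickness
round(45 μm / pitch) pixels built from rounded-radius digital shells (so
even a 1-pixel ring is topologically closed under 4-connectivity), inner
cortex with four small vascular bundles, and an infection zone tiled by a
seeded disk process of infected cells (~70 μm across) over uninfected
interstitial tissue, plus an uninfected central aggregation (mutant
phantoms only, emulating the centrally reduced glycosylation of mutant
nodules). Everything is deterministic given the seed.

`simulate_dataset` plants per-glycan abundances as zone profile ×
base intensity × genotype factor × LogNormal(σ = 0.3, mean 1), and emits per
occupied pixel a centroided spectrum containing each glycan's first k
sodiated isotopologue peaks with N(0, 1 ppm) mass jitter, an additive
exponential intensity baseline, five hexose-oligomer (Hex₈–Hex₁₂) starch
interference peaks, and 20 uniform random noise peaks. The default zone
profile places sclerenchyma highest (1.0), infected cells 0.8, uninfected
cells/cortex/vasculature 0.1–0.3. The default 12-glycan panel encodes the
study conditions: four conserved paucimannose glycans (factor 1), two
complex truncation precursors at mutant factor 2 (planting a WT/MUT
truncation-ratio fold of 2), four Lewis-a and two oligomannose glycans at
mutant factor 3. Default study size is 2 genotypes × 3 sections of
120 × 120 pixels.

What the phantom does *not* model: ionization suppression and matrix
effects, isotopic interference between overlapping envelopes, profile-mode
peak shapes, section-to-section thickness variation, and spatial
autocorrelation of noise. Passing recovery tests therefore demonstrates the
correctness of the analysis chain under a controlled forward model, not
instrument-level robustness.

`simulate_quant_table` generates paired WT/MUT log2 abundances (protein
baseline N(20, 2), shared per-pair effect sd 0.15, replicate noise sd 0.25)
with a planted MUT−WT shift (default 1.0 on 50 of 1000 rows, five pairs)
and left-censored missingness (dropout probability ∝ 4th power of reverse
abundance rank — the same low-abundance mechanism the downshifted
imputation assumes). Planted rows draw baselines from the upper half of the
abundance distribution, reflecting that differential glycoprotein
candidates in this kind of study come from the well-quantified abundant
proteome; with uniformly placed shifts, imputation noise on censored rows
dominates the paired test for low-abundance rows, which is a real property
of the workflow, visible here by lowering the planted-row baselines. Three
designated carrier accessions double as Lewis-a glycopeptide carriers in
the companion identification table.

## Numerical choices and degenerate inputs

* Extraction windows are relative: half-width = m/z · ppm · 10⁻⁶; pixels
  with no in-window centroid are 0; the reducer (sum default, max optional)
  is configuration because either is defensible for centroided data.
* AUC of two empty groups, empty databases, empty datasets, non-positive
  abundances, continuous-mode imzML, and unknown monosaccharides all raise
  with messages naming the offending item; absent glycans, undefined
  correlations and zero-signal precursors are flagged, not raised, so batch
  runs complete.
* All randomness flows from `numpy.random.default_rng` seeded explicitly;
  per-section streams are spawned from a root `SeedSequence`, so datasets
  are bitwise reproducible and section count changes do not perturb earlier
  sections' draws.
* Problem sizes in the test suite (40–120 px grids, 1–3 sections per
  genotype, 10³–10⁴-row tables, 10³-trial oracles) were chosen as the
  smallest sizes at which the planted effects and nulls are comfortably
  resolved by the statistics under the default noise model.

## Known limitations

* Composition-level annotation cannot separate linkage isomers; Lewis-a and
  core-fucose labels are capacity statements, not structure assignments.
* Pixel-pooled AUC ignores spatial autocorrelation; section-mean mode with
  many sections is the statistically conservative alternative.
* The MSM formulas are this package's own concrete instantiation of the
  three named ingredients; scores are comparable within a run, not across
  tools.
* Annotation counts from an enumerated combinatorial database are not
  comparable to counts from curated databases.
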