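# Methods

`smvk` re-implements, as one tested pipeline, the computational steps of
a spatial multi-omics comparison of microvascular-invasion-positive
(MVI+) versus MVI- hepatocellular carcinoma: boundary geometry on the
Visium spot lattice, data-driven marker-panel selection, gene-signature
scoring, spatially-aware shrunken-centroid (SSC) segmentation of
mass-spectrometry-imaging (MSI) rasters with metabolite-class
enrichment, landmark registration and cross-modal correlation, and
multiplex-immunofluorescence (MIF) single-cell quantification. Because
the pipeline's patient data are not part of the package, every stage is
exercised on a synthetic cohort with planted, recoverable effects.

## Lattice geometry

Spots live at integer `(array_row, array_col)` with constant row+col
parity (the 10x convention); the six neighbors of a spot are
`(r, c±2)` and `(r±1, c±1)`. A spot of a region is a **boundary** spot
when at least one of its six neighbor positions is missing from the
section or carries another region label, otherwise a **core** spot.
Missing neighbors (the tissue edge) deliberately count as "not in the
region", which makes edge spots boundary — the conservative reading of
the rule. Distances are exact Euclidean minima over boundary spots,
always computed from the micrometre centroid coordinates, never from
array indices; the spot pitch is taken from the positions table and
never assumed. The operation is region-generic (`target_region` is a
parameter) so it applies equally to the tumor lesion and to the
capsule. Distance ties resolve to the lexicographically smallest
boundary barcode so results are order-independent.

## Marker panel selection

Marker statistics use log1p counts-per-10k normalization throughout.
For each gene: `log2fc` compares group means of normalized expression
with a 1e-9 floor; `pct1`/`pct2` are detection fractions (raw count
> 0) inside and outside the cluster; p-values are two-sided Wilcoxon
rank-sum (exact for small tie-free samples, normal approximation
otherwise) with Benjamini–Hochberg adjustment within the comparison.

The panel procedure is the published four-step recipe made fully
deterministic and auditable:

1. rank genes by log2FC (top 30) and keep those with `pct1 > 0.8`;
2. seed marker = survivor maximising `pct1 − pct2` (ties: larger
   log2FC, then lexicographic id);
3. companion = survivor with the strongest Pearson correlation to the
   seed across a supplied bulk reference matrix (an explicit, local
   stand-in for a web-tool co-expression lookup);
4. append the a-priori tumor-specificity marker (GPC3 by default).

Each step's candidate set is recorded in an audit trail. Whether step 1
ranks by log2FC or p is not fixed by the published description; log2FC
is the default and exposed as a parameter. When the survivor set has a
single gene the procedure errors rather than silently widening the
candidate pool.

Signature scores follow the module-score convention: genes are binned
into 24 equal-frequency bins by mean normalized expression; each set
gene contributes 100 control genes from its bin and the score is the
mean set expression minus the mean pooled-control expression per spot.
When a bin holds fewer genes than requested the whole bin serves as the
control set — this keeps the degenerate identities exact (constant
matrices score 0 to machine precision; scoring all genes against all
genes cancels exactly) and matches the common implementation.

## MSI segmentation and enrichment

Pixel spectra are TIC-normalized to the global median total ion
current. Spatial smoothing averages each pixel's spectrum over its
(2r+1)×(2r+1) grid neighborhood with Gaussian weights (σ = r/2); the
structurally-adaptive variant (SASA) additionally multiplies by
`exp(−‖x_j − x_i‖²/(2σ_a²))` with σ_a the median neighbor spectral
distance over the image, which preserves sharp region borders.

Segmentation is nearest-shrunken-centroids iterated to a fixed point
(≤100 iterations) from a k-means++ initialization: per-ion statistics
`t_kj = (centroid_kj − mean_j)/(m_k (s_j + s0))` with
`m_k = sqrt(1/n_k + 1/n)` are soft-thresholded by the sparsity
parameter s, centroids are rebuilt from the thresholded statistics, and
pixels join the segment with the smallest standardized squared distance
to the shrunken centroid. Empty segments are dropped, so k is the
*maximum* number of segments. Two numerical choices are deliberate:

- `s_j` is the **global** per-ion standard deviation of the smoothed
  matrix (with `s0` its median), held fixed across iterations rather
  than re-pooled within clusters. This keeps the scaling a fixed
  feature transform, so at s = 0 and r = 0 the iteration is *exactly*
  Lloyd's k-means on the standardized matrix — a limit the test suite
  verifies against an independent k-means — and it avoids the
  instability of rescaling the metric while assignments move.
- the −2·log(prior) term of the classical discriminant is available
  (`use_priors=True`) but off by default for the same reason.

With s > 0 the centroid update is not the minimizer of the assignment
objective, so the summed discriminant score is guaranteed
non-increasing only in the unshrunk limit; the per-iteration objective
is recorded on the model for inspection. Defaults are r=1, k=15, s=3.

Marker ions per segment are the ions with positive shrunken statistic,
ranked descending (top 10 by default). Class enrichment builds, per
metabolite class at the chosen annotation level and over annotated ions
only, the 2×2 table (markers in/out of class × non-markers in/out),
tests it with the two-sided Fisher exact test, and reports the odds
ratio with a Haldane 0.5 correction applied **only** when a zero cell
occurs — so exact tables match an enumeration oracle — plus a log-OR
normal-approximation 95% CI and BH-adjusted q values. Differential
metabolites between two pixel masks use Wilcoxon p-values and log2 fold
changes of mean TIC-normalized intensity with |log2FC| > 1, q < 0.05
defaults (the published volcano's thresholds are unstated; these are
configurable assumptions).

Ion annotation matches observed m/z against a reference table at 5 ppm
relative tolerance, taking the record with the smallest absolute error;
ties break by smaller error then lexicographic name, making annotation
idempotent and independent of reference row order. Negative-mode
rasters are accepted but not analyzed by default.

## Cross-modal registration and correlation

Serial sections differ mainly by scale, rotation and shift, so a
4-degree-of-freedom similarity transform is fitted to matched landmark
pairs by least squares (Umeyama); the residual RMSE is reported.
Raster pixels map through the transform into the spot frame and join
the nearest spot center within half the lattice pitch; per-spot ion
values are pixel **means**, so they are independent of the pixel pitch,
and uncovered spots are missing (NaN), never zero — pairwise deletion,
no imputation. Correlations (Pearson by default) run per sample over
covered spots; zero-variance ions report a missing coefficient. Pooled
estimates are unweighted means across samples with per-sample values
retained. Correlation is at spot resolution because deconvolved cell
proportions only exist per spot.

## MIF quantification

Per channel: rolling-ball background subtraction (radius 15 px),
positivity cutoff = background mean + 3 population SDs measured on a
control region (by default all pixels beyond a 10 µm dilation of the
nuclei — a deterministic stand-in for manually drawn background
regions; thresholds are computed once per image and applied uniformly).
Nuclei are connected components of the thresholded (Otsu by default)
subtracted DAPI channel; objects outside 25–200 µm² are removed — the
area filter applies to the **nuclear** object before expansion — and
survivors expand by 3 µm with contested pixels going to the nearest
nucleus. The per-cell positivity statistic is the mean intensity over
the full expanded cell region (≥ threshold counts positive; a cell with
zero signal never does, so an all-dark channel yields no positives);
a nucleus-restricted mean is available. Ratios use the GPC3+ cell count
as denominator: triple ratio (%) = 100·|STMN1+HMGN2+GPC3+|/|GPC3+|,
with the analogous double ratios, so triple ≤ each double by
construction. Group contrasts of per-image ratios use a two-sided
t test (Welch default; pooled-variance Student available, matching the
published figure legends). Note that rolling-ball subtraction is not
equivariant under intensity rescaling (the ball has a fixed intensity
extent); the thresholding stage itself is, and is tested as such.
Touching nuclei are not watershed-split in this version; the
close-nuclei test documents the supported geometry (non-touching
nuclei, expansion fronts split at the equidistant line).

## Synthetic cohort

The generator emulates the study's tissue architecture on a 40×40-spot
hex lattice at 100 µm pitch: a central tumor disk (radius 1,100 µm), a
closed capsule annulus (width 350 µm, ≥ 2 spot rows by construction —
thinner capsules error), paratumor elsewhere; normal sections are all
paratumor. Counts are negative binomial (var = µ + 0.5 µ²) with
log-normal gene baselines, sparse log-normal region effects and a
per-spot library factor. A triple-positive subpopulation is planted in
tumor spots at prevalence 0.30 (MVI+) vs 0.05 (MVI-), boosting the
panel genes by log2FC 2. The panel baselines (STMN1 1.0, HMGN2 2.0,
GPC3 2.4 expected counts) are set so the planted selection signal is
separated from sampling noise by several standard errors: the boosted
STMN1 clears the pct.1 > 0.8 filter with margin while staying sparse
enough outside the subpopulation to carry the largest pct.1 − pct.2,
and GPC3/HMGN2 are detected broadly enough that their specificity is
clearly lower — the ordering the selection procedure must recover. The
bulk reference matrix shares a latent proliferation factor loading on
STMN1 (1.0) and HMGN2 (0.9) but weakly on GPC3 (0.35), so the
companion step has a planted answer.

Cell-type proportions are Dirichlet draws with region-specific
concentrations; inside the capsule the iCAF concentration grows with
distance from the tumor boundary (monotone planted gradient). The
matched raster lives on its own axis-aligned 100 µm scan grid, related
to the spot frame by a planted similarity transform (default scale 1,
rotation 0.01 rad, shift (30, −20) µm); transforms that would blow the
raster up beyond twice the tissue extent error. Ion intensities are
log-normal around region-dependent means shared across the cohort;
glycerolipid ions are multiplied by 2^(−1) in MVI+ tumor pixels; the
taurine channel is an affine function of the covering spot's iCAF
proportion plus Gaussian noise whose SD is calibrated from the realized
iCAF variance so the sample Pearson correlation matches the planted
ρ = 0.6 (exactly affine, r = 1, when ρ = 1).

MIF fields place 300 disk nuclei (radius 3–4 µm, within the 25–200 µm²
window) on a jittered grid, which guarantees non-overlap by
construction where rejection sampling jams; positive cells paint
nucleus + 3 µm halo at background mean + 8 SD (a warning fires at zero
contrast, the planted negative control). Per-cell marker positivity is
drawn either independently per channel or with an explicit planted
triple rate.

All randomness descends from one integer seed through named
sub-streams (CRC32-keyed children of a `SeedSequence`), so the cohort
is bit-reproducible and no two stages share draws; every planted effect
is exported to a machine-readable `truth.json`.

What the generator does **not** emulate: touching or doubled nuclei,
segmentation errors, batch effects beyond a scalar library factor,
realistic H&E appearance, spectral artifacts (isotopes, adduct
ambiguity) or nonrigid section deformation. Passing tests therefore
demonstrate correctness of the computations and recoverability of
planted effects under clean conditions, not robustness to those
real-data complications.

## Problem sizes and runtime choices

The default test/reproduction conditions are: 1,600 spots × 500 genes
per section (four tumor sections), ~1,500 raster pixels × 24 ions,
one 512×512 px MIF field per image with 300 cells, 100 random lattices
for the geometry oracle, 50-replicate null error-control runs, and a
100-replicate binomially simulated power check for the group contrast
(per-image full-image synthesis at that replicate count would add
nothing to what the end-to-end image test already shows). These sizes
keep the whole suite and the reproduction script to a few minutes on a
single CPU while leaving every planted effect several standard errors
from its detection threshold.
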