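# Methods

## Data model

A field of view (FoV) is one acquired tile: three co-registered 2-D
rasters — CARS, TPEF, SHG — default 152 × 302 pixels at 1 µm/pixel,
stored as 16-bit unsigned integers.  A *sample* is one tissue block of
one patient, imaged as a rectangular grid of FoVs and labelled normal or
tumor as a whole; a patient contributes up to two samples (one of each
tissue).  Grid convention everywhere: row-major (row, col), 0-based,
top-left origin.  On disk a sample is a directory with either a
multi-page TIFF (three consecutive pages per FoV) or per-channel 16-bit
PNGs, plus a CSV sidecar mapping FoV → grid position → channel page/file
and a JSON file with sample metadata.  Channel identity always comes
from the sidecar, never from pixel statistics, and TIFF tags are not
relied on for grid metadata (dialect fragility).

## Tile quality control

Border, hole and saturation tiles carry no usable texture.  The
published procedure was visual; here it is reconstructed as explicit
rules on each tile (all thresholds configurable, defaults in
parentheses):

* a pixel is *foreground* when CARS + TPEF exceeds a fraction (0.05) of
  the combined representable range; SHG is excluded because it is
  legitimately sparse in normal liver;
* **saturation**: more than 1% of pixels with any channel at the dtype
  maximum (65535 for 16-bit);
* **low coverage** (border): foreground coverage below 0.90;
* **hole**: largest 4-connected background component above 5% of the
  tile area.

Rules are evaluated saturation → low_coverage → hole and the first
failure is reported, so a tile that is both mostly empty and holey reads
as low_coverage.  Filtering is idempotent and monotone in the coverage
threshold.  Because no numeric thresholds exist to match, these defaults
reproduce the *intent* of the curation, not its exact tile counts.

## Texture features

Each channel is min–max normalized to [0, 1] per FoV (a constant raster
maps to zeros and is flagged).  First-order parameters use population
moments: mean; sd = √m₂; skewness m₃/m₂^1.5 and non-excess kurtosis
m₄/m₂² (Gaussian → 3), both defined as 0 when m₂ = 0; entropy is Shannon
entropy in bits of the 256-bin equal-width histogram on [0, 1], empty
bins skipped.

GLCMs quantize the normalized raster into 8 equal-width gray levels
(asymmetric pair counting by default; both configurable).  For distance
d the pixel pairs are (row, col) offsets 0° → (0, +d), 45° → (−d, +d),
90° → (−d, 0), 135° → (−d, −d); only pairs with both ends inside the
raster count, and counts are normalized to sum to 1.  From each matrix:
contrast, correlation (0 when a marginal variance vanishes), energy
(= angular second moment Σ P²), homogeneity (Σ P/(1+|i−j|) — the inverse
*absolute* difference moment; note that some libraries use the squared
difference under the same name).  For each distance the four orientation
values are averaged arithmetically.  Distances default to 1, 12, 30
pixels = µm.

Per-channel family subsets define the feature vector.  Named presets:
`full` (17 × 3 channels), `reduced_shg` (17 + 17 + 8, the default — SHG
contributes its first-order parameters plus contrast only, since SHG
correlation/energy/homogeneity are dominated by the sparse-background
geometry rather than fiber texture), `cars_only` (17), and
`first_order_only`.  Degenerate inputs never produce non-finite feature
values by construction.

## Discriminant model

Gaussian class-conditional classifier over the ordered classes
(normal, tumor).  Means are per-class sample means.  The linear variant
pools the within-class scatter with divisor N − K (K = 2); the quadratic
variant uses per-class covariances with divisor n_k − 1.  Priors default
to empirical class frequencies; a uniform option exists (see the null
control below).  When a covariance's condition number exceeds 10⁸ a
ridge ε·(trace/dim)·I is added with ε grown by decades from 10⁻¹⁰ until
conditioning is acceptable; the ε applied is recorded in the model.
This matters in practice: 42-dimensional covariances from a few hundred
tiles are routinely near-singular because GLCM parameters at
neighbouring distances are highly correlated.

Posteriors are computed in log space through the symmetric
eigendecomposition of each covariance and combined with a two-class
logistic normalization, p(tumor|x) = 1/(1 + exp(Δ)) with
Δ = log p(normal,x) − log p(tumor,x); this is overflow-safe and exact at
the symmetry point (Δ = 0 → exactly 0.5).  A tile is labelled tumor iff
its tumor posterior exceeds 0.5; an exact 0.5 resolves to normal
(conservative tie rule, logged).  Models serialize to JSON at full
float precision and classify identically after a round-trip.

## Evaluation

Two hold-out granularities mirror the study design: leave-one-sample-out
cross-validation (LOSO; the benchmark used to select the model type and
feature subset) and a patient-level train/test split whose test side
contains only patients with matched tumor and normal samples.  Metrics
treat tumor as positive.  Pooled (image-level) sensitivity and
specificity coincide with the per-class correct rates; macro (unweighted
per-sample) averages are reported alongside because the two conventions
genuinely differ on unbalanced cohorts, and published figures of this
kind are often a mixture of both.  Model selection scores each
(feature-subset, model-type) candidate by LOSO correct rate, breaking
ties toward fewer features, then linear over quadratic; the candidate
set is channel-structured (the presets above), not the 2⁴² power set.

## Synthetic cohort

The generator's purpose is to exercise every pipeline stage with
realistic *texture* contrast, not photorealism.  One rendering routine
is driven by a continuous motif parameter vector:

* hepatocyte cords: randomly oriented quasi-periodic bands (period
  24 px) with smooth phase jitter, in CARS and TPEF;
* glands/nests: soft rings (mean radius 22 px, bright epithelial rim,
  suppressed lumen) in CARS and TPEF;
* lipid droplets: bright CARS disks (radius ~4 px);
* collagen fibers: gently curved blurred polylines in SHG.

The normal parameter vector has strong cords, no glands, ~25
droplets/tile and ~4 fibers/tile; the tumor vector has glands (~22/tile),
no droplets and dense fibers (~30/tile).  The *separability* knob
s ∈ [0, 1] linearly interpolates the tumor vector from the normal one,
so at s = 0 both classes are draws from the identical distribution —
the built-in null.  Per-sample log-normal jitter (sd 0.08) on amplitudes
and densities emulates inter-patient variability and creates the
within-sample correlation real cohorts have.  Motif fields are scaled to
~22 000 photon counts (Poisson noise by default; Gaussian optional) and
stored as uint16, leaving headroom below the 65 535 ceiling so only the
deliberate saturation artifact saturates; a per-channel floor of 0.18
keeps tissue safely above the QC foreground threshold.  Every FoV draws
from its own random substream keyed by (seed, patient, sample, tile), so
cohorts are bit-reproducible and partially regenerable.  Artifact tiles
(hole ~8% of area, border strip ~25%, saturated disk ~3%) are generated
to violate exactly one QC rule each.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: optical physics (PSF, depth
attenuation, spectral bleed-through), necrosis/fibrosis/steatosis
heterogeneity within a sample, mucinous and homogeneous tumor variants,
stitching artifacts, and formalin-fixation autofluorescence changes.
Benchmark numbers on synthetic cohorts are a stand-in demonstrating that
the pipeline recovers a known texture signal, not an estimate of
clinical performance.

## Benchmark problem sizes and numerical checks

The default benchmark cohort is 8 matched patients × 2 samples ×
30 tiles = 480 full-size FoVs, which keeps the complete LOSO benchmark
at about a minute on one CPU; structural tests run on smaller tiles.
Verified properties include: GLCM equals brute-force pair enumeration
exactly over random rasters, orientations, distances and both symmetry
modes; posteriors match direct Gaussian-density evaluation to < 10⁻¹⁰;
QDA collapses to LDA when class covariances coincide; a fitted linear
model recovers the analytic Bayes accuracy Φ(Δ/2) within 2 points at
2000 training points/class; and LOSO accuracy is non-decreasing in
separability.

Two calibration subtleties in the null (s = 0) checks are worth
recording.  First, pixels within a tile are spatially correlated and
tile-level generative variation dominates pooled pixel histograms, so
the two-sample KS check of class-distribution identity subsamples 20
pixels per tile; pooling everything would reject almost surely even
under a true null.  Second, LOSO itself is biased *below* chance under
the null when priors are empirical: the held-out sample's class is
always the underrepresented one in its training fold (7 vs 8 samples),
which tilts both the priors and the mean geometry against it (measured
0.395 ± 0.041 over 12 seeds, versus 0.484 ± 0.033 with uniform priors).
The null control therefore uses uniform priors and a cluster-aware
interval built from per-sample correct fractions (mean ± t₀.₉₇₅ ·
sd/√n); the positive benchmark keeps empirical priors.

## Maps

Posterior maps are a pure function of (results, discard table, grid
shape, palette).  Palette anchors are fixed so rendering is bit-exact:
orange (230, 120, 20) at p = 1, mid gray (128, 128, 128) at p = 0.5,
light blue (120, 180, 230) at p = 0, interpolated linearly in two
segments; discarded tiles dark gray (60, 60, 60); never-acquired grid
slots black.  Each map is written as a PNG (one block per tile) with a
CSV twin (tile_row, tile_col, state, posterior_tumor).

## Known limitations

* QC thresholds are reconstructions; on real data they need tuning
  against a curated tile set.
* The discriminant model assumes Gaussian class-conditional features;
  heavy-tailed feature distributions (e.g. from necrotic tiles) violate
  this and were a documented source of misclassification in practice.
* The ridge regularizer stabilizes near-singular covariances but is not
  a substitute for feature selection when n per class approaches the
  feature dimension (especially for the quadratic model).
* Entropy and GLCM conventions (256 histogram bins, 8 levels, asymmetric
  counting, per-FoV normalization) are choices among several in common
  use; alternates are configurable but change absolute feature values.
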