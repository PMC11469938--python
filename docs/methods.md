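# Methods

## Scoring model

The pipeline grades pulmonary fibrosis on whole-section histology with
the ordinal Ashcroft scale. A section raster is downscaled by 50% (area
averaging; output dimensions rounded half away from zero, minimum 1;
microns-per-pixel metadata scaled inversely) and partitioned into
512×512-pixel tiles in row-major order, 0-based, half-open (row, col)
coordinates. Partial edge tiles are padded with background white and
keep a `valid_fraction` record, so the tile grid always covers the
raster exactly and reassembles it bit-exactly — the geometry is a true
partition, which heatmap rendering relies on.

Each tile receives one of ten classes: grades 0–8 or *non-alveolar*
(large bronchi / vessels). The whole-section composite score is the
tile-count-weighted mean grade over included tiles,
`(Σ g·n_g)/(Σ n_g)`. Two kinds of tile are excluded identically from
numerator and denominator: non-alveolar predictions, and tiles whose
tissue fraction falls below 5% (blank glass would otherwise dilute the
score toward 0). Excluded counts are reported separately. A section
with no included tiles raises an error rather than returning 0, since a
silent 0 would read as "no fibrosis".

The tissue mask classifies a pixel as tissue iff luminance < 0.92 of
full scale or saturation > 0.08; both thresholds are exposed parameters.
These defaults, and the 5% tile rule, are this package's choices — they
concern background glass, which the scoring design itself leaves open.
We downscale before tissue detection.

## Classifier and training

Training data assembly: tiles are split 75/20/5 into train/validation/
test, stratified per class with largest-remainder apportionment (error
< 1 tile per class per partition; ties in the remainder go to the larger
fraction). Class balancing oversamples, with replacement, every
represented class in the **training partition only** up to the
majority-class count; balancing before splitting would let duplicated
tiles cross partitions and inflate validation agreement, so the split
comes first. Augmentation draws 90°-multiple rotations, horizontal/
vertical flips and multiplicative brightness in [0.8, 1.2] (the ±20%
magnitude is our choice; the transform set is standard for this design).

The reference classifier (`small_cnn`) is a compact convolutional
network implemented directly on numpy: three 3×3 conv blocks
(16/32/64 channels, ReLU, 2×2 max pooling), global average pooling and
a dense softmax head (~25k parameters). Tiles are resized to 32×32 on
ingest, so any square tile size works. Training runs exactly
`epochs` epochs (default 25) of Adam (step size 1e-3, batches of 32),
records validation accuracy per epoch, and returns the weights from the
best-validation epoch (selection rule: strictly-greater accuracy,
earliest epoch wins ties). All randomness — init, shuffling,
augmentation — flows from one seeded generator, so training is
bit-reproducible. At prediction time the tile label is the argmax of
the probability vector with ties broken toward the lower grade
(conservative: under-calls fibrosis) and the non-alveolar class losing
ties.

A second implementation of the same model contract,
`baseline_texture`, classifies by nearest class centroid in a fixed
six-feature texture space (airspace/tissue/collagen palette fractions,
mean luminance, edge density, ring-shape score), z-scored on the
training set. It is deterministic with no iterative training and serves
as a fast oracle in tests; on noiseless synthetic fixtures it recovers
ground truth exactly.

## Agreement statistics

Cohen's kappa is computed from the confusion matrix as
`κ = (p_o − p_e)/(1 − p_e)`, where for a weight matrix `w` (0/1 for the
unweighted case, |i−j|/(K−1) linear, its square quadratic) the observed
and chance agreements are `1 − Σ w·p_obs` and `1 − Σ w·p_exp`. The
degenerate case `p_e = 1` is defined as κ = 1 for perfect agreement and
0 otherwise, and flagged. Unweighted kappa is the default (reports
include all three weightings side by side, since ordinal scales are
often analyzed weighted). Section-level agreement rounds composite
scores half-up to the nearest grade before kappa and also reports Lin's
concordance correlation on the unrounded scores. Non-alveolar tiles are
excluded from agreement by default (they are excluded from scoring); a
flag includes them as an extra class.

## Morphometry and stereology

Positive-pixel rules are explicit per-stain hue/saturation/luminance
ranges, or an exact palette-distance rule for synthetic rasters (which
keeps the oracles closed-form). The real-stain presets are plausible
editable starting points and are **uncalibrated**: the thresholds used
by commercial morphometry software on real slides are not public, so no
numerical equivalence on real slides is claimed. "Total sectional
area" is interpreted as tissue area (background excluded by the tissue
mask); a flag switches the denominator to the full raster.

Lobule volume is displaced-fluid mass over fluid density (default
1.0 g/mL, the density of the displacement fluid not being specified in
the protocol this follows); conversions to mm³ and µm³ are provided.
Whole-lobule marker volume is the mean %-area across serial sections
(spacing 300 µm, carried as metadata) times lobule volume; the
single-section estimate is reported alongside for representativeness
analysis, and the serial-section summary gives mean, SD, CV and each
section's deviation from the lobule mean. No Cavalieri ΣA×t estimator
is fitted, because volume here comes from displacement; Cavalieri is a
natural optional extension.

## Synthetic histology

The generator emulates only what the pipeline needs: an ordinal,
learnable texture scale with exact ground truth. Grade `g` renders a
jittered square alveolar lattice (period 16 px) whose wall thickness
grows strictly with grade (2…10 px) on a trichrome-like palette (pale
airspace, pink parenchyma, blue collagen), overlaid with a fibrous
collagen mass drawn by thresholding a smoothed Gaussian field at the
exact per-grade coverage quantile: 0, 0.05, 0.12, 0.22, 0.35, 0.50,
0.65, 0.80, 0.96 for grades 0–8 (endpoints fixed at 0 and ≥ 0.95 so the
scale spans "normal" to "near-total obliteration"). The non-alveolar
class is a large annulus — a geometric bronchus/vessel surrogate chosen
precisely because it is separable from the grade continuum. I.i.d.
Gaussian pixel noise (sd 8, clipped to [0, 255]) keeps the
palette-fraction oracles computable with tolerance. Default tile side
is 64 px (desk scale); the collagen-palette fraction is strictly
increasing in grade, and a plain texture-feature classifier separates
the default classes at ≥ 90% held-out accuracy, so fixtures are
learnable by construction.

What passing tests on these fixtures shows: the plumbing, formulas,
training loop, agreement statistics and end-to-end score recovery are
correct. What it does not show: performance on real stained slides —
real histology has stain variability, scanner artifacts and grade
ambiguity that the surrogate deliberately omits.

## Problem sizes and numerical choices

The recovery experiments use 60 tiles per class over the 10 classes
(600 tiles; 450 train / 120 validation / 30 test after the 75/20/5
split) and five 4×5-tile sections, all at 64-px tiles — sizes chosen so
the full suite trains and evaluates in well under a minute on one CPU
while leaving every contract exercised. On this corpus the reference
CNN reaches test-partition kappa ≳ 0.95 and recovers section scores to
within 0.06 grades; the deterministic baseline on noiseless fixtures is
exact.

Other numerical choices: composite scores and kappa are exact rational
arithmetic in floating point (oracle agreement asserted to 1e-12);
probability vectors normalize to 1 within 1e-6; downscale interpolation
is anti-aliased bilinear (area-averaging behavior: constants are
preserved exactly); heatmap colors follow a perceptually uniform
monotone ramp over grades 0–8 with neutral gray for excluded tiles
(monotonicity is the contract, the exact ramp is configurable).

## Known limitations

* The classifier architecture is a small CNN, not a large pretrained
  network; it is sized for reproducible CPU training, not for
  state-of-the-art accuracy on real slides.
* Stain profiles for real slides are uncalibrated presets.
* Pyramidal WSI formats (SVS/NDPI), stain normalization and scanner
  metadata are out of scope; inputs are flat TIFF/PNG rasters.
* Tile-level splitting is the default; a per-section grouping option
  would be needed to rule out intra-section correlation leakage when
  several tiles come from the same real slide.
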