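# Methods

`rbscreen` implements a screening pipeline for fundus-like images of the kind
used in retinoblastoma triage: pre-processing, optional colour segmentation,
fused handcrafted + filter-bank feature extraction, wrapper feature selection
by two binary variants of the Arithmetic Optimization Algorithm (AOA), and a
standard two-class evaluation suite.  Everything runs on synthetic data with
known ground truth, so every stage is testable without any image download.

## Synthetic data

**Images.**  A retinoblastoma lesion presents ophthalmoscopically as a
yellowish-white, textured blob on the bright circular retinal field.  The
generator renders exactly these appearance cues: a dark surround, a reddish
circular field (radius `fundus_radius_frac * min(H, W)`, default 0.45) with a
mild parabolic brightness falloff and band-limited texture (white noise
smoothed at `texture_scale` px, default 4, scaled to
`background_noise_sigma` intensity units, default 8), and — for the diseased
class — one disc-shaped lesion (radius uniform in `tumor_radius_range`,
default 8–16 px) whose intensities are multiplied by
`tumor_brightness_gain` (default 1.6), shifted toward yellow-white, and
overlaid with finer texture (half the background correlation length).  The
lesion mask is returned as ground truth.  Specular light spots (saturated
discs placed within 0.35·min(H, W) of the centre, i.e. well inside the
field) can be added together with their exact pixel mask.

What the generator does **not** emulate: vasculature, optic disc, camera
vignetting and illumination gradients beyond the parabolic falloff, lesion
shape irregularity, and inter-patient variability.  Passing tests therefore
demonstrate correctness of the computational stages and recoverability of a
planted signal, not clinical performance.

**Tables.**  The table generator draws `n_samples x n_features` Gaussian
features; a random subset of `n_informative` columns receives a class-mean
shift of `effect_size * noise_sigma` (defaults: 200 x 50 with 5 informative
columns at 2 sigma, balanced classes).  The informative mask is attached as
ground truth.  These defaults are the study conditions used by the
feature-selection recovery tests and the acceptance script.

All generators derive per-item seeds from the dataset seed through a
counter-based `SeedSequence`, so outputs are bit-reproducible element-wise.

## Pre-processing

* **Median filtering** (default 3x3, edge replication) smooths impulse noise;
  RGB images are filtered per channel.
* **Spot removal** treats the image as a diffusing field.  The spot mask is
  first dilated (default 3x3 square) so the hole reaches valid surrounding
  pixels; the hole is then relaxed by Jacobi 4-neighbour averaging until the
  largest per-sweep change is below `tolerance` (default 1e-3 on the [0, 1]
  scale) or `max_iterations` (default 500) is reached.  This harmonic
  (Laplace) inpainting is the transport-free limit of fluid-flow inpainting;
  it satisfies the discrete maximum principle and reproduces affine intensity
  fields exactly.  Note that the stopping rule bounds the *per-sweep* change;
  the distance to the converged harmonic solution can be roughly
  `tolerance / (1 - rho)` with `rho` the Jacobi spectral radius of the hole,
  so callers needing near-exact restoration of large holes should tighten
  `tolerance` (the restoration tests use 1e-6).
* **Augmentation** provides flips, rescaling, random and sliding crops, and
  texture-kernel pasting (hard-pasting a seeded patch of the same image at a
  seeded location).  Labels and lesion masks propagate through every op.

## Segmentation

The background-removal stage follows the classic colour-clustering recipe:
RGB -> HSV, min-max normalization of the hue channel, multi-level Otsu
thresholding of a 64-bin hue histogram (exhaustive search over threshold
tuples maximizing between-class variance — tractable for up to 4 levels),
hue posterization back to RGB, seeded Lloyd k-means on RGB triples (K = 3,
farthest-point seeding after a seeded random first centroid, ties broken by
lowest index), and removal of the cluster whose centroid is nearest pure
white.  The returned image is the *original* with the background cluster
painted with the fill colour, so the stage only ever touches removed pixels.
Segmentation is off by default on the feature path: the lesion/field
contrast that drives the synthetic features does not require it, and the
stage is primarily useful for slide-like inputs with white backgrounds.

## Features

* **Handcrafted (GLCM).**  The image is converted to gray, uniformly
  quantized to `levels` gray levels (default 8), and for each offset
  `(d_row, d_col)` in the default set {(0,1), (1,0), (1,1), (1,−1)} the
  co-occurrence matrix `C(i, j)` counts ordered pixel pairs
  `(p, p + offset)`.  Matrices are symmetrized (C + Cᵀ) and normalized, and
  summarized by contrast, correlation, energy and homogeneity (the standard
  Haralick definitions; degenerate zero-variance marginals report
  correlation 0 with a flag so constant images remain processable).  Default
  vector length: 4 offsets x 4 statistics = 16.
* **Filter bank.**  An untrained, seeded bank of random 3x3 kernels
  (default 8) applied in valid mode (un-flipped kernels, the usual
  feature-extraction convention), plus bias, ReLU and non-overlapping
  max-pooling, flattened with provenance names.  This realizes the
  convolution/activation/pooling feature stack at desk scale; its output
  dimensionality is configuration-determined rather than tied to any trained
  network.
* **Fusion** is concatenation under disjoint name prefixes.
* Before fitness evaluation, columns are standardized using training-fold
  statistics only.

## Feature selection (BAOA-S / BAOA-V)

The continuous AOA keeps M candidate positions in `[0, 1]^D`.  Per iteration
`L` of `N`:

* `MOA(L) = Min + L (Max − Min)/N` (defaults 0.2 -> 0.9) gates exploration
  vs exploitation: a per-coordinate uniform draw `r1 > MOA` selects
  exploration.
* `MOP(L) = 1 − L^{1/alpha} / N^{1/alpha}` (alpha = 5) scales the operator
  magnitude `((ub − lb) mu + lb)` with `mu = 0.499`.
* Exploration regenerates the coordinate as `best / (MOP + eps) * mag` or
  `best * MOP * mag` (even coin); exploitation as `best ∓ MOP * mag`.
  Results are clipped to the bounds.

**Binarization.**  The incumbent best solution is a bit vector.  Its
continuous image — the attractor `best` used by the operators above — is the
soft embedding `center + (bit − 1/2) * spread` with `spread = 0.5`, i.e.
0.25/0.75 on the unit interval.  This choice is deliberate: embedding at the
bounds would freeze the division/multiplication operators for 0-bits (both
map 0 to 0), while embedding at the centre would erase the bit information
altogether.  At 0.25/0.75 every operator can move a proposal across the
threshold in both directions with decaying probability as MOP shrinks.

* **S rule** (BAOA-S): bit = 1 with probability
  `sigmoid(gain_S (x − center))`, `gain_S = 12`.  The sharpened argument is
  needed because raw positions live in [0, 1]: an unsharpened sigmoid there
  spans only [0.5, 0.73] and cannot concentrate the sampling distribution on
  any particular bit string, so the population never converges.  With the
  sharpened rule the sampler behaves like a stochastic threshold with an
  exploration fringe.
* **V rule** (BAOA-V): each bit of the incumbent best is complemented with
  probability `|tanh(gain_V (x − attractor))|`, `gain_V = 1`.  Using the
  *step off the attractor* as the argument is the analogue of velocity-based
  V-shaped binarization: as exploitation steps shrink, flip probabilities
  vanish and the search refines around the best solution, while exploration
  branches keep injecting larger steps (hence flips).

With these rules both variants solve the 20-bit OneMax benchmark
(population 20, 200 iterations) in 20/20 seeded runs across several seed
blocks; the bundled acceptance checks assert ≥ 18/20.

A **literal mode** implements the hill-climbing reading of the method:
single-bit flip (S) or XOR with a sparse random vector (V, per-bit
probability 1/D, at least one flip), with improvement-only acceptance, run
as M independent climbers sharing a global elite.  The optimizer minimizes
throughout; elitism makes the recorded history non-increasing by
construction.

**Wrapper fitness.**  `f(bits) = w * err + (1 − w) * |S|/D` with `w = 0.99`;
`err` is the mean misclassification rate of a 5-NN classifier over seeded
stratified 5-fold inner cross-validation restricted to the selected columns
(training-fold standardization; an empty subset is charged `err = 1`).
Evaluations are cached by bit pattern.

## Evaluation

Confusion-count metrics (accuracy, precision, recall/sensitivity,
specificity, F1) with an explicit undefined flag for 0/0 cases — means are
taken over defined folds only and the defined count is reported, which avoids
silently deflating or inflating averages.  k-fold CV uses a seeded shuffle
and near-equal contiguous folds (plain, with a stratified option);
the three-way split shuffles once and slices 70/15/15 with the training set
absorbing rounding remainders.

## Problem sizes and tie-breaks

The bundled tests and the acceptance script use: 8x8 quantized images at 4
gray levels for GLCM oracle comparisons; 20-bit OneMax with population 20
and 200 iterations; feature-selection recovery on 200 x 50 tables (5
informative columns at 2 sigma) with population 20 and 40 iterations; and a
40-image 96x96 synthetic cohort for the end-to-end run (filter-bank pooling
23 -> 128 bank features + 16 GLCM features).  Equal fitness keeps the
earlier-evaluated solution (stable elitism); k-means assignment ties go to
the lowest cluster id; the initial population is binarized by thresholding
at the domain centre.

## Known limitations

* The filter bank is untrained; it is a fixed random projection with
  CNN-style nonlinearities, not a learned representation, and its features
  are only as discriminative as the planted intensity/texture contrast.
* Harmonic inpainting cannot restore texture inside holes (it is an
  averaging process); restoration accuracy degrades with hole size and
  background curvature.
* The hue-clustering segmentation targets white-background scenes; on
  fundus-like images it is optional and off by default.
* Perfect synthetic metrics (accuracy 1.0 on separable cohorts) say nothing
  about clinical data; they verify the pipeline's mechanics, not medicine.
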