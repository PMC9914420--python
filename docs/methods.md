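# Methods

This note records the scientific and numerical choices behind the package:
what each stage computes, the defaults and why, what the synthetic generator
does and does not emulate, and the known limitations.

## Directional associated histogram equalization

Plain local histogram equalization re-values each pixel from the cumulative
histogram of a window centered on it. The directional variant used here
additionally evaluates the equalization with the processed pixel placed at
each of the eight anchor positions of the window — the four corners and four
edge midpoints, at offsets `(±(n−1)/2, 0)`, `(0, ±(n−1)/2)` and
`(±(n−1)/2, ±(n−1)/2)` from the window center — so the response records edge
orientation. The eight directional images are fused per pixel; the default
rule is the maximum (the minimal reading of "keep the higher-intensity
pixel"), with mean fusion available.

Conventions:

* **Window size** `n = 3` by default, any odd `n` accepted.
* **Borders**: edge-replication padding, so border statistics are not biased
  toward zero.
* **Constant window**: the formula degenerates to 0/0; the anchor value
  passes through unchanged. This preserves the operator's character as an
  edge amplifier — flat regions are left alone.
* **Rounding**: floor(x + 0.5), i.e. deterministic half-up, clamped to
  `[0, L−1]`.

A consequence worth stating explicitly: the operator is *rank-based*. Its
output depends on the pixel's position in the local intensity ordering, not
on absolute brightness, so it amplifies local contrast and discards global
contrast. This drives two design choices recorded below (segmentation
source, synthetic background).

## Finite ridgelet transform

The continuous ridgelet transform is discretized as the finite Radon
transform over `Z_p x Z_p` with `p` prime: direction `k ∈ {0..p−1}` sums the
image over the lines `{(i, (k·i + t) mod p)}` and one extra direction sums
the rows. Each direction partitions the `p²` pixels into `p` lines, so every
projection conserves the total image mass, and two distinct points share
exactly one line, which gives the exact inversion

```
x(i, j) = (backprojection(i, j) − total_mass) / p .
```

This discretization is chosen precisely because it is non-redundant and
exactly invertible (round-trip error is at machine precision; the test
tolerance is 1e−9). Images are center-cropped to the largest prime that fits
before transforming; the resolved `p` is fixed once per dataset so all
feature vectors align.

The 1-D wavelet step uses an in-package periodized orthogonal DWT
(Haar, Daubechies-2, Daubechies-4; default **db4, 2 levels** — a reasonable
compromise between smoothness and support at `p ≈ 61`). Odd-length signals
are extended by repeating the last sample before each analysis step; the pad
is tracked and dropped on synthesis, so reconstruction is exact for any
length. The transform is implemented here because no wavelet library is part
of the supported runtime environment.

The scalar features taken from the transform are, per direction and
sub-band: energy `Σc²`, mean `|c|`, and standard deviation — the minimal
explicit summary of a transform whose use as a feature source is otherwise
unconstrained. Length: `(p+1)·(levels+1)·3`.

## Texture features

**GLRLM.** Intensities are re-quantized to `G = 16` uniform bins (the
conventional choice for 8-bit texture analysis; configurable), maximal runs
are counted along 0°, 45°, 90° and 135°, and seven statistics are computed
per orientation with `len` = number of runs, gray index `a` 1-based:

SRE `Σ M/b² / len`, LRE `Σ M·b² / len`, GLNU `Σ_a(Σ_b M)² / len`,
RLNU `Σ_b(Σ_a M)² / len`, RUP `len / n_pixels`, LGLRE `Σ M/a² / len`,
HGLRE `Σ M·a² / len`. The short/long and low/high pairs follow the standard
definitions their names imply.

**ELTP.** Each pixel's ring of `P = 8` integer neighbors at radius `R = 1`
(the 3×3 ring) is coded against the full-patch mean `ace` with the
full-patch mean absolute deviation `we` as tolerance: `+1` if
`a_p − ace ≥ we`, `−1` if `a_p − ace ≤ −we`, else `0` (the boundary is
inclusive). `we` is floored so a constant patch codes to all zeros. The
ternary pattern is split into its positive and negative binary halves, each
mapped to rotation-invariant uniform bins (patterns with ≤ 2 circular
transitions map to their popcount, the rest to one shared bin) and
histogrammed. Comparisons are carried out in exact integer arithmetic
(cross-multiplied by the patch area), so two properties hold *exactly* on
integer images rather than up to float rounding: histograms are invariant
under quarter-turn rotations, and intensity inversion swaps the positive and
negative channels.

**Moment invariants.** Central moments to order 3 about the intensity
centroid (translation-invariant by construction) and the seven classical
rotation invariants of the normalized moments, computed via scikit-image.

**Assembly.** The feature vector is the fixed-order concatenation
GLRLM (28) | ridgelet stats | Hu (7) | ELTP histograms (20), restricted to
any configured subset; all blocks are extracted from the AHE-enhanced image,
the ridgelet block from its prime crop. A hash of the extraction
configuration stamps every vector and feature table; mixing configurations
within a dataset raises.

## Classification

A fully connected network with one hidden layer of
`max(8, n_features / 2)` logistic units and a logistic output, trained by
back-propagation (Adam, learning rate 0.01, 500 epochs, fixed seed) on
standardized features; standardization parameters are frozen at training
time. The L2 penalty defaults to **1.0**, deliberately strong: the assembled
vector is typically much wider (hundreds of ridgelet statistics) than the
training set, and an unregularized net overfits the wide uninformative block
at the expense of the discriminative texture features. All settings are
config-exposed. Prediction is an explicit forward pass through the stored
weights, so a serialized model (plain JSON) reproduces its scores exactly.

Scores are thresholded at 0.5 with ties called abnormal — in a screening
context the costlier error is the missed lesion. Evaluation uses stratified
k-fold cross-validation (k = 2 by default; stratification protects the
small-n regime), per-fold misclassification errors `C(k)`, their mean `mu`,
and pooled confusion counts with the derived metric suite. Ratios with zero
denominators (e.g. LR+ at specificity 1) are reported as NaN, never raised.

## Segmentation

Abnormal images are thresholded (Otsu), cleaned morphologically, and reduced
to 8-connected components of at least `min_area = 25` px with a disk of
radius 3 as the default structuring element (both configurable; nothing in
the problem pins them). Erosion uses the fit-inside convention with
outside-image pixels as background.

Two deliberate deviations from the "obvious" pipeline, both forced by
measurement:

* **Binarization source.** Thresholding operates on the *un-enhanced*
  grayscale image by default (`source="enhanced"` is available). The
  enhancement is rank-based: a uniformly brighter lesion interior has the
  same local rank statistics as background, so the enhanced image carries no
  global separation for a threshold to find — Otsu on it cannot recover a
  lesion interior even in principle. The enhanced image drives feature
  extraction; the raw grayscale drives thresholding.
* **Morphology order.** The default is closing *then* opening. A thresholded
  textured lesion is riddled with sub-element gaps (its own texture dips
  below threshold); opening first erases the whole lesion (measured mean
  Dice 0.07 on the synthetic world), whereas closing first solidifies it and
  the subsequent opening removes background specks (mean Dice 0.98). Both
  orders and the single operations remain available.

## Synthetic cervigrams

The generator emulates the regime of a screening image bank: 64×64 RGB
images with a dominant red cast, a smooth linear illumination gradient
(amplitude 25 counts across the frame) over a base intensity of 120, and —
in abnormal images (probability 0.5) — one random ellipse (semi-axes 8–14 ×
6–12 px, uniform orientation) whose interior adds a +60 brightness offset,
Gaussian speckle (sd 18) and horizontal sinusoidal stripes (amplitude 25,
period 4 px). The mask delimits the ellipse exactly; label 1 iff the mask is
nonempty; everything is driven by one seeded generator, so datasets are
bit-reproducible.

The background has **zero pixel noise** by default. This is both the
faithful model — normal epithelium in a blurred photograph is locally flat,
while acetowhite lesions show punctation/mosaic microtexture — and the
property that makes the generated classes separable *by construction* in the
features this pipeline extracts: the rank-based enhancement stretches any
i.i.d. background noise to full range, erasing class structure, whereas
locally constant background windows pass through the equalizer's degenerate
case untouched. The lesion then differs from background in exactly the
measured properties: long vs short gray-level runs, zero vs saturated
ternary codes, isotropic vs striped run structure.

What a green end-to-end test therefore establishes: the pipeline recovers a
class difference that is expressed in run-length and local-ternary structure
and localizes a lesion whose brightness separates under a global threshold.
What it does not establish: performance on photographic cervigrams —
specular highlights, the os, mucus, vignetting of real optics, color
variation and lesions without a brightness offset are all outside the
generator's world, and no clinical claim follows from these tests.

## Numerical conventions and degenerate inputs

* Grayscale conversion: Rec.601 luma, rounded half-up.
* Constant images: enhancement returns them unchanged; binarization returns
  an empty mask with a warning; the ELTP codes are all zero; training on
  constant features returns a model flagged `degenerate`.
* Empty vs empty masks score Dice 1.0.
* The cross-validation splitter, network initialization and the generator
  all derive from explicit integer seeds; rerunning a pipeline with the same
  config and seed reproduces `features.csv` and `metrics.json` byte for
  byte.

## Known limitations

* The finite-geometry Radon directions are not uniformly spaced angles;
  directional selectivity is exact in the finite sense but not calibrated to
  degrees.
* The ELTP implementation supports the exact integer rings `P ∈ {4, 8}`;
  interpolated rings (arbitrary `P`, sub-pixel radius) are not implemented
  because they forfeit the exact rotation invariance.
* Feature-vector length depends on the resolved prime `p`; datasets with
  mixed image sizes share the smallest admissible `p`.
* Run-time scales linearly in image count; the pipeline is single-threaded.
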