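# Methods

## The problem this package models

Photo transects over abyssal nodule fields have a characteristic statistical
structure: a quasi-homogeneous soft-sediment background, dense dark
manganese-nodule speckle, and *rare* megafauna (well under one individual per
square metre) whose visual appearance differs from the background. The
workflow exploits exactly this structure — organisms are detectable as
*anomalous superpixels* without any labels — and every design choice below
should be read against it.

## Synthetic survey generator

The generator is first-class, tested code: it defines the conditions under
which the rest of the package is validated.

* **Background**: base sediment tone (0.55, 0.50, 0.44) plus a smooth
  low-frequency intensity field (Gaussian-filtered noise, σ = image/8,
  amplitude 0.04) plus per-pixel Gaussian noise (`noise_sigma`, default
  0.02). Nodules are dark ellipses (semi-axes 3.5–6.5 px, 45–60 % of the
  local brightness), Poisson-distributed with mean `nodule_density` = 120
  per 256×256 scene. Nodule size and density were chosen once so that
  nodules survive Gaussian pre-smoothing and the segment-size floor,
  yielding the ~10²–10³ superpixels per scene the segmentation defaults are
  specified to produce.
* **Fauna**: Poisson mean `fauna_rate` = 2 instances per image, drawn from a
  weighted palette of six rendered morphotypes (ophiuroid-like disk+arms,
  sponge-like fan, anemone-like disk, urchin-like spiked star, holothurian-
  and xenophyophore-like blobs). Colors are pale or saturated tones displaced
  from the sediment, as epibenthic megafauna appear against brown abyssal
  sediment; the **xenophyophore entry is deliberately low-contrast**
  (0.60, 0.55, 0.48 vs. sediment 0.55, 0.50, 0.44) to emulate camouflaged
  tests that are genuinely hard to detect. Contrast is a free configuration
  parameter, not calibrated against any real survey. Ground-truth boxes
  tightly enclose rendered pixels.
* **Distractors**: paired saturated-red laser dots (radius 3 px, 20 px
  apart; Poisson mean 0.5 pairs/image) and near-black "water column" blobs
  (mean 0.3/image). They are recorded separately from ground truth — they
  are exactly the false-positive classes the post-processing step exists to
  remove.
* **Navigation**: a locally straight track at 0.26 m s⁻¹ (~0.5 kn) with
  images every 10 s (0.1 Hz) and fixes at twice that cadence; altitude
  drifts sinusoidally inside the 1.5–3.5 m band.
* **Randomness**: one master seed; each scene uses an independent
  counter-based substream (`SeedSequence(seed, spawn_key=(index,))`), so any
  scene is reproducible in isolation and surveys are bit-identical across
  runs.

What the generator does **not** emulate: perspective and lens distortion,
altitude-dependent scale and illumination falloff, overlapping/occluding
organisms, sediment texture gradients, image compression artifacts. Passing
tests therefore demonstrate the *mechanics* of the workflow under its stated
rarity/contrast assumptions, not performance on real imagery — on real
surveys the segmentation scale, Gaussian width and fauna/background contrast
all have to be re-tuned.

## Superpixels

Graph-based (Felzenszwalb–Huttenlocher) segmentation via scikit-image with
Gaussian pre-smoothing. Defaults `scale=100`, `sigma=1.0`, `min_size=50`,
`max_area_fraction=0.25`: on default synthetic scenes this yields ~130
segments, the sediment forming one dominant segment that the area-fraction
cutoff removes. Boxes are half-open `[x_min,x_max)×[y_min,y_max)` in 0-based
pixel coordinates throughout the package. Each retained segment is cropped
to a square window of side max(box width, box height) centered on the box
center (window origin = floor(center − side/2)), clipped to the image,
edge-replicated back to square, and bilinearly resampled to
`patch_size` (module default 64; the pipeline uses 32 — see *Problem sizes*).

## VAE features

A dense variational autoencoder implemented directly in numpy:
flatten → ReLU(hidden 128) → (μ, log σ²) of a `latent_dim`=100 diagonal
Gaussian; decoder mirrors with a sigmoid output. Training minimizes
per-pixel MSE + β·KL, KL = ½·Σ(μ² + σ² − 1 − log σ²), with the
reparameterization z = μ + σ⊙ε (training only) and Adam (lr 10⁻³). Log σ²
is clipped to ±10 for numerical stability; the KL term is asserted
non-negative every batch; a non-finite loss raises an error naming the
epoch. Inference uses μ only, so features are deterministic.

Two deliberate choices:

* **Dense, not convolutional.** The package targets single-CPU training in
  seconds–minutes with no deep-learning framework dependency; at 32–64 px
  patches a dense encoder separates the synthetic patch populations, which
  is the property the downstream anomaly detector needs. The encoder is an
  interface — any patch→feature model can replace it.
* **β = 0.1/n_pixels.** The 1/n_pixels scale makes the per-pixel MSE
  commensurate with the per-sample KL (the canonical sum-over-pixels
  formulation); the extra factor 0.1 prevents posterior collapse, which at
  β = 1/n_pixels empirically flattens every latent mean to ~0 on
  low-variance seafloor patches and erases the rare-patch separation the
  isolation forest depends on.

`project_2d` is plain top-2 PCA (scikit-learn) on the feature matrix, for
the diagnostic "background clusters at the origin, anomalies at the
periphery" view.

## Isolation forest

Implemented from scratch (scikit-learn's implementation serves only as an
independent cross-check in tests). `n_trees`=100 trees on uniform
subsamples of ψ=256 rows, height limit ⌈log₂ψ⌉; at each node a uniformly
random attribute and a uniformly random split value in (min, max) of that
attribute within the node; attributes constant at a node are resampled up
to d times before the node becomes a leaf. Scores follow

    s(x) = 2^(−E[h(x)]/c(ψ)),  c(n) = 2(ln(n−1) + γ) − 2(n−1)/n,  c(1) = 0,

with c(leaf size) added at truncated leaves. Flagging is ranked top-k:
exactly ⌈contamination·n⌉ highest scores (ties to the smaller patch id).
The default contamination 0.4 is intentionally high — the goal is to flag
camouflaged organisms too and let the downstream filter remove the false
positives.

## Weak-annotation post-processing

Two selectable strategies, because percentile thresholding demonstrably
retains laser points and dark patches (they *are* anomalous, just not
fauna):

* `threshold`: keep scores strictly above the linear-interpolation
  percentile (default 75th) of the score vector.
* `classifier` (default): a small binary patch classifier — 16×16
  downsampled pixels into a 64-unit MLP (scikit-learn) behind a generic
  patch→probability interface — trained on positive/negative examples
  picked from the score-sorted review queue. In the pipeline, the expert
  picking those examples is emulated from synthetic ground truth: a flagged
  patch is a positive iff its box overlaps a planted fauna box (IoU > 0);
  negatives are capped at 4× the positives to bound class imbalance.

Weak annotations carry the superpixel's own bbox (no box invention) and its
anomaly score. Labeling copies the morphotype of the max-IoU overlapping
ground-truth box (the emulated expert); the label vocabulary is the ten
morphotype classes. The train/validation split (default 90/10) is grouped
by scene — stricter than a purely random split — so near-duplicate
superpixels of one image can never leak across the split.

## Detection evaluation

COCO-style semantics restated explicitly: greedy per-class NMS by
descending confidence (IoU > threshold suppresses); greedy
confidence-ordered matching to the unmatched truth with highest
IoU ≥ threshold; 101-point interpolated AP per class, AP@.50:.95 as the
mean over thresholds 0.50:0.05:0.95; size strata small < 32², medium
[32², 96²), large ≥ 96²; AR_k caps detections per scene at k ∈ {1,10,100}
and averages recall over the ten IoU thresholds. Truths outside a size
stratum are ignorable (detections matching them count neither way). Empty
strata report NaN, never 0, and means skip NaN — a sentinel, so small
synthetic scenes cannot silently deflate the summary. The confusion matrix
uses class-agnostic matching with background row/column; row sums conserve
truth counts.

The `oracle_detector` replaces the out-of-scope trained two-stage detector:
it drops truths (miss rate), jitters corners, relabels via a confusion
matrix, and adds Poisson false positives at lower confidence, so evaluation
and ecology are exercisable at any chosen noise level, including the
zero-noise identity case used for parameter-recovery tests.

## Ecology

Images are georeferenced to the nearest navigation fix in time (ties to the
earlier fix; gaps beyond `max_gap_s` reported as unresolved, never silently
dropped). Footprint = 4a²·tan(fov_x/2)·tan(fov_y/2) from altitude a with a
64°×64° default field of view (config-overridable). Abundance divides the
detection count by the summed footprint of **all** surveyed images.
Diversity is the exponential of Shannon entropy over morphotype
proportions. For gridding, lon/lat are projected to planar metres by a
local equirectangular projection about the mean latitude (adequate at
survey scale); cell index is floor(x/cell), floor(y/cell) with 200 m cells,
a cell's footprint summing the images whose centers fall in it. No overlap
correction between consecutive images is applied; counts are assigned to
the image-center position without within-image refinement.

## Pipeline

Ten stages (`simulate` … `ecology`); each writes versioned outputs plus a
run manifest (config hash, global and stage seed, output SHA-256s) and
never mutates upstream artifacts. The global seed fans out to per-stage
seeds by hashing the stage name, so any stage is independently
reproducible. The YAML config is schema-validated with unknown keys
rejected before any computation.

## Problem sizes

The default pipeline scales are the package's own choices for single-CPU
runs: 256×256 scenes, 100-image surveys for end-to-end validation (three
seeds), 32 px pipeline patches, 16 VAE epochs, 100 trees. A full 100-image
pipeline run takes on the order of a minute on one core. The superpixels
module default patch size remains 64 for standalone use.

## Known limitations

* Synthetic contrast, not photorealism: results bound the mechanics, not
  field performance (see generator section).
* The dense VAE underfits texture; on real imagery a convolutional encoder
  behind the same interface would be preferable.
* The emulated expert (ground-truth overlap) is optimistic about label
  quality relative to a human annotator facing ambiguous morphotypes.
* Abundance ignores footprint overlap between consecutive images; at
  0.26 m s⁻¹ × 10 s spacing and a 1–4 m altitude band, successive footprints
  can overlap, biasing the surveyed-area denominator low.
* The isolation forest's scoring is O(n_trees · depth) per patch in pure
  Python; it is sized for 10³–10⁵ patches, not millions.
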