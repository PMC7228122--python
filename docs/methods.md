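# Methods

## The retrieval model

`otolookup` turns a classification CNN into a content-based image
retrieval system.  A backbone maps an image to a pooled feature vector
`f ∈ ℝ^F` (the output of its global average-pooling layer) and owns a
final fully connected layer `W ∈ ℝ^{F×C}`, `b ∈ ℝ^C` over the `C = 3`
diagnostic classes (middle-ear effusion, normal eardrum, tympanostomy
tube).  Every database image is projected to a class-score vector
`r = fᵀW + b`; stacking the rows gives the `N × C` lookup table.  A
query is projected identically and the nearest rows under Chebyshev
(`max_j |x_j − y_j|`) or cosine (`1 − x·y/‖x‖‖y‖`) distance are
returned as the most similar images.

Assumptions worth stating explicitly:

- Retrieval quality is inherited from classification quality: two
  images are "similar" exactly when the classifier assigns them similar
  class-score vectors.  The model does not capture within-class visual
  similarity beyond what the class scores encode.
- The lookup rows are raw pre-softmax scores, not probabilities.  A
  `normalize` flag optionally L2-normalizes rows and queries (off by
  default); under cosine distance normalization is a no-op, under
  Chebyshev it changes the geometry.
- The FC bias is included in the projection by default (`use_bias`),
  which keeps the identity "projected vector = the network's own
  pre-softmax output" exact; disabling it gives the bare `fᵀW` product.
- The retrieval database contains training images only; test images are
  never inserted.

## Backbone and transfer learning

The backbone is a contract (`Backbone`): pooled features plus an FC
projection, with a frozen-parameter hash for freeze-integrity checks.
The shipped implementation, `TinyCNN`, has three 3×3 convolution blocks
(3→16→32→`feature_dim`, ReLU, 2×2 mean pooling after the first two,
global average pooling after the third) followed by the FC head.  The
convolution filters are He-initialized from a seeded generator and
**never trained**: they play the role of the frozen pretrained stages
in transfer learning, providing a fixed nonlinear color/texture
embedding.  Layer bookkeeping: 11 named layers (conv/relu/pool ×3, gap,
fc, softmax), of which the first 9 are frozen and the trainable tail is
the FC layer plus its softmax/cross-entropy head.

With frozen features, head retraining is seeded mini-batch SGD
(momentum 0.9) on softmax cross-entropy over the pooled features —
i.e., softmax regression.  Defaults: 200 epochs, batch size 32,
learning rate 0.05; these are generous for the feature scale the conv
stack produces and converge in well under a second at the problem sizes
used here.  `epochs=0` is an exact no-op.  Per-epoch validation
accuracy is recorded and returned.

Input convention: images are bilinearly resized to the backbone's
input size (default 32×32) and scaled to [−1, 1].  Feature extraction
is deterministic given the backbone state.

## Synthetic data generator

The generator emulates the structure real otoscope frames give the
pipeline, not their photorealism:

- a bright elliptical "drum" inscribed in an inner content box, so the
  luminance bounding box *is* the box — ROI recovery is exactly
  testable;
- an exactly-black margin outside the box (value 0 in all channels),
  default 10% of the smaller dimension;
- a solid-white timestamp block inside the bottom-right of the content
  box, sized to sit within the preprocessing module's default removal
  region after cropping;
- class palettes in HSV: effusion = warm amber (hue 0.07, saturation
  0.60), normal = pink (hue 0.93, saturation 0.40), tube = desaturated
  gray-blue (hue 0.55, saturation 0.18) plus a small bright
  low-saturation ellipse; per-image hue jitter SD 0.01, low-frequency
  Gaussian brightness texture (amplitude 0.06 of the value channel).

A `separability` parameter `s ∈ [0,1]` linearly interpolates each
class's hue/saturation center between one shared palette (`s = 0`:
classes statistically identical, including the tube ellipse whose
contrast scales with `s`) and the disjoint palettes above (`s = 1`).
Defaults are 96×128 pixels, 8-bit RGB, landscape aspect like typical
otoscope stills.  Everything flows from one seed; identical specs give
bit-identical image sets.

What passing tests on this data do **not** show: robustness to specular
highlights, wax, motion blur, focus variation, illumination shifts, or
the subtle within-class spectrum of real eardrums.  The generator makes
class structure *controllable* (separable vs. chance-level), which is
what the pipeline's correctness properties need; it makes no claim of
clinical difficulty.  An optional `blur_sigma` adds Gaussian blur for
quality-sensitivity experiments.

## Preprocessing and augmentation

- Margin removal binarizes Rec. 601 luminance at a fixed threshold
  (default 10 of 255 — JPEG-black borders are near-zero but not zero;
  Otsu was rejected as unstable on mostly-dark images) and takes the
  first/last foreground row and column as a half-open 0-based box.
- Timestamp removal zero-fills the bottom 8% × right 25% rectangle,
  preserving geometry; it is idempotent.
- Augmentation draws one affine transform per call: optional horizontal
  and vertical flips (fair coin each, when enabled), rotation uniform
  over the full circle, scale uniform in [0.7, 2.0], horizontal and
  vertical shear uniform in [0°, 45°], integer translations uniform in
  [−30, 30] px.  Resampling is bilinear about the image center with
  black fill; output shape equals input shape.  A degenerate spec is
  the exact identity (short-circuited, so no resampling error).
- Class balancing oversamples each minority class with augmented copies
  of members resampled with replacement; majority classes pass through
  untouched.
- Order of operations: margin crop → timestamp removal → (training
  only) augmentation.

## Handcrafted baseline

`f1 = [HSV histogram | color autocorrelogram | color moments | Gabor]`.

- HSV histogram: joint 8×2×2 bins, L1-normalized.
- Autocorrelogram: RGB uniformly quantized to 64 colors (4 levels per
  channel); for each color `c` and chessboard distance
  `d ∈ {1,3,5,7}`, the probability that a pixel at L∞ distance exactly
  `d` from a `c`-colored pixel is also `c`.  Out-of-image neighbors are
  excluded from the denominator.  Note that under the L∞ ring at
  `d = 1` the four diagonal neighbors of a checkerboard pixel share its
  color, so a 1-pixel checkerboard has value 7/15 on an 8×8 board, not
  zero; exactness is verified against an all-pairs counting oracle.
- Color moments: per-channel mean and population standard deviation.
- Gabor: bank of 4 scales × 6 orientations; center frequencies
  geometrically spaced in [0.1, 0.4] cycles/pixel (lower frequencies
  would need kernels wider than the working image sizes), orientations
  evenly spaced over [0, π).  Kernels are DC-corrected (complex mean
  subtracted) and applied on a symmetrically padded image, so constant
  inputs respond exactly zero; features are the mean and SD of response
  magnitude per kernel.
- Each dimension is z-scored with training-set statistics before use;
  without this, families on different scales dominate distances
  arbitrarily.

A KNN (k = 5, Euclidean) or linear one-vs-rest SVM fitted on these
vectors scores every training image into a `C`-vector (KNN: neighbor
vote fractions; SVM: decision values), giving a lookup table
structurally identical to the deep one — the same retrieval and
evaluation machinery applies to both.  All these hyperparameters are
package defaults exposed in `HandcraftedConfig`, chosen as the common
CBIR conventions.

## Evaluation harness

Stratified k-fold protocol (default 10 folds; experiments here use 5
for speed at 180 images): per fold, ~1/k of the images (stratified by
class) are test queries; the remainder splits 70/30 into train and
validation, also stratified.  Training images are class-balanced by
augmentation, the head is fitted, the lookup table is built from the
*original* (unaugmented) training images, and every test query runs at
k ∈ {1,3,5,7,9} under both metrics.

- Accuracy at k is the pooled fraction of retrieved items whose label
  matches the query's, `Σ_q #correct / Σ_q min(k, N)`; at k = 1 this
  equals top-1 fraction-correct.
- Per-category precision = correct retrievals for class-c queries /
  items retrieved for class-c queries.  Recall's denominator is the
  class-c database count per class-c query (the strict "all relevant
  images" reading); a `cap_recall_at_k` switch instead caps it at
  min(k, class count), under which precision = recall = F1 at k = 1.
  With the strict default, recall ≈ k / class-size even for a perfect
  system, so per-category F1 values are structurally far below 1 at
  small k — compare F1 across categories, not against 1.
- F1 = 2PR/(P+R), defined 0 when both are 0.  Classification accuracy
  follows the one-vs-rest (TP+TN)/total form, micro-averaged over the
  C binary problems by default (macro and plain fraction-correct are
  switchable); TN is otherwise undefined for multiclass.
- Aggregation: mean and sample SD (ddof = 1) of accuracy across folds;
  per-category counts are pooled over folds before computing rates.
- Ties in retrieval break by insertion index (stable sort), making runs
  bit-reproducible.  All randomness (splits, balancing, head init and
  batching, the random-score null) derives from one experiment seed;
  per-fold seeds are fixed multiples reduced mod 2³¹−1.

Since the convolutional stages are frozen and seeded once per
experiment, pooled features of the original images are extracted once
and reused across folds; only the FC head differs per fold.  This is
numerically identical to re-extracting per fold.

The `random` method replaces all class scores with seeded Gaussian
noise — the chance-level floor (≈ 1/3 with balanced classes) against
which the deep and handcrafted methods are ordered.

## Numerical and degenerate-input choices

- Zero-norm vectors under cosine raise an explicit error (query, table
  row, or normalization target); silent defaults would mask upstream
  bugs.
- An image entirely at or below the luminance threshold raises a
  "no foreground" error in ROI detection.
- A feature/projection dimension mismatch, duplicate lookup ids, empty
  training splits, and classes smaller than the fold count all raise
  `ValueError` with specific messages.
- Scale-invariance, metric axioms, and oracle equalities in the test
  suite use tolerances of 1e-9 to 1e-12 for floating-point identities
  and exact equality where the computation is exact (Chebyshev,
  autocorrelogram counting).

## Problem sizes

Tests and the acceptance script run the full pipeline at 60 images per
class (180 total, 96×128 px), 5 folds, 100 head-training epochs — about
20 seconds end to end for all five experiment variants on one CPU.
These sizes give stable fold statistics for the properties asserted
(≥ 0.90 mean top-1 accuracy at full separability; chance level within
3 fold-SDs at zero separability) while keeping the suite fast.

## Known limitations

- The synthetic classes are separable by design through color and one
  geometric cue; results on them bound nothing about clinical data.
- `TinyCNN`'s frozen random convolutions are an embedding, not learned
  perception; the package's claims are about the *conversion* of a
  classifier into a retrieval system, which is architecture-agnostic.
- Out-of-focus handling is manual: `blur_score` (variance of the
  luminance Laplacian) estimates sharpness and the harness accepts an
  explicit `exclude_ids` list, but no threshold is applied
  automatically and no claim is made about which images a clinician
  would discard.
- Approximate nearest-neighbor indexing, metric learning and multi-query
  fusion are out of scope; search is exhaustive (N is small).
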