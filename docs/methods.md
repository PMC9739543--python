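# Methods

This note documents the models, conventions and numerical choices behind
`blebcount`, and what its synthetic validation does and does not show.

## Problem and pipeline

The input is a 3D grayscale z-stack (axis order `(z, y, x)`, 8- or 16-bit)
of a neurofilament-immunolabelled optic nerve.  Axonal blebs appear as
bright, compact, roughly ellipsoidal objects that persist through several
optical sections with a stationary in-plane position.  The two dominant
confounders are bright axonal segments — elongated structures whose
apparent centroid shifts from slice to slice as neighbouring segments come
into focus — and small speckled artifacts.  The pipeline is:

    tile slices → 2D UNet segmentation → stitch → binarize (0.5)
    → 3D assembly → slice-span filter (≥ 5)
    → centroid-shift filter (≤ 15 px) → per-slice opening
    → size filter (≥ 100 voxels) → count

## Conventions

* 0-based indices everywhere; pixel centers at integer coordinates.
* ROI polygons are `(x, y)` vertex lists; a pixel is inside a polygon if
  its center is interior **or on the boundary**.  An ImageJ rectangle ROI
  of width w and height h is interpreted as the boundary-inclusive polygon
  through the outermost pixel centers, so it rasterizes to exactly w·h
  pixels.
* Binary masks are `uint8` with values {0, 1}; probability maps are
  channel-first `(2, H, W)` with channels (background, bleb).
* A probability exactly equal to the binarization threshold is foreground.

## Network

The reduced UNet has three stride-2 "same"-padded 5×5 convolutions with
(10, 20, 30) filters, ReLU activations, a mirrored up arm of stride-2 5×5
transposed convolutions with (30, 20, 10) filters — each implemented as the
exact adjoint of the corresponding strided convolution and followed by
concatenation with the same-resolution down-arm feature map (at full
resolution, the input itself) — and a 1×1 two-channel softmax head over the
final concatenation (~75k parameters).  Input sides must be divisible by
2³ = 8; the default 320 px tile maps 320 → 160 → 80 → 40 and back.
"Same" padding keeps the output map the size of the input, which makes
tile stitching well defined; where total padding is odd it is split
asymmetrically (smaller pad before), matching the usual stride-2
convention.  Tiles are normalized to [0, 1] by the integer dtype maximum
before entering the network.

The implementation is plain numpy (strided sliding-window convolution,
analytic gradients verified against finite differences in the test suite).
At this model size a CPU is sufficient for both training and inference on
the scene sizes used here, and the absence of a framework dependency keeps
the package light.

## Tiling

Tiles are square (default 320 px) with origins advancing by
`stride = floor(side · (1 − overlap))` — 304 px at the default 5% overlap.
The last origin per axis is clamped to `dim − side` so the final tile abuts
the border; slices smaller than a tile are zero-padded.  Overlapping
predictions are merged by per-pixel **maximum** of the bleb probability:
the merge rule is deliberately isolated in one function; maximum is
seam-robust and errs toward sensitivity, which matches the pipeline's
character (the filters downstream remove false positives more cheaply than
a miss can be recovered).

## Training

* Split: seeded shuffle into 90% train / 10% validation (exact rounding).
* Loss: mean over pixels of `w · (−log p_true)`, probabilities clipped at
  1e-7.  Weights `w = w_class + w0 · exp(−(d1+d2)²/2σ²)` with d1, d2 the
  Euclidean distance-transform distances to the nearest and second-nearest
  connected objects of the truth mask; the boost needs ≥ 2 objects and
  decays to zero far from them.  Defaults: `w0 = 10`, `σ = 5`,
  `class_weights = (1, 5)` — the foreground up-weighting compensates for
  the ~2–5% bleb pixel fraction of the synthetic scenes; all three are
  config keys since the appropriate values are data-dependent.
* Optimizer: Adam, learning rate 1e-3, batch 8 (config keys).
* An "epoch" is one pass over the training tiles; the log carries an
  epoch-0 record with the untrained network's metrics so learning curves
  are anchored at initialization.
* Early stopping: after `patience` (default 3) consecutive epochs of
  rising validation loss, with best-validation weights restored.
  Validation *loss* (not Jaccard) drives the decision.
* Augmentation: exactly `round(0.5 · n)` training items per epoch, chosen
  by seeded shuffle, receive a random subset of {x-flip, y-flip, intensity
  rescale (×0.7–1.3), additive Gaussian noise (3% of max), Gaussian blur
  (σ 0.3–1.2), low-order polynomial multiplicative bias field (±30%)}.
  Flips transform image and mask together; intensity operations touch the
  image only.  The magnitudes are package choices; they are documented
  config behavior, not measured properties of any instrument.

## Post-processing

Filter order follows the method's numbered steps: (1) 3D assembly +
slice-span, (2) travelling-vector elimination, (3) opening + re-assembly +
size.  Decisions pinned for testability:

* 3D connectivity: 26-neighbourhood by default (config: 6 or 26).
* Span = number of distinct z slices occupied; kept iff span ≥ 5
  (inclusive).
* Centroid shift = Euclidean distance between per-slice centroids on
  consecutive occupied slices; **any** shift strictly greater than 15 px
  eliminates the whole object (no splitting).
* Opening: per-slice 2D, disc radius 1 (config); pixels outside the image
  count as background for the erosion.
* Size = total 3D voxel count after opening, kept iff ≥ 100 (inclusive).
  Whether the size threshold was meant per-slice or volumetric is
  ambiguous in 2D-trained/3D-counted pipelines; volumetric is the natural
  object measure and a `size_measure='2d'` switch provides the per-slice
  reading.

Because the span filter runs *before* opening, re-running the pipeline on
its own survivor mask is not guaranteed to be a fixed point (opening can
erode a 1-px cap slice and drop a span from 5 to 4); each individual
filter, however, is idempotent.

## Synthetic scenes

The generator emulates the geometric and intensity structure the filters
key on, over Gaussian background noise (mean 30, sd 8 on an 8-bit scale):

* **blebs** — ellipsoids, radius 4–6 px, spanning 5–9 slices, static
  centroid, intensity 160–220 (the detection target);
* **travelling segments** — per-slice capsules elongated along a random
  direction, whose center advances 18 px per slice (snapped to the
  half-pixel grid so the painted centroid is exact); long enough to stay
  one 3D component, mimicking bright axonal segments;
* **specks** — single-slice clusters of 3–20 px;
* **axons** — thin (radius 1 px) bright tubes along the nerve axis; scene
  dressing, not catalogued;
* distractor sub-populations of blebs violating exactly one filter each:
  short (span 2–4, large radius) and small (radius ≈ 2, span 5–7).

Objects are placed by rejection sampling with a minimum bounding-box
separation (4 px) so distinct objects can never merge under
26-connectivity; specs that cannot be placed are rejected with an error.
The catalog records each object's exact painted geometry, and the
qualifies-as-bleb flag is recomputable from span/size/shift plus a filter
configuration.  Two masks are produced: the training mask (bleb-class
voxels only — what a human would circle) and an all-objects mask used to
drive the filters with a perfect segmentation.

What the scenes do **not** model: light-sheet optics, clearing artifacts,
intensity attenuation with depth, nerve curvature, axon crossings through
blebs, and annotation noise.  Passing the synthetic recovery tests
therefore demonstrates the correctness of the filtering logic and the
learnability of the bright-blob segmentation task, not field performance
on real nerves, which depends on retraining with real annotated stacks.

## Validation design and problem sizes

The test suite and acceptance script use scenes of 24 × 176 × 176 voxels
with 64 px tiles (one scene ≈ 216 tiles), training for 12 epochs
(≈ 300 Adam steps) — sizes chosen so the full cycle of generation,
training and end-to-end evaluation completes in well under a minute while
leaving clear margins on every measured boundary.  Object-level F1 of the
trained model plus filters against planted truth on held-out scenes is
≈ 0.95–1.0 at these settings.

## Known limitations

* Greedy overlap matching is not guaranteed to be the maximum assignment
  in adversarial overlap configurations (it is exact on the instances
  tested; a minimum-IoU option makes matching stricter).
* The travelling filter removes whole objects; a real axon segment merged
  with a true bleb into one component would take the bleb with it.
* Training on full 320 px tiles is supported but slow on CPU; the numpy
  implementation favours portability over throughput.
* The ImageJ ROI codec covers planar outline types (polygon, rectangle,
  oval, freehand, traced); composite/point/line ROIs are rejected.
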