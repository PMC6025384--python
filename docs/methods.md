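# Methods

## Pipeline overview

The package classifies 2-D gray brain slices as *normal* or *abnormal*
in three stages: cerebrum segmentation, sub-band texture summarization,
and rule-based classification.  Each stage is usable on its own; the
`pipeline` module and the `run` subcommand compose them.

## Segmentation

All images are floats in [0, 1] (8-bit inputs divided by 255; RGB
collapsed with luma weights 0.299/0.587/0.114).  Coordinates are 0-based
`(row, col)`.

1. **Inversion** `I ← 1 − I` makes the dark background bright so the
   region grower can flood it.
2. **Seeded region growing** from pixel (30, 30) — guaranteed to be
   background for the default phantom geometry — accepts a neighbor when
   its intensity is within `grow_tolerance` (default 0.10) of the
   *running mean* of the region grown so far.  Because the running mean
   makes the result order-dependent, the traversal order is fixed: FIFO
   breadth-first, neighbors enqueued row-major, 8-connectivity.  The
   output is therefore deterministic and equals a naive BFS oracle.
3. **Edge enhancement**: either the Sobel magnitude `|Sx| + |Sy|`
   (templates applied as written, reflect padding, rescaled by the
   maximum) binarized with Otsu's threshold, or local adaptive
   thresholding (`I > local mean + offset`, window 31, offset 0.02) for
   images with a darker cerebrum.
4. **Mask construction**: foreground = complement of the grown
   background; edge pixels removed (this disconnects cerebrum, CSF gap
   and skull ring); opening with a disk of radius 2 removes debris;
   the largest 8-connected component is kept (the cerebrum — by
   construction the largest non-background, non-edge region); interior
   holes (dark ventricle, lesion edges) are filled; a dilation with a
   disk of radius 3 recovers the margin lost to edge removal.
5. **ROI** = original (non-inverted) image × mask.

The structuring radii (2, 3) are calibrated on the default phantom and
exposed in `SegmentationConfig`.  Out-of-image pixels count as
background in all morphology; convolutions and windows use reflect
padding.  Degenerate inputs (uniform images, all-edge maps) yield an
empty mask with a warning rather than an error.

## Texture features

The ROI — the full rectangle including its zeroed background — is
decomposed two ways:

* **DWPT**: separable 2-D wavelet packet transform with the `bior2.2`
  biorthogonal spline pair, symmetric (half-sample) boundary extension,
  dyadic downsampling.  At depth *d* every node is decomposed again, so
  depths 1 and 2 give 4 and 16 bands (natural order LL, LH, HL, HH,
  recursively), 20 band matrices in all.  A band of an *n*-sample parent
  has `floor((n + 5)/2)` samples per axis (6-tap analysis filters).
  The inverse transform reconstructs the input to < 1e−8.
* **DCT**: whole-image orthonormal type-II DCT, coefficient matrix
  partitioned into 2×2 quadrants and 4×4 blocks.  The whole-image
  transform avoids block-boundary artifacts; the partition mirrors the
  20-band DWPT layout so both transforms feed the classifier feature
  vectors of identical shape.

Each band yields nine statistics, in fixed order: mean, median, max,
min, range (= max − min), mode, standard deviation (population form,
divide by *N*), median absolute value (median of |coefficients|), and
mean absolute value.  The mode of continuous coefficients is the center
of the most populated of 256 equal-width histogram bins over
[min, max]; ties break to the lowest bin and a constant band is its own
mode.  20 bands × 9 statistics = 180 features per image, with
deterministic column names `<transform>_d<depth><band>_<stat>`.

## Rough-set LEM2 classifier

Continuous features are discretized per column into equal-frequency
bins (default 3; equal-width available).  Cut points are empirical
quantiles of the **training fold only** — never the test fold — and
duplicate cuts from ties collapse; out-of-range values clamp into the
end bins.

On the discretized decision table, objects with identical condition
tuples form indiscernibility blocks.  For a concept *X* the lower
approximation is the union of blocks inside *X*, the upper approximation
the union of blocks meeting *X*; their ratio of cardinalities is the
approximation accuracy (1 exactly on consistent tables).

LEM2 induces a local covering of each concept's lower approximation:
complexes are grown greedily by the attribute-value pair *t* maximizing
|[t] ∩ G| over the uncovered goal set, with deterministic tie-breaks
(smaller |[t]|, then attribute column order, then ascending value — the
classical description leaves value ties open); redundant conditions are
then dropped from each complex and redundant rules from the covering.
Only certain rules are produced, so inconsistent training data yields
rules from lower approximations only, and a concept with an empty lower
approximation yields none (with a warning).

Classification: fully matching rules vote with weight = support (number
of matching training objects).  A case matching no rule is scored by
partial matching — each rule contributes (matched conditions /
specificity) × support to its class — so the accuracy is always
computable; remaining ties fall back to the training-majority class.
This is a design choice over "refuse to classify", recorded here rather
than inherited from any reference implementation.

## Evaluation protocol

Repeated stratified random holdout: per repeat, each class contributes
its largest-remainder-rounded share of the train fraction (default ⅔) to
the training fold, with at least one object per class on each side.  The
classifier (discretizer included) is refitted per repeat.  Accuracies
are reported in percent as mean (SD, sample form) over repeats.  When
several configurations are compared, all cells share the same split
sequence, so per-repeat accuracies are paired and a two-tailed paired
t-test applies; zero-variance nonzero differences report t = ±∞ with an
exact-tie note, identical lists report (0, 1).

## Synthetic phantoms

A phantom is a 128×128 slice: background 0.02, bright skull annulus
(radii 39–45, intensity 0.95), dark CSF gap, and an elliptical cerebrum
(semi-axes 34×30, base intensity 0.60) textured with a smooth sinusoidal
modulation (amplitude 0.04) plus i.i.d. Gaussian noise (SD 0.03), with a
small dark central ventricle (semi-axes 7×5).  The abnormal class adds
three bright anti-aliased lesions (radius 3–6, offset +0.30), enlarges
the ventricle 2.4× (atrophy-like), and scales both texture components
1.6× (degenerative tissue is texturally more heterogeneous).  Dataset
generation jitters skull radii and cerebrum axes by ±2 px per image and
derives per-image seeds from a master seed, so datasets are diverse yet
bit-reproducible.

Geometry constraints are enforced by construction: the skull ring is
centered and its outer radius (≤ 47 after jitter) keeps the fixed
region-growing seed (30, 30) (distance 48.1 from center) in the
background.

Parameter choices worth noting:

* The cerebrum/CSF contrast (0.60 vs 0.02) keeps the cerebrum boundary
  gradient above the Otsu threshold of the Sobel magnitude along the
  entire contour.  With weaker contrast, single-pixel gaps in the
  detected boundary let the CSF annulus merge into the cerebrum
  component (observed Dice drops from ≈0.94 to ≈0.76).
* The three abnormal-class signals live on different feature axes:
  lesions drive approximation-band maxima, the enlarged ventricle drives
  approximation-band spread, and the texture factor drives detail-band
  energy.  Multiple semi-independent axes are what let conjunctive rules
  resolve the inherently mixed middle bin that equal-frequency tertiles
  produce on balanced, well-separated classes.

What the phantoms do **not** emulate: MR physics (bias fields, Rician
noise, partial volume), anatomical shape variability beyond an ellipse,
3-D context, and multi-modal (T1 vs T2) contrast differences.  Passing
tests therefore demonstrate the correctness and internal consistency of
the pipeline, not clinical performance on real MRI.

## Numerical choices and degenerate inputs

* Sobel magnitudes below 1e−12 are treated as exact zeros before peak
  rescaling (rounding residue on flat fields is not signal).
* Dice is defined as 1.0 when both masks are empty.
* A constant feature column gets no cuts and maps to a single bin.
* Histogram-mode ties break to the lowest bin; LEM2 ties as above; the
  training-majority tie falls to the first label in decision order.
* All randomness flows from integer seeds through
  `numpy.random.SeedSequence` spawning, so every public entry point is
  deterministic given its seed.

## Study sizes

The default synthetic study uses 60 images (30 per class) with 20
holdout repeats, and the generator-level class-separability check uses
200 phantoms; these sizes give stable statistics (accuracy SE ≈ 1–2
points) while keeping a full run in seconds on one core.

## Known limitations

* LEM2 on many weakly-informative discretized attributes can induce
  small-support conjunctions that are pure on the training fold by
  chance; support-weighted voting mitigates but does not eliminate the
  resulting test errors (observed as occasional single-image mistakes in
  the holdout study).
* Equal-frequency discretization with an odd bin count straddles the
  class boundary of balanced bimodal features, leaving a mixed middle
  bin; even bin counts align a cut with the boundary.  The default
  (3 bins) follows the classical setup; `n_bins` is exposed.
* The segmentation is calibrated for slice-like images with a closed
  bright skull contour; images without one fall back to the
  empty-mask warning path.
* The alternative mask source in the comparison grid is pluggable but no
  external segmentation tool is bundled.
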