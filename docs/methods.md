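# Methods

This note records the models, constants and numerical choices behind
`skyfilter`, and what the synthetic experiments do and do not demonstrate.

## The processing model

The workflow assumes nadir (straight-down) aerial frames of open water in
daylight: the water surface is the bright part of the histogram, bird
bodies are compact dark targets a few tens to ~150 pixels long, and the
ground-sample distance (GSD, cm/pixel) sets the target scale as
`footprint_px = body_length_cm / gsd_cm`. All three stages inherit these
assumptions; none of them is appropriate for thermal imagery, oblique
views, or targets brighter than their background unless the polarity
switch is used.

### Stage 1 — occupancy filter

Parent frames are tiled (inference grid 1440×1440, stride 1080, patches
rescaled to 960), each patch is scored, and the parent probability is the
**max** over patch probabilities. Thresholding the max is identical to the
any-patch OR rule while also yielding a continuous per-frame score for
threshold sweeps; the default decision threshold is 0.5 and is
deliberately exposed in configuration, because the right operating point
trades in-flight compute against the population-estimate bias caused by
false-negative drops. Dropped frames are never discarded: the run record
lists every dropped frame that contained ground truth.

Two interchangeable backends implement the patch score:

* `proposal_heuristic` — positive iff the blob stage emits ≥ 1 proposal;
  the score is `1 − exp(−n)` in the proposal count `n` (exactly 0 for a
  clean patch). No training, useful as a bootstrap and as a speed
  baseline.
* `small_cnn` — a compact convolutional classifier: a frozen feature bank
  of difference-of-Gaussian channels at σ = 1.5, 3, 6 px (both polarities)
  plus two gradient-magnitude channels on a 160×160 input, 4× max-pooling,
  one seeded-random 3×3 mixing convolution to 16 channels, global average
  pooling, and a single trained logistic (fully-connected) layer.
  Freezing the convolutional stack keeps training deterministic and
  CPU-cheap (seconds) while the GAP+FC structure preserves the
  class-activation-map seam used by the box refiner: `CAM(x, y) = Σ_c w_c
  F_c(x, y)` with `w_c` the trained class weights rescaled by the feature
  standardization. Fixed/random convolutional features with a trained
  linear head are a well-established compromise when a full deep backbone
  is out of scope; the backend seam accepts any stronger classifier that
  exposes `predict_proba`, `feature_maps` and `class_weights_`.

### Stage 2 — blob + HOG + SVM detection

Constants follow the workflow's standard values: intensity threshold 0.9
(dark foreground on bright water), square dilation element of side 12,
8-pixel connectivity. Contrast enhancement defaults to **none**: on
high-key open-water frames the raw intensities already sit near the top of
the range, and a full-range percentile stretch would spread the low-
amplitude wave texture across [0, 1], pushing most water below the 0.9
threshold and destroying exactly the separation the constant encodes.
`stretch` (2–98% linear) and `clahe` remain available for underexposed
imagery. Polarity is switchable; `bright_fg` thresholds above
`1 − threshold` so that flipping polarity on an inverted image reproduces
the dark-foreground mask bit for bit.

Proposals are the min/max pixel extents of each labeled blob. Because
blobs are labeled **after** dilation, those extents are systematically
loose by the dilation margin (5 px low side, 6 px high side for factor
12); `detect` shrinks each proposal by exactly that margin (probed
empirically against the structuring-element centering, clamped to ≥ 2 px)
before scoring. Without the correction every proposal would carry a fixed
IoU penalty against tight ground truth that grows as targets shrink.

Each proposal is resized to the 64×64 HOG window (8×8 cells, 2×2 blocks,
one-cell block stride, 9 orientations, L2-Hys — feature length 1764) and
scored by a linear SVM; scores are the logistic of the SVM decision value
so they are comparable across proposals, which greedy NMS (default IoU
0.5, ties broken by score, then x0, then y0) requires. Training labels
follow the evaluation's own convention: a proposal is positive iff its IoU
with some annotation reaches 0.5. Two training-set augmentations keep the
classifier well-posed on small annotation sets: the annotated crops
themselves (plus their flips and quarter-turns) are added as positives to
widen pose coverage, and when calm scenes yield fewer negative proposals
than positives, seeded random background boxes (IoU < 0.1 with all
annotations) fill the negative class.

### Annotation refinement

Loose manual boxes inflate background content and depress high-IoU
metrics. The refiner crops the loose box plus a context margin (default
20% per side), computes an activation map — `contrast` backend: absolute
deviation from the median of the crop border (the robust water level),
max-normalized; `cam` backend: the classifier CAM, bilinearly upsampled —
initializes at Otsu's threshold and evolves a two-phase morphological
level set. Each iteration applies one curvature-smoothing pass
(alternating sup-inf/inf-sup over four 3×3 line elements) and then flips
boundary pixels wherever that lowers the Chan–Vese two-phase variance
energy of the heat map; smoothing precedes the data force so that a
binary-disk heat map with disk initialization is an exact fixed point.
Evolution stops at `iters` (default 100) or after 3 unchanged iterations.
The refined box is the tight box of the largest 8-connected component.

Degenerate inputs fall back to the input box with `converged=False`: crops
whose intensity range is below 0.1 (no plausible target — plain water),
empty Otsu initialization, or a foreground below 4 px. The 0.1 floor sits
well above the wave-texture amplitude at moderate sea states (≤ 0.036)
and well below any target at the default contrast (0.5).

### Evaluation

Matching is greedy per image in descending score order; each detection
claims the unmatched ground-truth box of highest IoU if that IoU reaches
the threshold, with IoU ties broken toward the lowest ground-truth index.
Detections are then pooled across images into a single ranked list per
threshold (score ties resolved by stable sort on input order). AP uses
101-point max interpolation with the conventional 1/101 normalization so
AP ∈ [0, 1] — summing the interpolated precisions without normalization
would scale the metric by the grid size, inconsistent with every reported
value of the quantity. AR is the mean, over the IoU grid 0.50:0.05:0.95,
of the final recall at each threshold, with no max-detection cap (the
per-image detection counts here never approach typical caps). Undefined
ratios are surfaced as flagged nulls, never silent zeros: AP with zero
ground truth, precision with no positive predictions. GSD bins are
`[0, 0.6)`, `[0.6, 1.2]`, `(1.2, ∞)` cm — both edges owned by the middle
bin; empty bins produce flagged-null reports rather than errors.

## The synthetic generator

The generator emulates the features that drive these algorithms and
nothing more: a bright base level (0.94) with bounded band-limited wave
texture (sum of σ = 3 and σ = 16 noise fields, amplitude 0.12·sea_state,
normalized so the background never crosses the 0.9 threshold at sea_state
≤ 0.2), glare as saturated patches placed by quantile-thresholding a
σ = 24 noise field (so the saturated fraction tracks `glare_fraction` by
construction), and birds as flat-shaded rotated ellipses (axis ratio
0.35–0.65, intensity = background mean − contrast, per-pixel jitter
σ = 0.02). The default body length of 40 cm is a configurable stand-in for
a mid-sized sea duck — target pixel extents are not published quantities
here, only the GSD range is. Placement rejection-samples against a
pairwise box-IoU cap of 0.1 **and** a minimum box separation of 16 px
(one dilation factor plus margin) so that ground truth stays unambiguous
for matching and merging tests; birds that cannot be placed in 50 tries
are dropped and the returned annotations reflect what was stamped.

What the generator does **not** model: plumage and posture detail, wakes
and white-caps, birds partially submerged or overlapping, low-light color
shifts, sensor noise, and flocks denser than the separation floor. Tests
passing on these scenes therefore demonstrate the *mechanics* of the
workflow — tiling, aggregation, NMS, refinement geometry, metric
arithmetic, and the qualitative orderings (refinement helps, detection
degrades with GSD, the filter does not) — not field-data performance,
which in the motivating surveys requires trained deep backbones and
GPU-scale data.

## Problem sizes and determinism

The test and acceptance experiments use deliberately compact study sizes
chosen to exercise every code path with clear statistics: training scenes
of 720² px at GSD 0.3 cm (so one bird spans 133 px), evaluation parents up
to 1440² px (one inference tile each), 100 birds in the refinement
experiment, GSD series at 0.3/0.9/1.5 cm, and 20 half-empty parents for
the filter study. Every random draw — scene content, box loosening,
augmentation, SVM and logistic fits, background-negative sampling — is
driven by explicit integer seeds, so all experiments are exactly
reproducible; `scripts/acceptance.py` derives all of its seeds from the
single `--seed` argument.

## Known limitations

* The detector's HOG/SVM stage is scale-normalized by resizing proposals,
  so it cannot distinguish a bird from a bird-sized wave shadow by size
  alone; on rough seas precision relies on the classifier's texture cue.
* The occupancy filter's frozen feature bank targets dark-blob contrast;
  extreme glare fractions that saturate a whole patch suppress the signal.
* Refinement emits one box per loose box: multiple birds inside a single
  loose annotation are returned as the largest component only.
* The dilation-margin correction assumes the default square structuring
  element; custom elements would need a matching probe (the margin is
  probed, not hard-coded, so alternative factors are handled).
* Cross-track/flight-line duplicate removal between *different* parent
  frames is out of scope; NMS handles only intra-frame tile overlap.
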