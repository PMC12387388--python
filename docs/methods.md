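# Methods

## Planimetric measurement model

The measurement assumes the rendered-mode appearance of 3D
transesophageal echocardiography: cardiac surfaces drawn in saturated
colors against a black background, with the valve orifice appearing as
a dark region fully surrounded by tissue when the valve is open.  Under
that assumption the orifice is recoverable by luminance thresholding
alone — no edge detector or model of leaflet shape is needed.

**Grayscale.**  Luminance `0.2989 R + 0.5870 G + 0.1140 B`, rounded
half-up to an integer in [0, 255].

**Binarization.**  A single fixed threshold `t`; a pixel is bright iff
its intensity is *strictly greater* than `t`.  Descriptions of this
method sometimes phrase the rule as "pixels below t become black",
which would make the comparison non-strict; the formal definition uses
strict inequality and this package follows it.  The two rules differ
only for pixels exactly at the threshold.  `t` must satisfy
`0 < t < 255`; the degenerate endpoints produce constant images.

**Orifice detection.**  Dark (0) pixels are labelled into 8-connected
components.  Components touching the image border are background; of
the enclosed remainder, the largest is the orifice.  `None` (valve
closed) is a valid outcome.  Ties on size resolve to the first
component in raster order.  The boundary is traced with Moore-neighbor
tracing (Jacob's stopping criterion), giving an ordered, closed,
8-connected path of pixel centers.

**Physical units.**  Areas are `pixel count × cm_per_px_x ×
cm_per_px_y`; perimeters are polygonal arc lengths of the boundary
path, scaling each axis separately so anisotropic pixels are handled
exactly (`step = hypot(dx·cm_x, dy·cm_y)`).  This makes area scale as
k² and perimeter as k when both calibration factors scale by k.  Note
that a path through pixel centers slightly understates the outline of
the pixelated region (a 10×10-pixel hole at 0.1 cm/px measures 3.6 cm,
not 4.0); since the scan's stop rule compares perimeters of the *same*
metric at consecutive thresholds, only consistency matters.

**Threshold scan.**  Thresholds 10…30 in unit steps; each threshold
independently selects its best frame (largest orifice; ties go to the
earliest frame).  The scan stops at the first threshold whose
best-frame perimeter differs from the previous threshold's by more
than 1.0 cm in *absolute value*, selecting the penultimate threshold;
otherwise it runs to 30 and selects 30.  Two consequences of treating
each threshold independently: consecutive records may come from
different frames, and a frame with no orifice contributes area and
perimeter 0 (so a contour vanishing between thresholds can itself
trigger the stop).  The scan bounds, step and jump criterion are
configurable (`t_min`, `t_max`, `perimeter_jump_cm`).

## Calibration

* **Philips dialect** — a ruler of green dots.  A pixel is "green"
  when `G ≥ 100` and G exceeds R and B by a margin (default 60); blobs
  of at least 4 pixels (smaller ones are speckle) are 8-connected
  components, and the median consecutive centroid spacing along the
  ruler axis, divided into the configured physical spacing (default
  1.0 cm — vendor-dependent, so config-mandatory in practice), gives
  cm/px.  Square pixels are assumed since one ruler constrains one
  axis.
* **GE dialect** — a bright scale line in the lower-right corner.  The
  longest bright component's column extent divides the configured
  physical length (default 1.0 cm); the pixel is assumed symmetric.
* **Explicit** — both factors supplied directly.

## Severity grading

`a ≥ 4.0` no stenosis; `1.5 < a < 4.0` mild; `1.0 ≤ a ≤ 1.5` moderate;
`a < 1.0` severe.  The boundary conventions (4.0 not stenotic; 1.0 and
1.5 both moderate) follow the strict interval statement, which is the
only convention consistent with the bundled reference cohort (its
4.0 cm² exam is graded "no stenosis").  No upper bound exists: 7.4 cm²
is still "no stenosis".  The 30-exam reference cohort
(`planim/data/reference_cohort_mva.csv`) grades to 8/8/4/10 exams
(26.7/26.7/13.3/33.3%).

## Phantom generator

Each phantom emulates exactly the features the pipeline relies on:

* black background reaching the border;
* a bright tissue disk (radius 0.42 × image size) in four palette
  colors, all with luminance well above gray 30 and none matching the
  green-marker rule;
* a central orifice (ellipse of aspect 1.3, or a harmonically
  perturbed "blob") whose area follows a half-period raised-cosine
  open–close trajectory peaking at `peak_frame` with the requested
  diastolic MVA.  Ground truth is the *rendered* pixel count per
  frame, so rasterization is part of the truth;
* vendor markers per dialect (green dots 1.0 cm apart; 1.0 cm scale
  line) at the configured `cm_per_px` (default 0.02, i.e. a 224 px
  frame spans 4.5 cm);
* additive Gaussian channel noise, default σ = 8, clipped to [0, 255]
  — enough to exercise threshold sensitivity and speckle-robustness of
  the marker detector without defeating segmentation;
* for stenotic phantoms (MVA < 4 cm²), a pale thickened leaflet rim
  around the orifice, `6 + 1.5·(4 − MVA)` px thick (≈1.2–2.3 mm at the
  default calibration, the range reported for rheumatic leaflets).
  Thickened, fused leaflets are the anatomy that *causes* the
  stenosis and are visible in every frame of a real recording; without
  some per-frame morphological correlate of the diagnosis, single
  frames from the closed phase of the cycle would be uninformative
  about the video's class and no frame-level classifier could work —
  on phantoms or on real data.

Phantom videos are written as uncompressed 24-bit RGB AVI (RIFF with a
raw `DIB` stream), so a write/read round trip is bit-exact and
segmentation tests are stable; the same reader ingests any
uncompressed 24-bit AVI.  Compressed clinical exports would need
transcoding before use.

What the phantoms do **not** emulate: real speckle statistics and
shadowing, probe motion, gain variation, leaflet texture and doming,
arrhythmic cycles, neighboring anatomy.  Passing phantoms therefore
demonstrates the correctness of the *measurement chain* (calibration,
segmentation, scan logic, unit conversion) and the learnability of a
clean morphological signal — not clinical performance.

## Screening CNN

Architecture: conv 3×3 (valid padding) + ReLU + 2×2 max pool, four
blocks with 32/64/128/256 filters; flatten; dense 512 + ReLU; dense 2
+ softmax.  Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999), categorical
cross-entropy, batch 100, ≤10 epochs, early stopping monitoring test
loss with patience 3 and best-weight restore.  Input frames are
resized to `input_size` (default 128, anti-aliased) and divided
by 255.  Inference on a video averages nothing: each frame is argmaxed
and the video verdict is the majority vote, with ties going to
*has stenosis* (the clinically conservative call).  The network is
implemented on NumPy (im2col forward; input gradients as nine shifted
GEMMs; max-pool gradient routes to the first maximum in raster order),
single-threaded and fully seeded, so training histories are exactly
reproducible on one machine.

**Scaled-down screening experiment** (`run_screening_experiment`):
10 phantom videos per class × 10 frames, ×6 augmentation, 2 videos per
class held out entirely, remaining frames split 70/30, input 64×64
(the architecture is unchanged; 64 is the smallest power-of-two input
that survives four conv/pool stages comfortably).  Seeded runs reach
≥95% held-out frame accuracy and 4/4 correct verdicts on the unseen
videos in a few minutes on one CPU.  This validates the training loop
and data plumbing at desk scale; it says nothing about accuracy on
clinical echocardiograms, whose acquisition variability the phantoms
do not model.

## Augmentation

Random affine maps composed about the image center: rotation
U(−40°, 40°), shifts U(−20%, 20%) of each dimension, shear factor
U(−0.2, 0.2), per-axis zoom U(0.8, 1.2), horizontal flip with
probability ½.  Shear and zoom magnitudes are unstated in common
recipes that otherwise fix rotation and shifts; 0.2 is this package's
default and both are configurable.  Interpolation is bilinear with
nearest-edge fill for exposed pixels.  With all ranges zero and
flipping off the transform is exactly the identity (regression-tested),
and a fixed seed reproduces outputs bit-for-bit.

## Numerical and degenerate-input choices

* Grayscale rounding: half-up (`floor(x + 0.5)`).
* Threshold comparisons: strict `>`; validation rejects t ≤ 0 and
  t ≥ 255.
* Empty sequences, single-class datasets, non-positive calibration
  factors, oversized orifices: validation errors, never silent
  defaults.
* A single-pixel orifice has perimeter 0 (one-point path).
* Seeds: every stochastic component (phantom noise, cohort sampling,
  augmentation, weight init, batch shuffling, splits) takes an explicit
  seed; nothing reads global RNG state.

## Known limitations

* The fixed-threshold family fails on imagery whose orifice is not
  darker than its surroundings at every scanned threshold; adaptive
  (e.g. Otsu) thresholding is deliberately out of scope.
* The perimeter-jump rule compares best frames of *consecutive
  thresholds*, which may be different frames; a video with two
  near-tied openings can alternate frames across thresholds and
  trigger the stop without any contour leak.
* Calibration trusts the markers: wrong configured spacing scales all
  areas quadratically.
* The CNN is a from-scratch trainer sized for desk-scale experiments;
  wall time grows roughly linearly in frame count and quadratically in
  input size.
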