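# Methods

## The labeling model

All decisions are made in the 520×520 square crop of the native 772×520
frame, in continuous image coordinates (origin top-left, x rightward,
y downward; pixel (row i, col j) has center (j+0.5, i+0.5)). The annotation
geometry is a circle of radius 69 px (at side 520; it scales linearly with
the side) around the square center plus the two diagonals, which partition
the square into four closed triangles. The label function is total:

1. no detectable pupil → `closed`;
2. center inside the central circle (edge included): `correct` if the
   visible fraction exceeds 0.90, else `closed`;
3. center outside: `closed` if the visible fraction is below 0.15, else the
   triangle's directional label.

Two conventions close gaps that the verbal rules leave open. At exactly
0.90 visible with a central pupil the frame is `closed` (the conservative
choice: borderline frames are discarded rather than fed to the diameter
estimator); at exactly 0.15 visible with an off-center pupil the frame is
directional (matching the "at least 15 % visible" reading). Points exactly
on a diagonal are assigned with the fixed priority up > right > down > left;
the priority is arbitrary but deterministic, which is what reproducibility
needs. Both boundary sets have measure zero for continuous detections, so
neither choice is visible in aggregate accuracy.

## The synthetic frame generator

The generator replaces instrument recordings, which are not redistributable,
with parametric scenes rendered at the native resolution. A scene is: a
bright disc (the stimulation lens seen by the camera — everything outside it
is unilluminated and near-black), a bright sclera filling the lens view, an
iris disc concentric with the pupil, the dark pupil ellipse, eight saturated
glints on a ring near the pupil (corneal reflections of the illumination
LEDs), an upper and a lower eyelid rendered as skin-intensity regions
bounded by circular arcs with a dark lash margin along each edge, a smooth
random texture on iris and sclera, a linear illumination ramp vanishing at
the lens center, and additive Gaussian sensor noise clipped to [0, 255].

Geometry defaults are set at the instrument's scale of roughly 32.5 px/mm:
pupil semi-axes 85–115 px (a dark-adapted 5–7 mm pupil; PLR protocols
measure dilated pupils), iris radius 1.7–2.1× the pupil semi-axis, lens
radius 250 px. Gaze excursions displace the pupil center 110–200 px from
the axis; the ellipse may be clipped by the lens edge, as the device's
directional frames are. Blinks keep the eye roughly on-axis and close the
upper lid onto the lower lid. Appearance parameters (pupil 20–45, iris
105–150, sclera 195–235, skin 140–220 gray levels, texture amplitude,
ramp strength, lid gaps, lash-line darkness/width) are drawn per frame to
emulate subject-to-subject and illumination variability. These ranges are a
design choice: the instrument's own imagery is described only qualitatively,
so the generator aims for plausible near-IR eye appearance, not photometric
fidelity. Notably, appearance variability is not optional realism — with a
flat, single-intensity rendering all frames are nearly identical vectors
and any kernel method with a small fixed bandwidth degenerates.

Ground truth is exact by construction: the visible fraction is integrated
by pixel counting on a 4× supersampled grid over the pupil ellipse
(visible = inside the lens disc and not under the upper-lid occluder), and
the label is produced by the same rule function the package exposes, making
generated datasets self-consistent by definition. The eyelid apex for a
requested coverage fraction is solved by bisection on a coarser (1×)
subgrid of the same integral; the recorded visible fraction is always the
4× value, so the bisection tolerance (~10⁻³) never enters the ground truth.
Class-conditional sampling keeps coverage at least 0.05 away from the
0.90/0.15 rule thresholds and gaze angles 0.12 rad away from the diagonals,
then verifies the realized label by rejection; a class that cannot be
realized in 200 draws raises a generation error naming it.

Determinism: one master seed drives class sampling and per-frame seeds in a
fixed order; a (scene, seed) pair renders bit-identically.

What the generator does **not** model: corneal refraction, pupil dynamics
within a recording, eyelash clutter across the pupil (a streak overlay
exists behind a flag but is off in the benchmark suites), off-axis optical
aberrations, and real iris musculature texture. Accuracy numbers measured
on synthetic suites therefore validate the *pipeline logic and its
geometry*, not performance on instrument recordings, and are expected to be
optimistic: the benchmark thresholds used in the tests (rule pipeline
≥ 90 %, SVM-on-pixels ≥ 95 %) are sanity floors at desk scale, not claims
about real data.

## The rule-based detector

Stages, at the 520-px working side:

1. fixed centered square crop;
2. pixels below 80 are zeroed (lens-profile masking); min–max stretch to
   [0, 255];
3. Gaussian blur with a 21×9 kernel (σ derived from the kernel size as
   0.3·((k−1)/2 − 1) + 0.8, the convention of mainstream CV libraries); the
   wider horizontal support smears lashes, which are horizontal structures;
4. intensities are capped at T = max(70, 5th percentile of the nonzero
   pixels) and the image re-stretched, so the darkest few percent of the
   content span the full range — this *reference* image is near-bimodal and
   is also what candidate darkness is scored on;
5. locally dark pixels become mask foreground: a pixel is foreground when
   below its 9×9 block mean minus an offset (5) **or** at or below an
   absolute dark floor (128) on the reference. The block-mean term alone
   only marks the boundary band of any dark region wider than the block
   (inside such a region, pixel ≈ mean), and the subsequent 21×21 opening
   erases a band that thin — so the pure local test yields an empty mask on
   exactly the frames that contain a clean pupil. The dark floor on the
   near-binary reference is what makes the extraction pick up the pupil
   *body*; a degenerate (contentless) reference yields an empty mask;
6. foreground farther than 245 px from the square center is dropped (the
   lens edge is at a fixed, device-determined distance);
7. morphological opening then closing with a circular element of diameter
   21, implemented exactly via Euclidean distance transforms (erosion:
   EDT(mask) > r; dilation: EDT(¬mask) ≤ r), which is both exact for a disk
   and much faster than iterated structuring-element erosion; the ring cut
   is re-imposed afterwards because closing can dilate past it;
8. each 8-connected component is convex-hulled and kept only if the radius
   of the circle inscribed in its bounding box lies in [20, 150] px and its
   hull-interior mean on the reference is darker than 205 (inverted
   brightness > 50). Survivors are scored by circularity (4πA/P² of the
   hull polygon), darkness and hull area, each min–max normalized across
   the candidate set and summed with equal weight (the three criteria are
   named by the design; the weights are not, and equal weights are the
   neutral choice). Ties go to the larger area, then the leftmost-topmost
   center.

The frame label follows: no candidate → `closed`; bounding-box
height/width below 0.55 → `closed` (a lid squashing the pupil); otherwise
the rule table applied to the detected center with the pupil treated as
fully visible (the pipeline has no occlusion estimate; a heavily covered
pupil either fails the size/aspect gates or was never extracted).

All pixel-denominated parameters scale linearly with the working side;
kernel and block sizes are rounded to the nearest odd integer with a floor
of 3; intensity thresholds are resolution-independent.

## Shallow-ML baselines

Frames are square-cropped and downscaled by exact area averaging (PIL BOX
filter; the resampling filter is a package choice) to the feature input
side, 32 px by default. Features: raw row-major pixels scaled to [0, 1]
(length side²); HOG with 8 unsigned orientations, 4×4 px cells, 1×1-cell
blocks (length 8·(side/4)²); uniform LBP at R=5, P=100, histogrammed over
the P+2 uniform-pattern bins and normalized to sum 1. Raw LBP codes at
P=100 would enumerate 2¹⁰⁰ patterns; the uniform-pattern binning is the
standard compact encoding. Border pixels whose sampling circle leaves the
image are excluded from the histogram. Classifier hyperparameters are
fixed (SVM: RBF, C=1, γ=10⁻³; MLP: one hidden layer of 100 ReLU units,
Adam, max 500 iterations; RF: 100 trees, Gini; NB: 10⁻⁹ variance
smoothing; k-NN: k=3 uniform; AdaBoost and QDA are available but excluded
from headline comparisons). Training is seeded and single-threaded; no
class reweighting is applied to the imbalanced split, matching the
benchmark protocol.

The benchmark split reproduces the study's class proportions at 0.20 scale
(train 1482/208/117/109/126/53 for correct/closed/right/left/up/down) with
a balanced 100-per-class test set; the scale is a desk-time compromise, and
the rarest class (`down`, 53 training frames) remains the accuracy
bottleneck exactly as the full-scale imbalance suggests.

## Figure of merit

FOM = A²·exp(−(SFPT/τ)²). The exponent is squared: this is the only
reading under which the published calibration constant
(τ = 0.010/√ln(0.8²/0.5) ≈ 0.0201268 s) and the three published comparison
scores (0.767, 0.925, 0.096) are all reproduced; the non-squared reading
gives τ ≈ 0.0405 and fails all three. τ is stored unrounded and carries
seconds (it divides SFPT). Closed forms: τ from the calibration triple,
and the latency limit SFPT = τ·√ln(A²/FOM), which are mutual inverses
through the score to machine precision.

SFPT is measured per frame — one `predict` per frame, monotonic clock,
frames pre-loaded in memory (load time excluded by protocol) — because a
live instrument pays per-frame overhead that batch prediction hides. The
first 10 calls are warmup and excluded. The 90th percentile uses the
nearest-rank convention (the ⌈0.9·n⌉-th smallest); both mean and p90 are
reported, and the comparison table scores FOM on the p90, matching the
benchmark table's column. Wall-clock latencies are hardware-dependent:
they are reported by the tools but never asserted against published
timings; only the FOM arithmetic on published (accuracy, latency) pairs is.

## Numerical conventions and edge cases

* Min–max stretches map a constant image to zero.
* An empty candidate list is a valid pipeline outcome (`closed`).
* A single candidate (or a criterion with no spread) normalizes to score 1.
* Degenerate (collinear) components are skipped in hull construction.
* `measure_sfpt` rejects frame lists not longer than the warmup.
* The calibration requires 0 < target FOM < A²; the latency limit requires
  A² > target FOM; both raise domain errors otherwise.
* Dataset generation writes 8-bit grayscale PNGs, a CSV manifest
  (path, label, cx, cy, visible_fraction, seed — coordinates in the cropped
  frame) and a JSON sidecar with the profile and master seed; manifests
  round-trip losslessly and unknown labels are rejected with a line number.

## Known limitations

* Synthetic accuracy is an upper bound; no claim transfers to instrument
  recordings without re-validation (see the generator's non-goals above).
* The rule pipeline's thresholds are device constants tuned for this frame
  geometry; other optics require retuning, which is inherent to the
  approach rather than a defect of the implementation.
* The deep-learning branch of the original comparison (fine-tuned CNNs) is
  out of scope; its published operating point is still scored by the FOM
  tools.
* LBP at P=100, R=5 is an unusual operating point; with the uniform-pattern
  encoding most pixels of a noisy image fall into the non-uniform catch-all
  bin, which is consistent with its poor benchmark accuracy.
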