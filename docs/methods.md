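# Methods

This note documents the measurement procedures, the synthetic ground-truth
generator, the numerical choices, and the known limitations of tomatophen.

## Coordinate and colour conventions

Pixels are indexed with the origin at the top-left, x rightward, y
downward, 0-based; polygon vertices are (x, y) pairs, matching the LabelMe
annotation dialect. Hue is reported on a 0–360° scale and saturation/value
on 0–255. The acceptance window for fruit pixels is
`h_low ≤ H ≤ h_high` and `S > s_min`, `V > v_min` — the S/V inequalities are
deliberately strict. The hue window is a preset parameter (default
[0°, 180°], the red-through-cyan half-circle) because light backgrounds and
calyx tissue are rejected by the saturation/value floors rather than by
hue; cultivar classes differ only in those floors (`pure_color`: S > 110,
V > 100; `black`: S > 30, V > 130; `mottled`: S > 120, V > 60).

## Calibration

One ruler-card image per camera setup yields the pixels-per-centimetre
scale: dark card squares are found as 4-connected components (corner-touching
checkerboard squares stay separate under 4-connectivity), filtered for
squareness (bounding-box aspect in [0.75, 1.33], fill ≥ 0.8), and the scale
is the **median** side length √area over accepted squares — robust to one
mis-detected square. Fewer than four plausible squares is a hard
calibration failure; no measurement ever proceeds with a silent default
scale. The scale is an explicit argument to every measurement operation;
there is no global calibration state.

## Vertical-cut landmarks and diameters

The fruit contour (marching squares on the filled foreground component, so
specular holes cannot split a fruit) is simplified with Douglas–Peucker at
a tolerance of `epsilon_frac` × perimeter, and each retained vertex is
labelled convex or concave by its turn direction after normalizing the ring
orientation.

* **Navel**: the concave vertex with the largest perpendicular distance to
  the chord through its nearest convex neighbours. When two or more
  candidates score within 80% of the maximum, the mean saturation of the
  crop between each candidate and the contour centroid breaks the tie
  (lowest wins — the tissue near the calyx is paler than the flesh). A
  contour with no concave vertex falls back to the bottom-most contour
  point with a `no-navel-fallback` warning.
* **Top**: the contour point farthest from the navel; its adjacent convex
  landmarks are the nearest convex polygon vertices on either side along
  the contour (vertices within 3 px of the top point are excluded so a
  retained apex vertex cannot become its own neighbour).
* **Angles**: unsigned vertex angles in (0°, 180°] between the rays to the
  adjacent convex landmarks. Reflex angles are not meaningful for these
  landmarks.
* **Diameters**: sides of the rotated minimum-area rectangle of the
  contour; the side whose direction is better aligned with the navel→top
  axis is the vertical diameter. This assignment makes diameters invariant
  to in-plane rotation of the scene (< 2% drift at arbitrary angles in the
  test suite).

**Douglas–Peucker tolerance.** The simplified polygon stays within the
tolerance of the true contour, so a retained corner vertex can sit up to
roughly that distance away from the true corner along the outline. Landmark
angles inherit an error of about tolerance / lever-arm, where the lever arm
(apex-to-corner distance) is a few tens of pixels at realistic image
scales. The default `epsilon_frac = 0.005` keeps that error near one degree
while remaining an order of magnitude above marching-squares rasterization
noise (~0.35 px); at 0.02 the landmark wander alone exceeds a 5° angle
budget. The parameter is config-exposed; raising it trades angle accuracy
for robustness to rougher outlines.

## Horizontal-cut measurements

Sections come from the same HSV isolation. Locule segmentation is a
contract: any callable from (image, sections) to scored locule instances.
The default classical backend thresholds the value channel inside each
section at the automatic bimodal (Otsu) point, requires the two classes to
differ by ≥ 25 value levels (so uniform flesh yields zero instances rather
than hallucinated structure), applies a radius-2 morphological opening,
drops components below 0.4% of the section area, and scores each instance
by its value contrast against the surrounding flesh (normalized by 64,
clipped to [0, 1]). An oracle backend replays ground-truth annotation
polygons with score 1.0; running the full measurement with it isolates the
measurement mathematics from segmentation quality.

Locules are assigned to the section containing their centroid; strays are
discarded with a warning count. Per section:

* **count** = number of assigned instances (a fruit whose weakest locule
  score falls below 0.3 is flagged low-confidence instead of having its
  count overridden — hazy-septum cases remain visible in the output);
* **area proportion** = (union of locule masks ∩ section) / section area,
  so overlapping detections cannot push the proportion past 1;
* **pericarp thickness**: for each locule, a ray from the section centroid
  (area centroid of the mask — the most noise-robust "centre") through the
  locule centroid; the thickness is the distance between the ray's farthest
  crossing of the locule boundary and its farthest crossing of the section
  boundary, averaged over locules and converted to cm. The far side is used
  because the pericarp is the outer wall; the farthest locule crossing
  handles non-convex locule boundaries. A locule exactly concentric with
  its section leaves the ray direction undefined; since a concentric locule
  has the same radial gap in every direction, a deterministic +x ray is
  used and a warning recorded. Rays that fail to cross both boundaries in
  order are skipped with a warning.

Septum tissue near the navel axis is *not* part of this measurement; the
rays measure only the radial outer gap. Joined cut halves separated by a
visible slit are a documented acquisition failure mode (the synthetic
generator can inject one); the remedy is procedural — rejoin the halves or
cut a fresh fruit — not algorithmic inpainting.

## Augmentation and splits

One annotated source image expands to 12 geometric variants (original,
three right-angle rotations, two mirrorings, six bilinear rescalings at
0.1/0.25/0.5/0.8/2/4×) plus a 5×5-kernel Gaussian-blurred copy of each,
i.e. 24 variants — the factor that takes 335 sources to exactly 8,040
images. Polygon vertices ride through the identical geometric map (pixel-
centre convention for the lossless flips/rotations; realized per-axis
factors for rescaling, so a 2× rescale doubles coordinates exactly); blur
leaves geometry untouched. The Gaussian sigma is 1.0 by default (the kernel
size is the stated constraint; sigma is config-exposed). Rescales that drop
a dimension below 8 px are kept but flagged `too-small`. The 70/20/10 split
is a seeded shuffle followed by contiguous slicing with sizes
floor(0.7 n) / floor(0.2 n) / remainder, applied to the augmented pool —
which reproduces the 5,628/1,608/804 partition; a group-aware split by
source image (recommended whenever the split feeds model training, since
variants of one fruit leak information across subsets) can be had by
splitting source ids before augmenting.

## Evaluation and verification

Matching is greedy in descending prediction score (prediction index as the
deterministic tie-break); a prediction claims the unmatched ground truth of
highest IoU when that IoU is **strictly** greater than the threshold
(default 0.5). Greedy matching is the detection-evaluation convention; the
test suite cross-checks it against an exhaustive optimal assignment on
random well-separated instance sets, where the two coincide. True negatives
are acknowledged but unused: without a negative universe they are undefined
for instance segmentation.

The precision-recall curve sweeps the unique prediction scores; AP
integrates precision over recall with the all-point precision envelope
(running maximum toward higher recall), the instance-segmentation standard;
a `trapezoid` flag switches to raw integration for sensitivity checks.
Practical re-scoring (partial segmentations with correct counts,
hazy-septum cases) is explicit: a rule list naming the FP/FN ids to
re-classify as TP, applied with a full audit log — never inferred.

Verification against manual measurements reports the relative RMSE
√(1/n Σ((Rᵢ−Mᵢ)/Mᵢ)²) (scale-invariant; undefined if any manual value is
zero), squared Pearson correlation (undefined and flagged for constant
input), a median-centred Levene (Brown–Forsythe) variance-equality p-value,
and a Welch two-sample location p-value — the unequal-variance form is the
safer default even though the variance test usually licenses the pooled
one.

## Synthetic scenes and what they do (not) show

The generator rasterizes exact polygon geometry with no anti-aliasing, so
ground-truth areas are exact pixel memberships and annotation/raster
round-trips are tight. Defaults emulate the acquisition protocol: a white
background, 3–4 fruits per image placed at intervals, a 1 cm × 1 cm
checkerboard ruler card, fill colours spanning the cultivar classes (all
with hue inside the preset window), and mild uniform speckle (±5 levels) as
texture.

* **Vertical fruits** are a lower half-ellipse belly (half-width 1.8–2.4 cm
  at 50 px/cm), a conical top whose apex angle is the ground-truth top
  angle (cohort range 95–125°), and a wedge notch whose apex angle is the
  ground-truth navel angle (50–85°), with a pale band painted inside the
  notch to exercise the saturation tie-break. The cone construction is
  chosen over a small triangle fused onto the ellipse apex because it keeps
  the apex the farthest point from the navel and makes its convex
  neighbours exactly the cone base corners, so both angles are analytically
  exact; the builder enforces the "apex farther from the navel than the
  equator corners" dominance condition and the notch depth (0.4 of the
  belly half-height) gives the wedge sides enough lever arm that one-pixel
  corner jitter stays well under the angle tolerance. Very flat tops
  (≳ 150°) satisfy the dominance condition only for strongly prolate
  bodies — which mirrors the real ambiguity of locating "the top" of a flat
  oblate fruit by a farthest-point rule. Ground-truth diameters are the
  analytic twin of the indicator: min-area-rectangle sides of the
  unrasterized polygon under the same axis-assignment rule.
* **Horizontal sections** are disks (radius 1.7–2.3 cm) with 2–6 elliptical
  locules arranged radially, pericarp 0.3–0.5 of the radius, and locule
  fill 95 value levels darker than flesh; layouts retry with shrinking
  angular jitter until all locules are ≥ 4 px apart, falling back to the
  always-valid symmetric arrangement. Ground-truth proportion and
  thickness come from exact polygon areas and the same ray construction
  the measurement uses, evaluated on the analytic polygons.

Passing on these scenes demonstrates that the *measurement chain* is
correct and numerically stable — it does not demonstrate robustness to
photographic nuisance (shadows, specular highlights, juice stains,
off-white backgrounds, blurred septa), which the generator deliberately
does not model. In particular the classical locule segmenter is a clean
baseline for the segmenter contract, not a substitute for a learned model
on real photographs with hazy septa and seed texture.

## Problem sizes

The test suite and the acceptance script use cohorts of 24 fruits
(classical recovery), 54 fruits (oracle equivalence), 200 random instance
sets for the metric cross-checks, and the full 335-source augmentation run
at 256×256 px; these sizes give stable statistics while keeping a complete
run in the low minutes on one CPU.

## Known limitations

* No lens-distortion or EXIF-based scaling; one ruler card per fixed-focus
  setup is assumed.
* Diameter axis assignment assumes the navel→top axis approximates the
  biological vertical; fruits whose min-area rectangle sits near 45° to
  that axis can flip assignment between near-equal sides.
* Automatic preset selection per cultivar is out of scope; the preset is an
  input.
* The hue window default excludes hues wrapping below 0° (e.g. magenta-red
  at ~356°); such colours need a custom threshold window.
* Locule counts for hazy-septum fruits are reported raw with a
  low-confidence flag; deciding to treat such fruits as single-locule is
  left to the analyst.
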