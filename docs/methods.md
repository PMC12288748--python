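# Methods

## Scope and assumptions

The package analyzes one scute per photograph. It assumes (i) the photo
contains an 18% gray reference card, a region of which is lit like the
subject; (ii) the scute of interest is delimited by a closed, digitally
drawn outline in a color absent from the rest of the image (pure green by
convention); and (iii) the pattern of interest is yellower than the scute
average, i.e. separable by a red-minus-blue score. Geometric distortion
from shell curvature or camera angle is not corrected; its effect is meant
to be *quantified* through the replicate-CV machinery, not removed.

## Calibration and scale

Calibration is a per-channel linear gain mapping the mean of the card
region to 0.18, followed by clipping to [0, 1]. A linear gray-card gain is
the minimal standard model; no white-balance or lens model is attempted.
The numeric target (0.18 in linear reflectance units) is a configuration
choice (`calibration_target`), since a gray card standardizes only up to
the chosen anchor. The card region is user-supplied (sidecar CSV columns or
function argument) rather than auto-detected, so a sub-region lit like the
subject can be chosen under uneven lighting. Calibration is idempotent to
numerical precision when repeated with the same region.

Scale comes from the pixel length of the card's 50 mm edge:
`mm_per_pixel = 50 / card_edge_px`. At the scales this supports
(5–20 px/mm), 1 mm² spans 25–400 px, which the mm²→px conversion
reproduces exactly by `round(area_mm2 / mm_per_pixel²)`.

Mask extraction matches the outline color exactly by default (tolerance 0):
the outline is drawn digitally after calibration, so its color is exact in
the stored file. Because the calibration gain would shift that color, the
pipeline locates the outline on the stored image *before* applying the
gain; the gain moves no pixels, so the mask remains valid afterwards. The
exterior is found by 4-connected flood fill from the border; the interior
(the scute mask) must be a single region, and a 1-px 8-connected outline is
guaranteed to seal it under this connectivity pairing.

## Pattern extraction

Four steps, in a fixed order:

1. **Dynamic threshold.** Pattern iff `R − B > τ · mean(R − B over scute)`,
   τ = 1.10 default. The mean adapts the threshold to each image's
   lighting. If the scute mean is ≤ 0 (blue-dominant), the rule is still
   applied literally and a warning is emitted, so behavior is defined on
   arbitrary images.
2. **Small-object removal.** Components (8-connected by default) smaller
   than 1 mm² are dropped; survivors have pixel count ≥ the rounded
   threshold.
3. **Hole filling.** 4-connected background components fully enclosed by
   pattern and *strictly* smaller than 1 mm² are filled; a hole exactly at
   the threshold stays open. Hole analysis is written directly on labeled
   components to guarantee the strict inequality.
4. **Edge smoothing.** Morphological opening with a square structuring
   element of side `max(1, round(0.5 mm / mm_per_pixel))` px. Opening is
   anti-extensive and idempotent; it removes protrusions and 1-px bridges
   without regrowing the pattern. Fragments that fall below 1 mm² *after*
   opening are deliberately not re-filtered — the procedure has exactly
   four steps.

Objects use 8-connectivity and holes 4-connectivity, the customary
complementary pairing. The prepattern is monotone non-increasing in τ, and
steps 2 and 4 only remove pixels while step 3 only adds them; both
properties are enforced by tests.

## Measurements

Beyond the definitions in the README, the numerically consequential
choices:

- **Perimeter and eccentricity** come from `skimage.measure.regionprops`
  (boundary-configuration perimeter estimate, moment-ellipse eccentricity).
  Cross-checks on perimeter-based quantities are asserted to 5%/15%
  tolerances, not exactly, since pixel-perimeter estimators differ at that
  level. A single-pixel object has eccentricity 0 (degenerate moments).
- **PA units.** PA is mean perimeter in mm divided by mean area in mm²
  (units 1/mm): for a k×k square at scale s it is ≈ 4/(k·s). This keeps the
  measure dimensionally consistent.
- **Peak length** skeletonizes the pattern and its complement within the
  scute and uses `2·(scute px)/(skeleton px sum)·mm_per_pixel`. The formula
  is symmetric in the two skeleton counts. For period-λ stripes it recovers
  λ within ±2 px.
- **Hue** is averaged arithmetically (not circularly), matching the
  convention of treating hue as a scalar in [0, 1). Patterns straddling the
  red wrap-around (hue ≈ 0/1) would average misleadingly; the yellow
  patterns this targets sit safely near hue 0.1–0.2.
- **Grayscale** for IC uses the standard luma weights 0.2989/0.5870/0.1140.
- **Occupation factor** uses `skimage.morphology.convex_hull_image` (hull
  of pixel corner points, filled to pixels), counted even where the hull
  leaves a non-convex scute; OF ≥ FA always.
- **Undefined values** (color statistics of an empty pattern, contrasts
  without background, etc.) are NaN with a log entry; downstream statistics
  drop NaNs pairwise instead of aborting.

### Symmetry index

The pattern's pixel set A is mirrored left-right about its centroid,
rotated about the centroid by each grid angle, rounded to the pixel grid
(duplicates merged), and translated over an integer grid; Sy is the best
overlap divided by |A|. Since |mirror(A)| = |A| up to rounding, this is
effectively intersection-over-min; an intersection-over-union variant is
available (`normalization="union"`). The initial mirror axis is irrelevant
because the search spans all rotations of the mirror copy (reflections
about any axis are conjugate by rotations); this is also verified by test.

Defaults: angles ±180° in 5° steps with a 1° refinement pass around the
best coarse angle; translations ±25% of the larger bounding-box side in
1 px steps. Overlap maxima over translations are computed exactly by
integer cross-correlation (FFT, rounded back to integer counts), which
equals exhaustive enumeration on the same grid — asserted exactly against
an independent set-intersection oracle. `downsample=2` is available for
patterns beyond ~10⁴ px, with an observed accuracy cost ≲ 0.02 on the
index (tested at 0.05 tolerance). A perfectly mirror-symmetric pattern
scores exactly 1.0 whenever the grid contains angle 0, because the
mirrored integer coordinates land back on the original set.

## Variation analysis

- Pairwise CV `|x₁−x₂|/mean` for duplicates; sample sd (n−1) over mean for
  triplicates. The identity `cv_pairwise = √2·cv_standard` (two values)
  holds exactly and is tested to 1e−12. All CVs are invariant under
  rescaling of the measure.
- Two within-individual normalizations are provided: by the pair mean
  (default) and by the per-viewpoint mean across all individuals
  (`normalization="view_mean"`). They answer slightly different questions
  (relative noise per animal vs noise on the population scale) and neither
  is asserted as canonical.
- Across-individual CV: each turtle contributes its replicate mean; CV is
  taken across turtles per (measure, view), then averaged over views.
- The noise ratio within/across flags measures above 0.10 (configurable).
- Group comparison: Welch t by default (pooled optional) since group sizes
  are typically unequal; variance-ratio F with a two-sided p; and a
  CV-difference test implemented as an F test on group-mean-standardized
  values (each group's variance then equals its squared CV), with the
  Feltz–Miller asymptotic CV test as an alternative. The exact construction
  of a "CV F test" is not standardized; both variants are labeled in the
  output. p-values are BH-adjusted per test family within each view across
  the 19 measures.
- Threshold sensitivity reruns extraction at τ ∈ {0.90, 1.05, 1.15, 1.30}
  against the 1.10 baseline and reports per-view mean FA, percent change,
  and the mean baseline-vs-test pairwise CV.

## Consensus scoring

Ties at even n score exactly 0.5 (no tie-break). Blank survey cells are
read as 0 ("category does not apply"), with the count logged, since
volunteers mark only applicable categories. Marking more than four
categories violates the survey instructions but leaves the statistic
well-defined, so it warns rather than fails. Correlations use
pairwise-complete observations; the Cook's-distance screen comes from the
univariate OLS fit of consensus on each measure (statsmodels influence
diagnostics), flagging distances > 1.

## Synthetic scenes: what they emulate and what they do not

Scenes emulate a dark scute (olive ground, default RGB 0.13/0.11/0.07)
bounded by a 2-px pure-green outline (the inner boundary ring of the scute
polygon — 2 px so rotation jitter cannot break closure), yellow-ochre
objects (default 0.55/0.42/0.08) as discs, axis-aligned stripes or
disc-union blobs, a uniform gray card painted at 0.36 (one stop brighter
than its 18% target, so the calibration gain is non-trivial), per-channel
Gaussian pixel noise (sd 0.01), and a 5 px/mm scale — the low end of the
supported 5–20 px/mm range, keeping test images small. Replicate jitter
(illumination gain sd 0.05, translation sd 1 px, rotation sd 1°, two
replicates per view) is applied to the scene *geometry* — polygon vertices
and object centers are transformed and the scene re-rasterized — so
outlines stay exact-color and each replicate carries exact ground truth.
Rasterization is center-in-shape, making pixel-count ground truth exactly
recomputable by brute force.

Deliberately not emulated: 3D shell curvature and perspective (angle
effects appear only as affine jitter), glare and specular highlights,
anti-aliased or fuzzy object boundaries, non-uniform illumination across
the card, and stripe rotation under jitter (stripes translate but stay
axis-aligned). Passing tests therefore demonstrate correctness of the
algorithms on well-posed inputs, not robustness to every optical artifact
of real field photography — the latter is exactly what the replicate-CV
framework is designed to measure on real data.

## Problem sizes and numerics

Default test scenes are 240×320 px with 2–6 objects; the acceptance-level
properties use 50 seeded scenes, 100 random ≤30×30 patterns for the
symmetry oracle, 1000 pairs for the CV identity and 1000 simulations for
t-test calibration. The threshold-sensitivity closed form uses a radius-250
px gradient disc, large enough that rasterization error stays well inside
the 2% comparison band. Coordinate convention is row-major, 0-based, pixel
centers; masks are saved as 0/255 8-bit PNG; CSV floats are serialized at
12 significant digits so reruns are byte-identical.

## Known limitations

- The R−B score targets yellow-on-dark patterns; other pattern chemistries
  need a different channel pair (the threshold step is isolated so this is
  a small extension, but only R−B is validated).
- Arithmetic hue averaging is wrong for red-straddling hues (above).
- The symmetry search cost grows with pattern size and grid resolution;
  the FFT correlation keeps the default grid tractable (~0.4 s for a
  3000-px pattern), with downsampling as the documented escape hatch.
- Pairwise-deleted NaNs mean different measures can rest on different
  animal subsets in the CV and correlation tables; group sizes are reported
  per row.
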