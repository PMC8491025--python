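# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the rootcrown3d pipeline, in processing order.

## Coordinate frame and alignment

All geometry is in millimetres; depth increases along +z with the stem top
at depth 0. An input crown arrives in an arbitrary pose, so alignment must
find the stem axis from the point cloud alone.

The coarse stage scores candidate depth axes — the three principal axes of
the point covariance and their normalized pairwise/triple combinations
(needed because a crown that is wider than deep has near-degenerate
eigenvalues, and then no single eigenvector lies near the vertical) — by
the ratio of radial spreads in the two terminal 10% windows along the
axis: the stem end is the narrow extremity. Windows holding under 1% of
the points are penalized tenfold; otherwise an isolated cluster of root
tips along a horizontal direction can win on a spuriously tiny spread.

Refinement exploits two exact properties of the stem cylinder. First,
every planar cut of a cylinder is an ellipse centered on the axis, and a
whorl's root ring is approximately azimuthally balanced, so centroids of
2 mm depth slabs trace the axis; a Theil–Sen line through them is an
unbiased estimate (a covariance eigenvector of the top window is *not*:
an obliquely cut cylinder shell has a skewed covariance, which creates a
stable wrong fixed point around 2° of tilt). Second, once the stem-only
depth window is identified from the 95th-percentile radius profile (flat
at the stem radius, jumping when the first whorl appears; the top 2.5 mm
is excluded because the stem-top cap scatters around its plane and the
cloud minimum is an extreme-value statistic of that scatter), a
least-squares cylinder fit to that window pins the axis to a fraction of
a degree. The cylinder stage is a guarded refiner, never a searcher: the
fitted radius must be 4–40 mm (a maize stem, not a root tube — a root is
also a clean thin cylinder and an unguarded fit locks onto one), the rms
residual below a quarter of the radius, and the correction below 3°.
Candidates are ranked after refinement, with a bonus when a credible stem
was found. On synthetic crowns spanning the tested envelope the residual
tilt is 0.0–0.9°.

Rotation about the vertical is left free; all traits are invariant to it.

## Level-set stack

Slicing bins points into half-open 1 mm depth slabs and rasterizes each
slab's (x, y) occupancy at 0.5 mm/px (a pixel is foreground iff it
contains at least one point; no splatting). These defaults resolve the
2 mm whorl-separation limit with margin and keep a large crown around
300×300 px.

Cleaning per slice closes 1-px sampling gaps (3×3 morphological closing)
and fills enclosed holes, turning tube-wall annuli into solid sections.
A wall with a multi-pixel sampling gap cannot be filled from its own
slice; the pipeline therefore also fills holes against the union of the
slice with its two neighbors and carries over only the *enclosed
interior* of that union — never the neighbors' foreground, which would
smear moving sections.

Inter-slice interpolation (default k = 2 intermediate frames per gap,
giving an effective 1/3 mm slice spacing) morphs signed Euclidean
distance transforms of neighboring slices and re-thresholds at zero. A
temporal-closing pass first adds any pixel foreground in both neighbors
of a slice: a contour gap present in one slice but absent above and below
is an under-sampling artifact, and pairwise morphing alone cannot bridge
it because the broken slice is an endpoint of every morph it takes part
in. k = 0 is exactly the identity. The morph assumes successive sections
overlap, which holds whenever a section moves less than its own radius
per slice — true for roots at the tested resolutions but not for
arbitrarily fast translation of small objects.

## Per-slice detection

Otsu's threshold is computed exactly over the observed gray levels with
vectorized prefix sums (a 256-bin histogram version can shift the cut
between sparse levels). Components are maximal 8-connected regions (thin
diagonal sections survive); regions under 2 px² are noise and dropped.

Entangled sections are split by marker-based watershed: markers are
local maxima of the Euclidean distance transform at least 5 px apart
within each component, and the negated EDT is flooded from them. Two
adjacent watershed labels re-merge when the EDT ridge between them
reaches 90% of the shallower marker peak: such a pair has no real valley
and is a single elongated section (a slanted root's ellipse), not two
entangled roots. Two overlapping disks of radius 12 px with centers
18 px apart have a neck ratio near 0.66 and stay split.

The active-contour refinement is a greedy snake (periodic closed
contour; each vertex moves within its neighborhood to the minimum of
continuity + curvature + edge-distance energy, in a whole-pixel phase
followed by a half-pixel polish on a bilinearly sampled field). A sweep
that fails to lower the total energy is reverted, so the energy trace is
non-increasing by construction. Defaults: α = 0.015, β = 0.1, up to 500
iterations, initialization from each component's minimum enclosing circle
dilated by 5 px. The snake is off by default in the orchestrated
pipeline: occupancy rasters already have pixel-exact boundaries, so it
adds cost, not accuracy, there; it is intended for grayscale or smoothed
stacks and is fully config-exposed.

Fitted-circle diameters are `2·sqrt(area/π)·pixel` for filled sections
and a least-squares circle through the ring pixels for annular ones
(detected when hole-filling grows the area by ≥50%).

## Tracking

One constant-acceleration Kalman filter per root (state x, y, vx, vy,
ax, ay; measurement = centroid; process noise 0.1 px², measurement noise
1 px², initial covariance 10·I) and Hungarian assignment of predictions
to detections with a 20 px gate (rectangular cost matrices padded with
the gate cost). Unmatched detections spawn tracks; a track unmatched for
more than 4 slices terminates; 5 detections are required for acceptance.
On interpolated stacks both counts scale by (k+1) — they are physical
tolerances, not slice counts.

Two rules handle entanglement. When an established track goes unmatched
while its prediction lies inside a matched detection, that detection is a
merged multi-root blob: no track absorbs its centroid (which would drag
the absorber off its lane and corrupt its velocity), all involved tracks
coast on their own dynamics, and the blob spawns nothing; at separation
each track reacquires its own lane by prediction. And a track whose
prediction lies inside foreground is occluded rather than lost: it keeps
coasting (up to 40 slices) without aging toward termination.

## Structure graph

Track fragments are reassembled in four passes, all operating on ~2 mm
resampled polylines (three-point circumradius curvature of 1/3 mm-spaced
noisy vertices measures jitter, not geometry):

* **Entanglement splitting.** A track whose own section-area profile
  shows a merged zone (area above 1.5× the pre-zone median, after the
  emergence ramp), whose post-zone polyline does not continue the
  pre-zone curve (quadratic continuation over a 15 mm horizon,
  point-to-curve distance above 2 mm), and inside whose zone some *other*
  track died (the dying partner whose root the composite absorbed) is cut
  at the zone exit. Cut pairs are excluded from re-merging.
* **Crossing resolution.** For two tracks that approach within 5 mm at a
  common depth (positions interpolated across coasting gaps), both
  pairings of (proximal head, distal tail) are scored by the continuation
  metric and tails are exchanged when the swap is smoother by over 1 mm.
* **Trace connection.** Fragments merge greedily (smallest endpoint gap
  first, to fixpoint) when the 3D gap is within 10 mm, median resampled
  curvatures agree within 0.02 mm⁻¹ and each fragment continues the
  other's extrapolation within 2 mm. A fragment resuming within 3 slices
  and 2 mm of a track's end is its continuation unconditionally — no
  other root can occupy the same tube, and endpoint geometry at an
  entanglement is too corrupted for the curvature test to mean anything.
* **Back-tracking.** Leftover short fragments walk up to the nearest
  structure point within 10 mm: a smooth continuation extends that root,
  otherwise the fragment attaches as a branching lateral if it carries at
  least 5 mm of arc (a credible lateral), else it is reported unattached.

The stem is the track present in the topmost slice with the largest
median section area; its diameter is the median corrected fitted-circle
diameter over the top 10% of slices. A track is nodal iff its emergence
lies within 1.5 stem radii of the stem axis, measured as the minimum over
the first detections of centroid distance minus the section's own
equivalent radius (the centroid of a fat root on a slim stem sits one
section radius outside the emergence point). All other accepted tracks
are lateral.

Whorls come from the cumulative nodal-area curve: each nodal root adds
its emergence-slice area once, at its emergence. Emergence is the first
detection with area ≥25% of the track median — the raw track start is
the tube shoulder, up to about a tube radius above the true emergence.
Rise onsets are slices where the per-slice increment exceeds 2% of the
curve range; onsets closer than the 2 mm resolution limit merge, and a
straggler onset within twice that limit whose nearby total rise is under
30% of the previous whorl's accumulated rise folds into that whorl (a
single late-detected root, not a new whorl). Members are assigned by
emergence depth between onsets with a 1 mm guard band. Whorls are indexed
youngest (shallowest) first; distinguishing brace from crown whorls is
out of scope. "Occluded nodal roots" counts all nodal roots not in the
youngest whorl.

## Traits

Diameters entering traits are slope-corrected and raster-debiased: a root
crossing the slicing plane at inclination γ shows an ellipse whose
equivalent-circle diameter inflates by 1/√sin γ (the local inclination
comes from the track direction), and point-in-pixel occupancy dilates a
section by about half a pixel per side, so one pixel is subtracted from
the diameter. Without both, a 30° root's diameter reads √2 too large and
volume doubles.

Per-root polylines are trimmed of leading/trailing partial sections
(area below half the track median) before angle and length fits; partial
end sections are slivers of the tube shoulder whose centroids hook off
the centerline. Nodal angle is the total-least-squares 3D line through
the proximal 70% of arc length, reported against the horizontal in
[0°, 90°]. Lengths are cubic B-spline arc lengths with smoothing chosen
from heavy to none, accepting the smoothest fit within 1 mm of the
vertices — heavy-first matters because an interpolating spline follows
centroid jitter and overstates length. Volume sums π(d/2)²·L over stem,
nodal and lateral roots.

Whole-crown traits use the pre-interpolation stack: crown diameter is the
mean minimal-bounding-circle diameter at 10 equidistant non-empty depths
(exact Welzl circle on hull vertices); eccentricity is mean minimum over
mean maximum convex-hull caliper width (pixels enter as their four
corners, so a single-pixel slice is a square, not a degenerate point, and
scores 1); density is mean foreground over hull area (slices with
collinear pixels skipped); depth is slice count × thickness; projection
radius is the exact minimal enclosing circle of all foreground pixels
projected to the horizontal plane.

Missing traits are explicit NaN, never zero, with the cause recorded in
the QC report; the second-to-third whorl distance in particular exists
only when three whorls are detected.

The whole-root descriptor is the cumulative per-slice root area
normalized by the total, linearly resampled onto a 100-point grid over
normalized depth (slice i contributes at fraction (i+1)/n, clamping
below the first slice). It is measured pre-interpolation so it does not
depend on the smoothing factor, and is invariant to uniform pixel
rescaling. Descriptor distance is the RMS difference on the common grid.

## Validation statistics

r² is the squared Pearson correlation with its two-sided test p-value.
Broad-sense heritability uses method-of-moments one-way random-effects
ANOVA: σ²_G = (MS_genotype − MS_error)/r_h clipped at zero, with r_h the
harmonic mean of per-genotype replicate counts (equal to the arithmetic
mean when balanced). The headline entry-mean basis is
H² = σ²_G/(σ²_G + σ²_e/r_h); the single-plot basis σ²_G/(σ²_G + σ²_e) is
reported alongside. With 12 genotypes × 8 replicates and σ²_G/σ²_e = 3,
the analytic entry-mean value is 3/(3 + 1/8) = 0.96, which the estimator
recovers within ±0.05 over 200 simulations.

## Synthetic crowns: what they emulate and what they do not

A crown is a stem cylinder (default 22 mm diameter) with a top cap, 2–6
whorls at increasing depths, and per-whorl nodal roots whose centerlines
start at the insertion angle and steepen toward vertical at a constant
rate per mm of arc (default 0.25°/mm). Successive whorls are azimuthally
staggered by half a root spacing, as in real crowns; per-root azimuth
jitter defaults to ±8°. Surfaces are sampled at 10 points/mm² (at 5 the
tube walls average more than one two-pixel gap per ring slice, which no
real dense reconstruction shows), noise is Gaussian along the surface
normal, dropout uniform. Centerlines begin 1.5 mm clear of the stem
surface — beyond the raster-plus-closing scale, so the generator's own
definition of emergence (visible at the whorl depth) is realizable; the
ground-truth emergence depth is exactly the whorl depth. Ground truth
(counts, depths, angles by the same proximal-70% convention, diameters,
lengths, occupancy, total volume) is computed from the noise-free
centerlines.

The generator does not emulate photogrammetric artifacts (non-uniform
density, color, ghost geometry), soil residue, root taper or branching
hierarchy beyond one level of optional laterals. Passing tests on
synthetic crowns therefore demonstrate the geometry pipeline, not
robustness to reconstruction pathology.

## Known limitations

* **Entangled parallel descent.** Curving nodal roots from different
  whorls converge toward vertical in the same radial band; when two tubes
  stay within a section diameter of each other for tens of millimetres
  they rasterize as one column. If one root terminates inside the shared
  column, its termination is unobservable in occupancy data: the
  smoothness-based splitting and swapping cannot help because both
  continuations are genuinely smooth. Youngest-whorl mean length is then
  overestimated for the affected members. On random crowns spanning the
  tested envelope (2–4 whorls, 6–14 roots/whorl, insertion angles
  30–80°, noise up to 0.25 mm, dropout up to 0.1), whorl and root counts
  are exact on roughly two-thirds of crowns, whorl spacings, angles and
  diameters almost always within tolerance, but the mean youngest length
  stays within 2% only on about a third; crowns whose steep (≥75°)
  crowded whorls emerge beneath shallower whorls' travel paths fail
  structurally.
* **Whorl separations at the resolution limit** (2 mm at the default
  1 mm slabs) are detected, but emergence-detection delays of individual
  roots under occlusion can spread a whorl's onset and occasionally split
  it into two nearby onsets, so per-separation whorl counts near the
  limit are seed-sensitive.
* **Brace vs crown whorls** are not distinguished, and the two earliest
  (merged) embryonic whorls are not resolved — consistent with the
  method's stated scope.
* The slope correction assumes locally straight tubes; for curvature
  radii approaching the tube radius the diameter correction is biased.
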