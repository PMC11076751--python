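# Methods

## Problem and scope

`neuroplan` quantifies how accurately a participant plans tumor surgery on
a layered 3D head model: how well the painted scalp region covers the
tumor's scalp projection, how close the planned incisions come to the
tumor epicenter, and whether the craniotomy outline keeps a sensible
margin around the tumor border. The package covers the measurement
methodology and the paired pre/post statistics; it does not do image
segmentation, registration, or any rendering — the phantom substitutes an
analytic geometry for the patient-specific model that a clinical pipeline
would segment from DICOM imaging.

## Assessment plane and projection

All metrics are defined in one orthographic *assessment plane*: normal =
the phantom's projection axis (superior, +z by default), origin = the
tumor centroid, with a deterministic right-handed in-plane basis. The
tumor silhouette is the outline of the mesh's orthographic shadow —
computed as the convex hull of projected vertices for convex meshes and as
the union of projected triangles otherwise. Drawings made on the scalp or
bone layer are validated to lie on their layer mesh (tolerance 1.5 mm) and
projected into the same plane.

This planar convention is a modeling choice: human assessors judging a
semi-transparent model effectively compare projections, but they could
also have measured on the curved scalp. Geodesic (on-surface) areas and
distances are out of scope; for the gently curved scalp patch above the
default tumor the difference is a few percent and is uniform across
participants, so paired comparisons are unaffected to first order.

## Area engine

Areas, overlaps, centroids and distances use exact polygon clipping
(shapely/GEOS) on regions whose curved boundaries are polygonized densely
(ellipses at 256–1024 vertices; a 256-gon underestimates an ellipse area
by ~1e-4 relative). Exact clipping makes the conservation identity
`painted = covered + excess` hold to machine precision. A rasterized area
estimator (`raster_area`, default pitch 0.25 mm) is retained purely as an
independent cross-check; its error is bounded by pitch × perimeter and
halving the pitch demonstrably shrinks it.

## Edge margins and scoring

The signed margin of a craniotomy edge is measured along the ray from the
silhouette centroid through the *edge midpoint*: margin = (distance of the
midpoint) − (distance of the outermost silhouette-boundary crossing),
positive outside the border, negative inside. This midpoint-ray rule is
deterministic and matches the visual judgment "this edge sits N mm outside
the border"; a segment-minimum alternative is available behind the
`margin_convention` switch. An edge scores one point when its margin lies
in the **closed** band [5, 15] mm (ties included; a 1e-9 mm tolerance
absorbs float noise at the boundaries). The margin-deviation sum uses the
band midpoint, 10 mm, as the acceptable standard (`standard_margin_mm`,
configurable); the exact construction of the "acceptable standard borders"
is not prescribed anywhere, so the band midpoint is an assumption. Note
the documented non-equivalence: zero deviation sum implies a perfect
score, but a small sum (e.g. 18 mm concentrated on one edge) does not.

Degenerate cases: an edge whose centroid ray misses the silhouette
boundary scores 0 (with a warning) and is excluded from the deviation sum.

## Phantom

Scalp and outer skull are concentric ellipsoids (semi-axes 90/75/80 mm and
6 mm inward; skull shell 6 mm thick), the tumor an ellipsoid centered on
the superior midline at (0, 0, 40) mm — a parasagittal location under a
gently curved scalp patch. The tumor's in-plane semi-axes are fixed at
31.2 × 27.72 mm so the silhouette area is π·a·b ≈ 2,717 mm², the reference
tumor area all coverage metrics normalize by; the 20 mm depth semi-axis is
unconstrained by any metric. No physical tumor dimensions are prescribed
anywhere — only the projected area — so the semi-axes are a reconstruction
fitted to that single constraint. Head geometry values are chosen to be
anatomically plausible; no metric depends on them beyond requiring the
tumor to fit inside the skull.

Meshes are subdivided icospheres (subdivision 4, 5,120 faces), watertight
by construction; the silhouette of the mesh (an inscribed polyhedron)
underestimates the analytic ellipse by ~0.13%, well within the 1%
calibration requirement. The voxel path samples the implicit ellipsoids on
an isotropic grid (default 1 mm; labels overwrite in priority scalp <
skull < brain < tumor) and `extract_surface` recovers a mesh by marching
cubes after smoothing the binary mask with a 1-voxel Gaussian — raw binary
contouring carries a staircase area bias of several percent that does not
vanish with pitch, while the smoothed field converges (sphere fixture:
area error 1.5% at 2 mm pitch, 0.13% at 0.5 mm). The skull layer is
represented by its outer surface; shell thickness only exists in the voxel
volume, since no metric consumes skull interior geometry.

## Cohort simulator

A `SkillProfile` holds error distributions for the four drawing tasks; one
profile draw is turned into a full annotation set *by construction*, so
every downstream metric equals its sampled parameter exactly:

* painted region = silhouette scaled about its centroid by √factor (area
  × factor) and translated in a uniformly random direction; the
  translation either comes from an explicit displacement distribution or
  is solved by bisection so the realized coverage hits a sampled target;
* linear incision = an 80 mm chord whose foot lies at the sampled offset
  from the epicenter, in a uniformly random direction;
* craniotomy = axis-aligned quadrilateral whose four midpoint-ray margins
  equal the sampled values, found by fixed-point iteration (the margin of
  one edge moves when the others move; convergence to 1e-9 mm in a few
  iterations); sampled margins are floored at 3 mm from the centroid so
  the quad stays simple;
* U-incision = three of the craniotomy edges with the base left open;
  burr holes = the four corners (stored, never scored).

This generator/metric inversion is what the tests exploit: point-mass
profiles must reproduce their parameters exactly, and distributional
profiles transfer their first two moments to the metric table unbiased.

**Default calibration.** The default profiles emulate the reference cohort
summaries (38 participants = 14 residents + 24 interns): coverage targets
are Beta on [0, 100] moment-matched to 66.4 ± 26.2 % (AA1) and 77.2 ±
17.4 % (AA2); painted-area factors and incision offsets are Gamma
(nonnegative, exact mean/SD match — residents improve from 16.3 ± 9.6 mm
to 8.3 ± 7.9 mm, interns stay at 16.3 ± 9.6 mm); per-edge margins are
Normal(10 mm, s) with s = S̄/(4·√(2/π)) so the expected margin-deviation
sum matches 57.3 mm (AA1) and 47.2 mm (AA2).

**Pairing.** Pre and post draws of each participant are coupled through a
Gaussian copula with correlation ρ = 0.8 (`ability_rho`), modeling stable
individual ability: independent draws at the reference SDs would give
paired-difference SDs (~31 percentage points for coverage) far too large
for a paired design of this size to detect anything, which contradicts the
calibration goal that the default cohort shows the reference improvement
pattern in the large majority of replicates (measured power ≈ 0.90 for
coverage at n = 38 and ≈ 0.94 for the resident incision improvement at
n = 14). Under the null (identical pre/post profiles) the copula does not
disturb test level (measured type-I ≈ 0.048 at α = 0.05).

**Randomness.** One master seed; participant i uses substream seed
`seed XOR i` (recorded in every annotation), with angles drawn
independently per assessment. Identical seeds give bit-identical cohorts.

**What the generator does not emulate.** Real drawings are free-form:
painted regions are not affine images of the silhouette, craniotomies are
not axis-aligned rectangles, and per-edge margins are correlated and
likely asymmetric. Consequences worth knowing: (i) the simulated ordinal
scores are more pessimistic than the reference medians (iid Normal margins
pinned to the reference deviation sums put ~26% of edges in the band,
median score 1 vs reference 2 [1–3] — the reference score and margin-sum
summaries are not jointly reachable by any iid symmetric margin model);
(ii) excess-coverage SDs are inflated relative to the reference because
painted area and coverage are sampled independently. Passing tests
therefore validate the measurement and inference machinery, and the
first-moment calibration of the continuous metrics — not the full joint
distribution of human drawing errors.

## Statistics

Paired t-test (scipy) for continuous metrics; Wilcoxon matched-pairs
signed-rank implemented in-package: zero differences dropped (count
reported), midranks for ties, exact null distribution by dynamic
programming on doubled midranks for n ≤ 25 (exact even with ties), normal
approximation with tie correction and 0.5 continuity correction above.
Two-sided p = min(1, 2·min tail). `auto` follows the study's usage — t for
continuous (mm, mm², %), Wilcoxon for 0–4 scores — rather than a
normality pretest. All-zero-difference samples return a flagged degenerate
result (statistic 0, p = 1) instead of an error. Descriptives: mean ± SD
(ddof = 1) or median [Q1–Q3] with linear-interpolation quartiles (the
quartile convention is stated because tools differ and it changes
Likert-style medians such as "9.5 [9–10]"). Stratified comparisons run
independently per group with no pooling; strata with fewer than two pairs
are skipped with a warning. No multiple-testing correction is applied
across the seven metrics; every comparison result carries a note saying
so.

## Problem sizes used by the test and acceptance runs

Chosen as the package's own defaults: phantom meshes at icosphere
subdivision 4; voxel fixtures at 0.5–2 mm pitch on a 120 mm sphere
phantom; conservation and invariance properties over 200 random region
pairs; Wilcoxon exactness over all-integer samples of n ≤ 8 against 2^n
enumeration; type-I calibration over 2,000 metric-level null cohorts;
power over 200 replicate cohorts; incision-offset recovery over 2,000
simulated annotations (2 SE acceptance band). Metric-level cohort
replication samples profile distributions directly — justified by the
separately verified generator/metric inversion — while single-cohort
checks run the full geometry path end to end.

## Known limitations

* Planar (projected) areas and distances only; no geodesic measurements.
* The default phantom is smooth and convex; highly irregular tumors would
  exercise the triangle-union silhouette path, which is tested but not
  calibrated against a reference case.
* The cohort simulator reproduces first moments (and SDs where feasible)
  of the reference summaries, not their joint structure; see above.
* The U-incision simulator reuses the craniotomy rectangle's limbs; real
  U-incisions need not be congruent with the craniotomy.
* Annotation JSONs store plane coordinates; 3D scalp coordinates can be
  reconstructed by ray-lifting (`lift_to_surface`) but are not persisted.
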