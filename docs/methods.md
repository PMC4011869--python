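# Methods

This note documents the models, estimators and numerical choices behind
`mandigrow`, in the spirit of a statistical-software methods appendix:
what is computed, under which assumptions, and what a passing test does
and does not establish.

## 1. Coordinate conventions and tolerances

All geometry is in millimetres in a canonical anatomical frame:
+x anterior, +y subject-left, +z superior, origin at the volume centroid
of the mesh. Distances are reported in cm, angles in degrees, volumes in
cm³. Geometric tolerances default to 1e-6 mm (support/side tests, mirror
checks) and 1e-9 rad (normal normalisation, parallelism); faces with area
≤ 1e-12 mm² are rejected at construction. Every extremal or arg-max query
breaks ties to the lowest vertex index, so all detectors are
deterministic functions of the mesh bytes.

## 2. Geometry primitives

**Volume.** Signed-tetrahedron (divergence-theorem) sum over outward-
oriented faces; refused (not estimated) for non-watertight input.
Orientation is repaired on file read: consistency by breadth-first edge
propagation, global sign by the signed volume.

**Discrete curvature.** Angle-deficit Gaussian estimate normalized by the
Meyer mixed area (Voronoi area for non-obtuse triangles, A/2 at the
obtuse corner and A/4 elsewhere). Boundary vertices are flagged and
excluded. The estimator is parameter-free and sign-stable on protruding
tips, which is all the coronoid detector needs; it is noisy on
marching-cubes meshes at flat or saddle regions, which is why the
coronoid rule is applied inside an ROI restricted to the process itself.

**Support planes.** The posterior-ramus and inferior-corpus "borders" are
operationalised as supporting (tangent) planes of ROI vertex sets. Three
strategies are implemented:

* *align* — the convex-hull facet whose outward normal best matches an
  outward hint. Exact and stable whenever the hint is (and remains) the
  tangency direction; used for the inferior corpus border, whose outward
  direction is straight down — an eigendirection of the growth map, so
  the selection is stable across timepoints.
* *contact* — the hull facet touching the most ROI vertices. Retained as
  an option; on rounded borders it competes with facets tangent along the
  rounded edge cylinder and can be marginal at coarse resolutions.
* *fit* — iterative extreme-band refinement: fit a total-least-squares
  plane to the points within a shrinking band at the extreme of the
  current direction, re-orient, and finally place the plane through the
  extreme contact point along the fitted normal (so the support property
  is exact by construction). Band widths are proportional to the ROI
  extent, making the estimate similarity-equivariant. Used for the
  posterior ramus border, which carries a flat strip: the fit converges
  onto the strip at any mesh resolution, whereas a pure best-aligned-facet
  rule locks onto whichever sliver of the rounded-edge facet continuum
  happens to match the fixed hint and made the gonion drift by ~1 mm
  across a simulated year.

**Bisecting plane.** For planes with unit outward normals n₁, n₂ the
bisector of the obtuse wedge (the side into which the normals diverge)
contains their intersection line and has normal ∝ n₁ − n₂; the direction
n₁ + n₂ lies in it and the dihedral angles to both planes are equal to
machine precision.

**Gonion.** GO is the point of the bisector–surface intersection curve
closest to the two support planes' intersection line, restricted to a
ring (default 8 mm) around the border ROIs so the infinite bisector plane
cannot latch onto distant anatomy (e.g. the contralateral corner, which
is equidistant from the corner line). Candidates are the continuous
closest approaches of every intersection-curve *segment*, not just its
vertices — vertex-only candidates quantize GO to the mesh edge spacing,
which grows with the anatomy and was the dominant error term at late
timepoints.

**Voxel round trip.** `voxelize` computes occupancy of voxel centers by
vertical-ray parity counting, with centers half a voxel inside the
bounding box so axis-aligned faces are reproduced exactly;
`voxelize_and_reconstruct` lightly smooths the binary occupancy
(Gaussian, σ = 0.5 voxel) and re-extracts the 0.5 isosurface. σ was set
so that a 0.5 mm round trip of the template moves no landmark more than
half a voxel (larger σ erodes the coronoid tip; none leaves stair-step
curvature artefacts).

## 3. The synthetic growing mandible

**Template.** An implicit surface — a parabolic-arc body tube with
elliptical cross-section, tilted rounded-box ramus plates, condylar
ellipsoids, round-cone coronoid processes and a genial-tubercle bump,
blended with a polynomial smooth union — meshed by marching cubes. The
field is evaluated at |y|, and vertices are explicitly symmetrized, so
the mesh is bilaterally mirror-symmetric to machine precision. The
default anatomy is sized to a one-month-old miniature-pig mandible
(~9 cm long, ~7 cm wide, ~40 cm³).

**Growth model.** Vertices move by a region- and direction-weighted
expansion about the centroid,

    x'_a = x_a (1 + c(t) · g_a(x)),   a ∈ {AP, ML, SI},

where g_a blends per-region rates (ramus, body, anterior, condyle,
coronoid) through smooth plateau weight fields, and the time curve
c(t) = (1 − e^{−k(t−1)})/(1 − e^{−k(T−1)}) rises from 0 at T1 to 1 at
T12. k ≈ 0.204/month is solved so half the change accrues by month 3.9 —
just inside month 4, so the fourth measurement robustly clears the 50%
mark instead of sitting on a knife edge.

Default total rates (AP, ML, SI): ramus/coronoid (1.65, 0.60, 1.60),
condyle (1.45, 0.66, 1.45), body (1.00, 0.50, 0.60), anterior
(1.20, 0.42, 0.60). These were fixed once by a constrained search:
maximize the margin of the qualitative orientation ordering
SI > AP > AI > ML (with the ramus outgrowing the body) subject to the
deformation never folding the surface, checked on the actual mesh with
headroom for between-subject jitter. Two structural choices matter:

* every automatic-landmark neighbourhood lies on a weight plateau, so the
  deformation is locally an exact diagonal affine map there — extremal
  and curvature arg-max vertices are preserved exactly across timepoints,
  and the gonion construction is covariant up to the (sub-0.1 mm)
  non-covariance of the angle bisector under anisotropic scaling;
* the coronoid shares the ramus rates (and their jitter), because the
  ramus weight field has a gradient at the coronoid apex and unequal
  rates there would distort the tip and destabilise the curvature
  arg-max.

**Between-subject variation.** Per subject: a global size factor
(SD 3%), a shared per-axis anisotropy factor on all rates (SD 4%,
clipped at ±10%), and a small per-region factor (SD 1.5%, clipped at
±3%). The per-region term is deliberately small: independent region
jitter beyond ~6% makes the map non-injective (the surface folds) at
region transitions. A smooth odd displacement field adds mm-scale
left-right asymmetry.

**Noise.** Measurement noise (default SD 0.15 mm, i.i.d. Gaussian per
coordinate) applies to the manual-landmark channel only — mesh topology
and the automatic detectors' input are never perturbed, separating
detector error from simulated observer error.

**What the generator does not emulate.** No CT physics (beam hardening,
partial volume, HU calibration), no teeth or soft tissue, no remodeling
(material points only expand; real condylar growth is appositional), no
segmentation error beyond the optional voxel round trip. A green
parameter-recovery test therefore establishes that the pipeline measures
what the deformation did to the landmarks — not that it would survive
real scan artefacts.

## 4. Growth statistics

Per series: Δ = v_T − v₁, N = Δ/v₁, d_t = v_t − v_{t−1},
p_t = 100(v_t − v₁)/Δ, half-growth month = first t with p_t ≥ 50 (no
interpolation). Δ = 0 flags the percent series undefined and returns
N = 0. Identities Σd_t = Δ, p₁ = 0, p_T = 100 hold exactly; N and p are
invariant to positive rescaling of the series.

Group means are unweighted over member parameters of the per-parameter
(across-subject) means, with nested AP subgroups (whole-mandible spans;
anterior/body; posterior/ramus). This reproduces the published summary
table's own arithmetic. Note the caveat verified in the acceptance
suite: per-pair normalized changes computed from cohort-mean initial and
final values agree with cohort-mean per-subject ratios only up to
across-subject covariance (mean of ratios ≠ ratio of means); the
residual reaches 0.05 for a few anteroposterior pairs of the published
table itself.

The orientation test is a one-way within-subject ANOVA on the four
per-subject group means, computed from the sums-of-squares decomposition
(cross-checked against pingouin to 1e-9 in the tests). Exact degeneracies
(zero error or zero effect sum of squares, relative to 1e-12 of the
total) return F = 0, p = 1 or F = ∞, p = 0 rather than a roundoff-noise
ratio. Greenhouse–Geisser ε is reported alongside the uncorrected p;
pairwise paired t-tests run when the effect is significant at α and are
flagged against the Bonferroni threshold α/6 stored at full precision
(0.008333…). The type-I error of the uncorrected test is calibrated by a
seeded 2000-replicate null simulation in the acceptance suite. ICC uses
the two-way random-effects, absolute-agreement, single-measurement form
(ICC(2,1)), clipped below at 0.

## 5. Regions of interest

The detectors' ROIs stand in for a human pointing at the gross position
of each structure. Defaults are procedural — axis-aligned boxes in
bounding-box fractions, tuned to the synthetic template family — and
overridable (YAML boxes in the canonical frame) for other anatomies. The
gonion support-plane hints default to straight down (corpus) and
posterior with an 18° inferior tilt (ramus), matching the template's
gonial angle; both are arguments of `detect_gonion`.

## 6. Known limitations

* The gonion is defined along a border that runs parallel to the corner
  line; its position *along* that border is fixed only by the curvature
  of the blended fillet, i.e. less sharply than its position across it.
* The coronoid rule ("largest curvature") is an arg-max over a noisy
  discrete field; it is reliable for a pointed process inside a tight ROI
  and would need regularisation for a ridge-like process.
* Growth is a static material expansion; no attempt is made to model the
  remodeling-based migration of landmarks over the bone surface.
* The half-growth month is reported without interpolation, so it is a
  monthly-resolution statistic by design.
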