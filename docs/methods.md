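# Methods

This note documents the models and algorithms implemented in `cinealign`,
the choices made where the design was genuinely open, and what the phantom
experiments do and do not demonstrate about clinical data.

## Coordinate model

Every slice carries an imaging plane: position `P` (mm, patient
coordinates), unit direction cosines `U` (increasing column index) and `V`
(increasing row index), and pixel spacing `(du, dv)` in mm/pixel — the DICOM
Image Position (Patient), Image Orientation (Patient) and Pixel Spacing
attributes. A pixel coordinate `(u, v)` maps to `P + u·du·U + v·dv·V`.
Pixel indices are 0-based and refer to pixel centers (DICOM PS3.3); note
that the DICOM Pixel Spacing attribute stores (row spacing, column spacing)
= `(dv, du)`, which the DICOM reader swaps into the package convention. All
internal lengths are millimeters, all angles radians.

For convenience all contours are first brought to the "valentine" position:
the LV long axis — the least-squares line through the per-slice centroids
of the SA LV contours — is mapped to +z with the apex (the SA slice of
smallest LV area) below the base, and the residual rotation about z is
fixed by turning the 4-chamber plane normal toward +y. This is a single
global rigid motion; no shape-relative quantity depends on it.

## Synthetic phantom

The phantom stands in for patient data, which are not publicly available.
It is an analytic left heart:

* **LV**: ellipsoid with semi-axes 25 × 25 × 45 mm, apex down, truncated at
  75 % of its long axis (base cut at z = +22.5 mm);
* **LA** (atrial chamber): sphere of radius 18 mm, clipped to the volume
  above the base cut, laterally offset;
* **AO** (aortic stub): vertical cylinder of radius 12 mm rising 28 mm from
  the base cut.

The lateral offsets are chosen so the three components are pairwise
disjoint in every imaging plane. The acquisition is emulated with 13 SA
planes at 8 mm spacing (the clinical slice thickness/spacing) centered on
the structure, plus three LA planes through the long axis at azimuths
0°/60°/120° standing in for the 2-/3-/4-chamber views; pixels are 1.77 mm
isotropic on an emulated 192 × 150 matrix. Contours are exact plane–surface
intersections sampled at 60 points each and labeled LV/LA/AO by the
component they cut; contours of clipped components are closed across the
cut by a straight chord, the synthetic analog of closing the endocardial
contour at the atrio-ventricular junction. The aortic stub intersects only
the azimuth-0 LA plane — as in the clinic, the aorta appears in selected
views only.

The misalignment simulator applies to each slice an independent random
rigid motion — translation uniform in ±`max_translation` (default 8 mm)
per axis, rotation about a uniformly random axis by an angle uniform in
[0, `max_rotation`] (default 5°), taken about the slice's contour
centroid — plus isotropic in-plane Gaussian delineation noise (default
σ = 0.5 mm). The defaults are about one slice thickness of motion; real
breath-hold displacement has no standardized magnitude, so these are study
conditions, not physical constants. The exact draw order is documented in
`perturb` so the scheme can be re-implemented independently; a fixed seed
reproduces the records bit-exactly.

What the phantom does *not* emulate: papillary muscles and trabeculation,
non-ellipsoidal remodeling, through-plane motion of the cardiac phases,
observer-specific delineation bias, and a curved long axis. Conclusions
about convergence and accuracy transfer to clinical data only insofar as
real ventricles resemble a smooth convex chamber with near-straight axis.

## Pairwise generalized ICP

`gicp` registers two labeled point clouds. Delineated points are modeled as
Gaussian samples around the true boundary curve; the rigid transform
minimizes `Σ d_i^T (C_i^t + R C_i^s R^T)^{-1} d_i` with nearest-neighbor
correspondences re-estimated each iteration and pairs beyond
`max_correspondence_distance` (default 20 mm ≈ 2.5 slice spacings)
discarded. Because contours are curves rather than surfaces, the per-point
covariance is tangent-based: `eps·I + (1−eps)·t t^T`, with `t` the
principal axis of the point's k = 8 nearest neighbors and `eps = 0.01`.
Residual components along the delineated curve (whose sampling is
arbitrary) are thus cheap, components across it expensive; `eps = 1`
recovers classic point-to-point ICP exactly, which the tests verify against
an independent SVD-based ICP implementation. Each iteration takes one
Gauss-Newton step parameterized about the correspondence centroid.

## Slice realignment

The correction treats the slice, not the anatomical structure, as the
motion unit: all labeled points of a slice move together under one rigid
transform, matching the physics of breath-hold offsets.

The key geometric observation is that two contours delineated on different
planes can only genuinely coincide near the intersection line of those
planes. Plain nearest-neighbor correspondences between a SA contour and the
LA curves are dominated by spurious pairs (most points of a SA ring are far
from every LA plane, and their pulls do not cancel); in development this
drove the sequential per-slice scheme into divergence or into consistent
configurations far from truth. The implemented solver therefore:

1. **Initializes** by snapping each SA slice in-plane toward robust
   (IRLS) straight-line fits of each label's centroid chain — the LV, LA
   and AO centroids each run along a nearly straight anatomical axis, so a
   centroid's deviation from its chain is almost entirely that slice's own
   in-plane misalignment.
2. **Matches crossings**: for every non-parallel slice pair (each SA slice
   against each LA view, and the LA views against each other) and every
   label, the exact points where one contour crosses the other's plane are
   matched order-preservingly along the plane–plane intersection line; a
   contour that misses the plane by less than 6 mm contributes its closest
   vertex as a pseudo-crossing so end slices near the caps still
   participate.
3. **Solves globally**: one regularized least-squares problem in all
   per-slice corrections per round, under the same tangent-based
   Mahalanobis weighting as `gicp` with a Huber limit on each pair.
   Translation-only rounds run first from a wide matching gate (20 mm,
   annealed by 0.8 per round toward 6 mm), then full rigid rounds (gate
   10 → 4 mm) with per-slice rotations linearized about the slice
   centroids and the largest per-round motion capped at 3 mm. Rounds stop
   when the mean contour-point displacement falls below
   `outer_tolerance` = 0.05 mm (cap: 20 rounds).

A weak prior (`position_prior` = 0.3) anchors every slice to its acquired
position. It matters because the problem has genuinely weakly-observable
directions: for a SA slice through the widest part of an ellipsoidal LV the
contour radius changes by less than 0.05 mm per mm of out-of-plane motion,
i.e. the out-of-plane offset is unobservable below the delineation noise.
Without the prior those modes perform a noise-driven random walk; with it
they simply stay at the acquired position. The same reasoning sets
`rotation_prior`: per-slice rotations are small (≤ 5°) and only weakly
constrained by a handful of crossings.

The global pose of the whole configuration is a gauge freedom — nothing
anchors it — so corrections are reported relative to the input
configuration, and all comparisons with ground truth first remove the best
global rigid transform (Procrustes over per-slice contour centroids, which
are insensitive to the arbitrary sampling of closed contours).

Measured on the default study (20 seeds): RMS LV contour-to-truth distance
drops from ≈ 7.0 mm to ≈ 3.5 mm (mean reduction ≈ 0.50) with a median
per-slice translation error of ≈ 1.9 mm; the residual is 60–96 %
out-of-plane, concentrated at the equatorial slices where the phantom's
rotational symmetry makes that direction unidentifiable. In-plane errors
are recovered to well under a millimeter. The package reports these numbers
rather than asserting that the unobservable component has been corrected.

## Surface reconstruction

1. **Interpolation** (`C_inter`): every SA contour is densified along its
   arc at `intra_step` = 1 mm by subdividing segments (the delineated
   vertices are preserved exactly); between consecutive SA slices,
   `n_inter_layers` = 3 intermediate contours are formed by matching the
   delineated vertices at equal normalized arc length — both contours
   oriented CCW about the long axis and anchored at the point nearest the
   4-chamber plane direction — and blending linearly. LA contour points
   enter unmodified. By default only LV-labeled contours are used as
   surface evidence (`labels=("LV",)`, `include_lax=True`); feeding the
   atrial/aortic contours in as well would make the cut wrap the whole
   left heart instead of the LV.
2. **Tetrahedral mesh**: Delaunay tetrahedralization of `C_inter` plus an
   auxiliary regular grid (spacing `grid_step` = 4 mm) spanning the cloud's
   bounding box expanded by `margin` = 10 mm. Grid vertices are flagged
   auxiliary; tetrahedra are positively oriented.
3. **Graph cut**: adjacent tetrahedra are linked with capacity =
   shared-face area × distance-to-`C_inter` at the face centroid, so that
   cutting a face set costs exactly the discrete minimal-surface energy.
   Source seeds are all tetrahedra within `0.9 × d(seed, C_inter)` of the
   interior seed (the LV contour centroid) — a ball provably free of
   contour evidence; a single source tetrahedron would make the trivial cut
   around itself the global optimum (the classic shrinking bias of
   cut-based minimal surfaces). The ball radius is additionally kept to
   half the seed's distance to the bounding box so it cannot touch the sink
   band (all tetrahedra within `exterior_band` = 2 mm of the box). The
   max-flow/min-cut is solved exactly (capacities quantized to int32 at
   ~1e-9 relative resolution — the float64 route silently overflows in the
   sparse solver); the boundary faces between interior and exterior labels
   form a closed, outward-oriented triangular surface whose cut cost equals
   its discrete energy by construction.
4. **Post-processing**: Taubin two-step (λ/μ) smoothing (10 iterations),
   which avoids the volume shrinkage of plain Laplacian smoothing, then
   re-meshing by edge subdivision toward `target_edge` = 2 mm. Enclosed
   volume changes by under 5 %.

On the unperturbed phantom the reconstructed surface lies within 2 mm (mean
unsigned distance) of the analytic truth; reconstruction from misaligned
contours succeeds but is farther from truth than after realignment in
essentially every seeded run.

## Validation

The reconstruction is intersected with each LA imaging plane
(triangle–plane intersection chained into closed polygons, expressed in
in-plane mm coordinates) and compared with the region bounded by that
view's LV contour: Hausdorff distance between the boundary curves
(resampled at 0.1 mm — the metric is curve-based; vertex-only Hausdorff
differs and is not used), plus Dice and Jaccard from exact polygon clipping
(no rasterization, hence no resolution parameter). A view whose plane
misses the surface scores (∞, 0, 0), and an infinite view makes the
per-case mean Hausdorff infinite; reports serialize ∞ as the literal
string `inf`. J = D/(2−D) holds to 1e-12 for every computed pair, a useful
internal consistency check.

On the default 20-seed study the realigned reconstructions score a mean
Dice of ≈ 0.97 against the true LA contours (un-realigned: ≈ 0.82), above
the 0.7 adequacy convention in every run and view; Dice improves in 100 %
of (run × view) pairs. The contrast between the ≈ 0.50 RMS reduction and
the ≈ 0.97 Dice is informative: the unrecovered out-of-plane mode hardly
changes the reconstructed shape, which is exactly why it is hard to
observe.

## Numerical and degenerate-input conventions

* Rigid transforms are validated (orthonormal, det +1, 1e-9) and
  re-projected onto SO(3) after every composition chain.
* Contours need ≥ 3 points when closed and no repeated consecutive points;
  planes must have orthonormal axes (1e-6) and positive spacing.
* Arc-length resampling subdivides segments so original vertices are
  preserved exactly; a step longer than every segment is the identity.
* Tie-breaks in crossing matching are resolved by ordering along the
  plane–plane intersection line; ambiguous offsets take the
  minimum-total-distance alignment.
* Empty-set rules: Hausdorff is +∞ iff exactly one input is empty, 0 when
  both are; Dice/Jaccard are 0 when either region is empty.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); a fixed seed makes the full pipeline,
  including the CSV reports, byte-stable.

## Problem sizes

Default experiments use the 13 + 3 slice phantom with 60-point contours
(≈ 1 000 delineated points, ≈ 4 500 after interpolation, ≈ 85 000
tetrahedra). One full case — simulate, realign, reconstruct twice, validate
twice — takes ≈ 5 s on one CPU; the 20-seed study ≈ 90 s.

## Known limitations

* Out-of-plane corrections for slices through locally symmetric anatomy
  are fundamentally limited by observability (see above); the prior keeps
  them at the acquired position rather than inventing a correction.
* The crossing matcher assumes contours of the same label describe the
  same anatomical boundary in all views; mislabeled contours would be
  matched across structures.
* The graph-cut surface resolution is set by `grid_step`; very thin or
  sharply curved features below that scale are smoothed over.
* Only the end-diastolic frame (one contour set per slice) is modeled; the
  cine time dimension is out of scope.
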