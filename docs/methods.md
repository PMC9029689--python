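# Methods

## Problem and approach

Surface models of segmented anatomy (brain, ventricles, bone, kidney) are
built from binary masks on the MR voxel lattice.  The two standard routes
have complementary failure modes:

- **Marching Cubes / Flying Edges (FE)** follows the mask faithfully but
  produces staircase artifacts that must be removed by a smoothing
  post-process, and smoothing pulls the surface away from the data.
- **MPU implicits** (multi-level partition of unity) are smooth by
  construction — local quadrics blended by a partition of unity — but one
  tolerance parameter `tol` controls both smoothness and accuracy, so a
  smooth result can round off narrow features or distort small structures.

The hybrid method runs both, compares them triangle by triangle against the
segmentation boundary, keeps whichever triangle is locally closer, merges
the kept triangles' vertices into one oriented point cloud and refits an MPU
implicit with a small tolerance.  For each MPU triangle with centroid
`C_MPU`, the nearest FE triangle centroid `C_FE` and the nearest boundary
point `P` are found and the winner is

    delta(T_MPU, P, T_FE) = min(||C_MPU - P||, ||C_FE - P||).

Because the merged cloud is much denser than the original boundary cloud, a
small refit tolerance (default: a quarter voxel) yields a surface that is
simultaneously smooth and close to the segmentation.  By construction the
mean of `delta` never exceeds the mean centroid-to-segmentation distance of
either input mesh; the end-to-end guarantee (hybrid mean distance at most
that of FE and of MPU, up to a 0.1-voxel slack) is verified on phantoms by
the test suite.

## Coordinate conventions

Voxel (i, j, k) of a mask sits at `origin + (i, j, k) * spacing`
(voxel-center convention, 0-based, world units mm).  Anisotropic spacing —
e.g. the 1:1.3 in-plane-to-slice ratio typical of clinical acquisitions — is
carried through gradients, meshes and metrics.  Out-of-bounds voxels count
as background, so objects touching the array border get closed surfaces
(masks are additionally padded by one background layer before extraction).

## Isosurface extraction

The extractor implements the 256-case Marching-Cubes lookup organized as the
Flying-Edges pass structure: (1) x-edge classification with per-row counts
and trim intervals, (2) y/z-edge classification, (3) output sized from the
counts, (4) vertex interpolation and per-cube triangulation.  Execution is
serial; row independence of the metadata is asserted by a test rather than
exercised by threads.

The case table is generated at import time rather than transcribed: on every
cube face the isosurface crossings are paired so that each maximal run of
*inside* corners (value >= isovalue; ties inside) is cut off by one segment,
the pairs chain into closed loops, and loops are fan-triangulated with
normals oriented from inside to outside.  The pairing depends only on the
face's absolute inside/outside pattern, so the two cubes sharing a face
always triangulate it identically — the surface is crack-free for all 256
configurations, ambiguous faces included, with a fixed rule rather than an
asymptotic decider.  Extended 33-case tables and topological disambiguation
are out of scope.

Vertices are welded exactly by edge index (no coordinate hashing).  On a
linear field every vertex reproduces the isovalue to machine precision.
Triangles of exactly zero area (possible when a sample ties the isovalue)
are dropped after construction.

Smoothing is Taubin's lambda/mu filter (lambda = 0.5, mu = -0.53, 20
iterations by default; delegated to trimesh), a volume-preserving low-pass
chosen as the standard staircase remover; the filter family and parameters
are config-exposed because pipelines differ on this point.

## MPU implicit

An octree covers the oriented boundary cloud.  Each cell gathers points
within `R = alpha x cell diagonal` (alpha = 0.75), growing `R` in 10% steps
until at least `n_min = 15` points are covered, and fits

- a **bivariate quadric** over the plane orthogonal to the mean normal when
  all local normals lie within 90 degrees of the mean (single-sheet patch), or
- a **general trivariate quadric** constrained by off-surface points at
  `+/- d` along the normals (`d` = half the local point spacing; auxiliary
  points closer to another input point than to their parent are discarded), or
- a **plane** when either system is rank-deficient (never fails).

Sharp-feature fits of the original MPU formulation are omitted: smooth
anatomy does not need them.  The fit error is the Taubin first-order
distance `|f(p)| / ||grad f(p)||`, taken as a maximum over the support
points after scaling by the cell's own blending weight normalized to peak 1.
Cells whose error exceeds `tol` split into eight children (default max
depth 8); child octants whose initial support ball is empty are excluded
from the blend, and if all children of a splitting cell are empty the parent
fit is kept as the leaf.

The global field blends leaf quadrics with quadratic-B-spline bumps
`b(1.5 r / R)` — non-negative, C1, compactly supported — normalized to a
partition of unity over the covered region.  Sign convention: negative
inside, positive outside.  Queries outside every support ball (deep object
interior, far exterior) return the signed distance to the nearest input
point oriented by that point's normal.  An earlier variant extrapolated the
nearest leaf's quadric there; a quadric's second sheet can re-cross zero far
from its cell, which fragmented polygonized meshes with spurious sub-voxel
components, so the oriented-point fallback is used instead (the coverage
flag still reports when it was taken).

Polygonization samples the field on a uniform grid (default: half the
smallest voxel spacing) over the cloud's bounding box plus a three-step
margin and reuses the shared extractor at isovalue 0 — with no smoothing
post-process, since smoothness is intrinsic to the implicit.

The build is fully deterministic: no randomness anywhere, point order fixed
by the input.

## Hybrid stage choices

- Matching is one-directional (MPU -> FE) by nearest *centroid*; exact
  point-to-triangle distance is deliberately not used for matching because
  the selection rule is defined on centroids.  A symmetric mode (union of
  both directions) exists behind a flag, default off.
- Ties `d_mpu == d_fe` go to FE, the mask-faithful method (configurable).
- Welding tolerance defaults to 1e-6 of the joint bounding-box diagonal
  (exact-share welding); merged points average their sources' positions and
  carry renormalized area-weighted average normals recovered from the source
  meshes — normals are not re-estimated from the volume.
- FE triangles matched by no MPU triangle are dropped (the one-directional
  reading); duplicated FE winners are deduplicated, not down-weighted.

## Metrics

- **Absolute distance**: for each segmentation boundary point, the exact
  Euclidean distance to the nearest point *on* the mesh surface (vectorized
  closest-point-on-triangle with KD-tree candidate pruning whose ball radius
  provably covers every possibly-closer triangle, so the result equals an
  exhaustive scan).  Statistics are reported seg -> mesh in the
  Min / Max / St dev / Mean / % < 0.5 / % < 1.0 layout; "% <" uses
  non-strict comparison (<=).
- **Hausdorff**: symmetric max-of-min over point sets; meshes are sampled at
  10 points/mm^2 (area-weighted, fixed seed) plus all vertices.
- **Mean curvature**: cotangent Laplacian with Meyer mixed (Voronoi-safe)
  vertex areas, `|H| = ||sum (cot a + cot b)(v_i - v_j)|| / (4 A_mixed)`;
  boundary/non-manifold/zero-area vertices are skipped and counted.
- **Color maps**: per-vertex values on a linear blue -> green -> red palette,
  written as colored PLY.

## Phantoms

Reconstruction cannot be validated on its own output, so the test fixtures
are voxelized analytic shapes with exact signed-distance ground truth:
sphere (r = 10 mm; low curvature), torus (ring 7 mm, tube 3 mm; sustained
high curvature), narrow-neck dumbbell (6 mm lobes, 2 mm neck; the feature a
loose tolerance rounds off) and a two-component object (8 mm spheres, 3 mm
gap; the component-merging failure mode).  Grids are at most 40 voxels per
axis at 1 mm spacing so the full three-method pipeline runs in seconds per
phantom.  Masks are clean (no noise) because the inputs of interest are
binary segmentations; an optional deterministic voxel-flip flag exists for
robustness experiments only.

What the phantoms do not emulate: partial-volume effects, segmentation
errors, the sparse slice spacing of clinical contour stacks, and anatomical
surface texture.  Passing the phantom suite shows the geometry pipeline is
correct and the hybrid selection behaves as designed; it does not quantify
accuracy on clinical data.

Two phantom-specific observations worth recording:

- On the two-component fixture the intermediate MPU never actually merges
  the components: the normal-constrained general quadric resolves two
  facing sheets at every tolerance (component merging arises on sparse
  clinical contours).  The guarantee tested is that the *hybrid* output
  keeps two components even under a deliberately loose tolerance.
- The tolerance-accuracy sweep is run on points lying exactly on the
  analytic sphere.  On the voxelized boundary cloud the quantization bias
  (boundary voxel centers sit up to ~1 voxel inside the true surface)
  dominates: tighter tolerances then track the staircase, not the sphere.

## Numerical choices and degenerate inputs

- Straddle test: endpoint inside iff value >= isovalue, so the
  interpolation denominator is never zero on a crossing edge.
- Normals from the mask: Gaussian smoothing (sigma = 1 voxel,
  nearest-mode padding to keep planar symmetry exact at grid borders) and
  central differences divided per-axis by spacing, negated and normalized.
  A zero gradient falls back to the mean direction toward background
  6-neighbors; a perfectly symmetric isolated voxel gets an arbitrary
  deterministic +z normal with a warning (at sigma = 0 it is an error).
- All-zero and all-one masks are rejected before boundary extraction;
  empty selections and empty point sets raise immediately with the stage
  name attached.
- Degenerate (zero-area) triangles are filtered; duplicate points are
  welded by single-linkage clustering within the weld tolerance.

## Problem sizes

Defaults used throughout tests and the reproduction script: phantom grids
28-40 voxels per axis, boundary clouds of 1-2 thousand points, polygonization
at 0.5 mm, meshes of 10-20 thousand triangles.  These sizes make every
documented check reproducible on a laptop-class single core in seconds while
remaining large enough that boundary effects, anisotropy and topology are
exercised.

## Known limitations

- Orientation metadata of NIfTI files is reduced to voxel spacing plus
  origin; oblique direction cosines are not applied (masks are treated in
  their voxel frame).  NRRD support covers raw and gzip encodings.
- Strictly one-directional matching can drop FE surface regions with no MPU
  counterpart; the symmetric flag exists but changes the method.
- Self-intersecting contours are filled as drawn (with a warning), not by a
  strict even-odd rule.
- The FE pass structure is kept but executed serially; no shared-memory
  parallelism.
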