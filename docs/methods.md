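# Methods

This note records the models the package implements, the conventions it had
to fix where the method description leaves freedom, and what the synthetic
test data does and does not establish.

## Tri-state voxel classification

The classifier assigns every voxel (a, b, c) a state with respect to the
closed contour polygons of its slice: −1 outside all contours, 0 on a
contour, +1 inside. Slices are independent — no interpolation between
contours of neighbouring slices — and a slice with no polygons is entirely
outside.

Conventions fixed here:

- **"Inside" across multiple polygons** defaults to the even-odd rule, so a
  hollow organ's nested wall contours leave the lumen outside. The literal
  reading — inside at least one polygon — is available (`rule="any"`) and
  fills the lumen; the hollow-organ reading is the default because it matches
  the anatomy the pipeline targets.
- **Point-in-polygon** is ray casting with a half-open edge convention (an
  edge covers the half-open y-interval of its lower endpoint), making results
  deterministic for points level with polygon vertices.
- **The 0 state** is decided first, from the exact Euclidean distance to the
  nearest polygon segment, with tolerance `on_tolerance` (mm, default 0: the
  0 state then arises only from exact hits, or from `classify_implicit`'s
  `zero_tolerance` band on sampled implicit functions). Enlarging the
  tolerance can only grow the 0 set, never shrink it.

## Surface extraction

A marching-cubes variant on the tri-state labels:

- Corner states reduce to binary for the case-table lookup with 0 counted as
  inside (0-state voxels lie *on* the surface, so they belong to the closed
  region the surface bounds).
- Each sign-crossing cell edge contributes a vertex at its exact
  **midpoint**; a crossing edge whose inside endpoint is 0 snaps its vertex
  onto that grid point instead, so the surface passes through 0-state voxels
  exactly. Snapping can collapse triangles; degenerate ones are dropped.
  Every vertex coordinate is therefore a multiple of half the voxel spacing.
- The label volume is padded with −1 so regions touching the border close.
- Vertices are welded by exact cell-edge (or grid-point) identity, never by
  floating-point proximity; the mesh is edge-connected across cells by
  construction.

**Case table.** The 256-entry table is generated at import rather than
transcribed. For each corner configuration, every cube face is cut by its
2-D marching-squares segments; the ambiguous face (diagonal insides) is
resolved by a fixed convention — *separate the negative corners*, i.e. the
inside region connects across the face. Segments are oriented so the inside
region lies to the right viewed from outside the cell, chained into closed
loops over the cell boundary, and fan-triangulated with outward winding.
Because a face's segments depend only on that face's corner states, which
the neighbouring cell shares, adjacent cells always agree and the mesh is
crack-free; any field whose inside region avoids the (pre-padding) border
yields a surface in which every edge borders exactly two faces.

**Relation to a trilinear reference.** On ±1 labels the trilinear
interpolant's saddle on an ambiguous face is exactly 0, so a reference
marching-cubes run *at* level 0 resolves those faces by an implementation
tie-break (two stock implementations disagree with each other there). The
fixed convention above equals the trilinear topology in the limit level → 0⁻;
the test suite therefore compares enclosed volume at level 0 (identical
midpoint geometry, observed agreement ~0.2 %) and Euler characteristic at
level −0.1 (any level in (−1/8, 0) selects the same reference topology).
One residual difference is *interior* ambiguity: this package triangulates
each boundary loop of a cell as a disk and never builds a tunnel through a
cell, while a trilinear reference tunnels in some four-corner configurations
whose interior saddle is also exactly at the level. On smooth blob fields
this affects topology in roughly one field in ten; geometry is unaffected.

**Normals.** At grid points the outward normal is the negative
central-difference gradient of f, M = ((f(a−1)−f(a+1))/2, …), pointing from
the inside (+1) toward the outside (−1); one-sided differences at volume
borders. Midpoint vertices average their two endpoint normals before
normalization. Where the difference vanishes (locally constant labels) the
normal falls back to the area-weighted mean of incident face normals. On a
64³ sphere all vertex normals point outward and the median angular deviation
from the exact radial is ≈ 13° — the price of quantized labels and midpoint
placement, halved at each refinement.

## Simplification (deletion algorithm)

Edges are ranked by Y(s) = Ct·T(s) + Cx·X(s) + Cg·G(s) and collapsed
cheapest-first onto their midpoints. Conventions and parameters:

- **T(s) ∈ [0, 2]**: max of 1 − L̇ᵢ·L̇ⱼ over all unordered pairs of unit
  normals of the triangles incident to either endpoint of s (0 coplanar,
  1 perpendicular, 2 fold-back). Taking the pool over both endpoints makes T
  sensitive to everything a collapse of s can distort.
- **X(s) ∈ [0, 1]**: 1 − min q over incident triangles with the mean-ratio
  quality q = 4√3·A/(a²+b²+c²), which is exactly 1 for an equilateral
  triangle and 0 in the degenerate limit. The shape coefficient is named but
  not defined in the source method; this standard quality measure is the
  package's substitution.
- **G(s)**: edge length divided by `length_scale` (default: the input mesh's
  mean edge length), making the three terms commensurable. Default weights
  Ct = Cx = Cg = 1; no weights are prescribed by the source method, and the
  defaults treat the three penalties as equally important at the scale of
  one mean edge.
- **Ordering**: lowest Y first (flat, well-shaped, short neighbourhoods are
  the cheapest to remove), ties broken by the smaller sorted vertex pair.
  The collapsed vertex sits at the edge midpoint — deliberately not a
  quadric-optimal point, to keep the algorithm the priority-function method
  rather than QEM.
- **Validity**: a collapse must pass the link condition (the common
  neighbours of the endpoints are exactly the vertices opposite the shared
  faces) and may not rotate any surviving face normal by more than 90° or
  create a zero-area face. Interior collapses remove exactly 1 vertex,
  3 edges and 2 faces, so watertightness and Euler characteristic are
  preserved.
- **Queue**: a binary heap with lazy invalidation (stale entries are skipped
  via per-edge stamps); after each collapse, priorities are recomputed for
  all edges with an endpoint in the modified neighbourhood. The behaviour is
  identical to exhaustive recomputation, which the test suite verifies
  step-by-step on meshes under 200 faces.

Decimating a ~5000-face sphere to 10 % of its faces changes enclosed volume
by under 3 % and preserves topology.

## Diagnostics

Accuracy, specificity and sensitivity are computed from the confusion counts
with `fractions.Fraction` (exact rationals; floats on request), raising a
named error whenever a denominator is empty. The ROC curve uses the
prediction rule score ≥ threshold (ties predicted positive), thresholds at
the unique scores in descending order plus a sentinel above the maximum, and
the trapezoidal AUC — which equals the tie-aware Mann–Whitney concordance
probability exactly, a property the suite checks to 1e−12 against a
brute-force pairwise count. No confidence intervals are reported.

## Synthetic data

- `make_sphere`: implicit signed distance, closed-form volume and area — the
  calibration object for every geometric claim.
- `make_bladder_phantom`: an ellipsoidal shell (outer radii 24×20×18 mm,
  wall 3 mm — a moderately full bladder) with spherical lesions of radius
  4 mm seated on the inner wall at seeded random directions, emulating
  broad-based papillary masses. Ground truths are fine-grid numeric
  estimates (voxel counting and iso-surface triangulation at 96³) and are
  flagged approximate; there is no closed form for the shell-lesion union.
- `make_blob_grid`: Gaussian-smoothed (σ = 2.5 voxels) seeded white noise
  thresholded at its 65th percentile — smooth, compact structures at 32³
  used to stress surface extraction against an independent implementation.

What the phantoms do **not** model: CT physics (noise, beam hardening,
contrast timing), partial-volume intensity profiles, or segmentation error.
Passing tests establish the geometric and algorithmic correctness of the
pipeline on clean labels, not clinical accuracy; the published diagnostic
performance of reconstructed CT in the motivating cohort cannot be
recomputed without patient data, and the package makes no attempt to.

## Problem sizes and determinism

The test suite reconstructs spheres at 48³–96³ (radius 12 mm over a 32 mm
domain), compares against the reference implementation on ten 32³ blob
fields, and verifies greedy optimality on meshes ≤ 200 faces — sizes chosen
so every geometric property is exercised at more than one resolution while
the whole suite stays interactive. All randomness flows through explicit
integer seeds; two pipeline runs with the same configuration and seed write
byte-identical STL files.

## Known limitations

- Slice contours are consumed, not produced: segmentation of real CT
  intensities is out of scope.
- Midpoint placement trades sub-voxel accuracy for robustness; volumes
  converge with resolution but surface area retains a staircase bias.
- NIfTI is the only volume format (axis-aligned affines only); meshes are
  STL/PLY/OBJ without colour or texture attributes.
- Boundary (open-mesh) edge collapses are supported only in the generic
  link-condition form; the pipeline's own meshes are closed by padding.
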