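# Methods

## Geometry pipeline

Planning operates on triangle meshes in world millimetre coordinates.
Meshes come either from STL/PLY files or from labelled volumes on regular,
axis-aligned voxel grids (voxel-centre convention, `world = origin +
index·spacing`). NIfTI affines with axis permutations and flips are
normalised to that convention; oblique or sheared affines are rejected
outright rather than resampled, because a silently misinterpreted
orientation is a patient-safety hazard in this application.

Cranial bone is segmented by Hounsfield thresholding (`threshold_mask`,
`mask = intensity ≥ threshold`). A brain/dura safety margin is produced by
anisotropy-aware Euclidean dilation (`dilate_mask`): a voxel is foreground
iff its centre lies within the margin (default 0.5 mm) of a foreground
centre, computed exactly via the Euclidean distance transform with the
voxel spacing as sampling. This dilation is a deliberately simple,
conservative construction for the margin around the dura; more elaborate
region-specific margin protocols exist in clinical practice but are not
reproducible as an algorithm, so the package keeps the transparent one.

### Surface extraction

Surfaces are extracted per label with marching cubes at iso-level 0.5 on
the binary indicator, padded with background so every surface is closed —
the containment tests in planning require watertight obstacles. Labels are
binarised one at a time, avoiding multi-label topology ambiguity.

Marching cubes on a *raw* binary mask carries a staircase bias: the
surface area of a digitised ball converges to ~109% of the true area no
matter how fine the grid (measured 8.5–9.3% over spacings 0.125–1.0 mm).
The extractor therefore anti-aliases the indicator with a narrow Gaussian
(σ = 0.8 voxel) before extraction, which restores sub-voxel surface
placement (ball-area error ≤ 0.6% across the same spacings, with an
accuracy floor of about half a percent below ~0.5 mm spacing). The filter
would erode structures thinner than about two voxels below the iso-level
entirely — a silent loss of a critical structure — so structures whose
maximum interior depth is < 2 voxels are automatically extracted from the
raw indicator instead (`smoothing="auto"`). Structures thinner than one
voxel are at the mercy of voxelisation either way; segment such structures
with a margin or supply them as meshes directly.

## Distance queries

The clearance of a drill axis is an exact segment-to-triangle-mesh minimum
distance. The per-triangle kernel decomposes the minimum into the
candidates that can realise it: a proper segment–plane crossing inside the
triangle (distance 0), the three segment–edge pairs (two-stage clamped
closest points between segments), and the two endpoint–triangle pairs
(plane projection with barycentric test, else edge clamping). For sliver
triangles (‖n‖² ≤ 1e−16 mm⁴) the plane branch is numerically meaningless
and is skipped; the edge candidates bound the interior within the sliver
height, far below any tolerance used here. Triangles with ‖n‖² ≤ 1e−30 are
degenerate and rejected (mesh construction already removes faces with area
≤ 1e−12 mm²).

Two query paths share this kernel: a brute-force scan over all triangles,
and a pruned scan that first computes a lower bound per triangle (distance
between the segment's and the triangle's axis-aligned bounding boxes),
seeds an upper bound with the exact distance of the nearest-box triangle,
and evaluates only triangles whose bound does not exceed it. Pruning can
only discard triangles that provably cannot attain the minimum, so the two
paths agree bitwise; the test suite asserts equality within 1e−9 mm on 200
randomised mesh/segment instances. For planning runs that evaluate
thousands of candidate entries against the same critical set, the
structures' triangles are concatenated once (`_MeshGroup`) — an
arrangement identical in outcome to the per-structure loop, chosen purely
to amortise per-call overhead.

Point-in-mesh containment (a segment lying wholly inside an obstacle has a
positive wall distance but is obviously not drillable) uses ray parity
with a vectorised Möller–Trumbore intersection; hits too close to an edge,
vertex or the ray origin are ambiguous and trigger a retry along the next
of four fixed, incommensurate directions. Non-watertight meshes skip the
containment test with a logged warning.

Feasibility is non-strict: a clearance exactly equal to the required
radius passes. The reported per-trajectory "distance" is the clearance of
the drill *axis*, not of the cylinder surface; the report metadata states
this.

## Planning

`required_clearance = drill_radius + safety_distance + drill_inaccuracy`
is the single derived quantity used everywhere. Defaults: drill radius
0.5 mm (1 mm drill, the working default of the protocol); safety distance
and inaccuracy default to 0 because their right values depend on the
scanner, fiducial and drill-guidance setup and must be chosen per case —
the bundled phantom configuration uses 0.5 mm and 0.2 mm respectively.

Candidate entries are skull triangle centroids within a Euclidean radius ρ
of the seed after snapping the seed to the nearest centroid (geodesic
distance would differ on strongly curved surfaces; Euclidean is the
simplest well-defined reading and is what the tests pin down). Candidate
order is distance-to-seed with index tie-break, making all outputs
deterministic. The skull itself is never an obstacle (it is the drilled
medium); the target's own structure and any structure explicitly listed as
noncritical (e.g. the ossicles when planning a round-window approach for
cochlear implantation) are excluded from the collision set.

The maximum safe diameter is `2·(clearance − s − e)`, floored at zero: the
largest drill whose radius still leaves both margins intact. When the
critical set is empty the clearance is reported as +∞ and the diameter as
unbounded rather than erroring, since degenerate configurations occur in
testing.

## Triple selection

The two clinical selection criteria — maximise the distance to critical
structures, and maximise the spread between ports — are automated as

    score = w_c · (min clearance / max clearance of the candidate set)
          + w_a · (CA / 540°),

with default weights w_c = w_a = 1 exposed in the configuration. The
normalisation by the candidate set's maximum clearance (not the triple's
own) keeps scores of competing triples comparable and makes the score
strictly monotone in the triple's minimum clearance. 540° is the
unattainable supremum of the cumulative angle. The search is exhaustive
over all triples of the `m_cap` highest-clearance candidates (default 40;
`None` disables the cap), with ties broken by larger CA, then by
lexicographically smaller entry coordinates, so the result is independent
of input order. Note that on finely meshed skulls the top-`m_cap`
candidates can be spatially clustered (adjacent triangles), which keeps
the selected CA small; raising `m_cap` or `w_a` trades run time for
spread.

Merge length uses the exact rigid-geometry formula
`L = (r₁+r₂)/(2 sin(α/2))`; a parallel pair returns +∞ ("infinite
overlap") rather than a number.

Diameter summaries per entry region use type-7 (linear-interpolation)
quartiles and Tukey 1.5·IQR outliers; the convention is stated here and in
the output because statistics packages differ in their defaults. Region
labels are user-supplied per-triangle IDs; the azimuthal-sector labeling
shipped for phantoms is a stand-in for anatomical parcellation, which is
out of scope.

## The phantom

The synthetic scene replaces segmented patient CTs. Its bone is a
hemispherical dome shell with a floor slab (a closed "pot"), outer radius
65 mm and thickness 5 mm in the bundled scene, with targets 25, 40 and
55 mm beneath the apex — depths comparable to the round window, internal
auditory canal and petrous apex. Obstacles are spheres (cochlea, jugular
bulb, ossicle mass), capsules (facial nerve, chorda tympani, carotid
artery) and a torus arc (semicircular canal). The primitive vocabulary was
chosen for testability: each primitive supports voxelisation, a directly
generated inscribed mesh with a computed chord-error bound, and a
closed-form (sphere: point–segment distance − R; capsule:
segment–segment distance − r) or 1-D-minimised (torus arc: multi-start
bounded minimisation over the arc parameter) clearance to any segment.
Mesh resolution is chosen adaptively to meet a chord-error tolerance
(default 0.05 mm); sphere and capsule bounds are exact (computed from the
mesh), the torus bound is the conservative sum of tube and arc sagitta.

Voxelisation default spacing is 0.25 mm isotropic, the scale of clinical
temporal-bone CT; the bundled three-target scene and the test phantoms use
0.5–1.0 mm so the full pipeline (10⁶–10⁷ voxels, 10⁵–10⁶ skull triangles,
10³–10⁴ candidate entries) runs in seconds to a couple of minutes on one
CPU. Overlapping primitives are an error, not an overwrite, so every label
has one owner.

`random_scene` guarantees by construction a corridor of recorded clearance
c* = 1 + 3·(1 − difficulty) mm from the dome apex to each target:
obstacles are rejection-sampled to keep c* plus an internal 1.5 mm slack
(absorbing entry-point snapping to mesh centroids and chord error) from
the corridor, to stay inside the cavity, and not to overlap each other or
bury the target. The same seed reproduces the same scene byte-for-byte.

What the phantom does *not* emulate: imaging noise, segmentation error,
anatomical shape statistics, or structures thinner than a voxel. Passing
tests demonstrate the correctness of the geometry and of the planning
logic, not clinical validity on real anatomy.

## Determinism and problem sizes

Every iteration order is fixed; reports are written with sorted keys, no
timestamps, and reproduce byte-identically on identical inputs. The
acceptance script plans the bundled scene at 0.5 mm spacing (~4700
candidate entries per target) and runs the randomised validation suites at
100 geometry instances, 30 analytic scenes and 5 monotonicity phantoms —
sizes chosen so a complete from-scratch run takes a few minutes on a
single core while still exercising every code path.

## Known limitations

- Straight rigid trajectories only; no curved or steerable drilling.
- Axis-aligned voxel grids; oblique CT orientations must be resampled
  upstream.
- The containment test requires watertight meshes (guaranteed for the
  package's own extraction, not for arbitrary imported STL files).
- The risk colour map is relative to the displayed set of trajectories,
  not an absolute risk scale.
- Sub-voxel structures can vanish from voxelised scenes; supply them as
  meshes.
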