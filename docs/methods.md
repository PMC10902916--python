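# Methods

This note records the models, conventions and numerical choices behind
`morphoedit`, the reasoning where the design was genuinely open, and the
limits of what the test suite demonstrates.

## Data model

An SWC record set is assembled into a soma (the type-1 points, input
order preserved) and a forest of neurites.  Sections are maximal node
runs between bifurcations; a bifurcation node is owned by its incoming,
parent-side section and recorded as the *attachment* of each child
section.  This ownership convention makes "first and last node of a
section" unambiguous, which the resampling operations rely on (those two
nodes are never discarded).  One consequence is that the implicit segment
between a bifurcation and a child's first node belongs to no section;
the oversampling and sharp-angle checks therefore do not examine it, and
resampling never touches it.

Multi-root files (forests) are accepted: every non-soma node whose parent
is absent or a soma point starts a neurite.  Soma points belong to no
neurite; selection expansion at section or neurite scope maps a picked
soma point to itself.

The soma bounding sphere is `c = mean(p_i)`, `R = mean(|p_i − c| + r_i)`.
No single formula is standard for SWC somas (1-point, 3-point and contour
descriptions all occur); this one reduces to the node itself for 1-point
somas, is exact for symmetric 3-point descriptions, and is robust to
contour noise because it averages rather than maximizes.

## Detection catalog

Eight pure checks; thresholds live in `ValidationConfig` (all in
micrometers or degrees):

* `position_tolerance` (1e-6 um) — "same position" for repeated nodes.
  Chosen at the writer's serialization precision so coincidence survives
  text round trips; grouping is connected components of the
  within-tolerance graph (k-d tree accelerated, equal to the quadratic
  scan by construction and by test).
* oversampling threshold — per-segment `r_i + r_j` by default (an
  adaptive criterion: two points closer than the sum of their radii add
  no membrane detail), or a fixed value.  Segments at or below
  `position_tolerance` are classified as repeated nodes instead; keeping
  each defect in exactly one catalog entry makes repairs composable and
  ground-truth labels exact.
* `soma_distance_factor` (4) — flags neurite roots farther than 4 soma
  radii from the soma center.
* `sharp_angle_threshold` (90°) — interior angle at a section-interior
  node; a straight trajectory measures 180°, so smaller is sharper.
  Bifurcation nodes and section-first nodes are not tested (no
  within-section neighbor pair exists there).
* `constant_radius_tolerance` (0) — a neurite is "constant" when
  max − min radius is within the tolerance; a single-node neurite is
  vacuously constant and is flagged.

All comparisons are strict: a value exactly at a threshold passes.  The
prose rules these thresholds come from are "below"/"exceeds"-style; a
fixed convention was needed for testability and strictness makes the
boundary cases (distance exactly `r_i + r_j`, angle exactly 90°) pass.

Branch interpenetration has no closed-form membrane test without the
mesh; the implemented surrogate flags sibling sections whose first-node
bounding spheres overlap.  It is deterministic and conservative but can
miss collisions that occur further along the branches — a known
limitation.

## Repair

Actions are per-finding and topology-preserving: removal re-parents the
node's children, so the neurite count never changes.  Conventions chosen
where several repairs were plausible:

* Duplicate groups keep the bifurcation member if present, else the
  smallest id; the survivors' geometry is untouched.
* "Midpoint" moves place the offender at the midpoint of its parent and
  first child; a leaf offender falls back to removal.
* Projection onto the soma surface uses `p' = c + R·(p − c)/|p − c|`;
  for the degenerate `p = c` the direction falls back to the node's first
  child, then +x.
* A node that is its section's sole node, and bifurcations with a
  removable partner, are never removed.

`auto_repair` iterates detect → apply, re-detecting after every mutation
because a repair can invalidate other findings.  Midpoint moves can
create new short segments, so iteration runs to a fixed point under a
hard limit (default 10 outer passes, with a per-check budget); hitting
the limit returns the partial result plus an explicit warning entry in
the log.  The default plan removes duplicates and oversampled nodes,
projects inside-soma nodes, moves distant roots to the soma surface and
re-centers sharp-angle outliers; the three judgement-call checks stay
report-only.

## Resampling

The simplifiers follow the standard polyline-simplification definitions;
where the literature admits variants, the conventions are: perpendicular
distance compares each point to the line through its original-sequence
neighbors and keeps the follower of a dropped point; Reumann–Witkam
advances the key to the first point leaving the chord-line corridor;
Opheim combines a minimum-tolerance ray corridor with a maximum radial
leash (`min_tol`, `max_tol`); Lang shrinks a look-ahead window (default
7) until all interior points are within tolerance of the window chord;
Douglas–Peucker uses point-to-chord-segment distance with strict `> tol`
retention, and the N variant adds globally farthest points (ties to the
smallest index) until exactly `count` remain.  All methods return index
subsequences containing 0 and the last index; kept nodes are returned by
identity, never copied or altered.

Refinement inserts `max(0, ceil(L·d) − 1)` points per segment at equal
parameter spacing — the smallest count that brings every inter-point gap
to at most `1/d`.  Cubic mode uses a Hermite spline with Catmull–Rom
tangents `(p_{i+1} − p_{i−1})/2` (one-sided at section ends): the
standard parameter-free tangent choice, which degenerates exactly to the
chord on equally spaced collinear input.  Radii are interpolated
linearly in both modes; radius smoothing is a separate concern from
trajectory smoothing and is deliberately not coupled to it.  A safety
cap (1e4 insertions per segment) guards against pathological densities.

## Meshing

The membrane approximation is deliberately simple: an icosphere
(trimesh's primitive, default 2 subdivisions) at the soma sphere, plus
one generalized cylinder per section with a vertex ring per node
(default 16 sides) oriented by parallel-transport frames (initial normal
from the smallest-component-axis rule, rotation-minimizing transport
thereafter, re-orthogonalized each step).  Child tubes start with an
extra ring at their attachment node so branch joins overlap rather than
gape; no blending surface is attempted, so the union is not watertight
at branches (individual tubes are, with outward winding — verified by
signed volume).  This preserves the contract that matters for editing —
any tracing change maps deterministically to a mesh change — while
staying far short of adaptive membrane reconstruction, which is out of
scope.

## Synthetic data

The generator grows `n_neurites` (default 3) binary trees to `depth`
bifurcation levels (default 3), 4–8 nodes per section, 3–6 um segments,
root radius 0.8 um tapering by 0.97 per node, around a three-point soma
whose derived sphere radius is 5 um — magnitudes typical of dendritic
arbors at micrometer scale.  Construction guarantees catalog-cleanliness:
direction jitter is capped at 20° (interior angles ≥ 160°), sibling
branch directions separate by 60–90°, every step strictly increases
distance from the soma center (no node can re-enter the soma), spacing
exceeds radius sums, and strict taper rules out constant radii and
radius-order violations.  Infeasible parameter sets (taper driving radii
below 1e-6 um) are rejected up front.

The injector plants requested error counts by local mutations (moving a
terminal onto its parent, squeezing a terminal segment, sinking a root
into the soma, pushing a root past 4R along its reversed first segment,
folding a penultimate node past its terminal, inflating a child radius,
flattening a neurite's radii, translating a child subtree onto its
sibling).  Sites are mutually reserved so mutations are disjoint, and
each candidate is verified by re-running the catalog and rejecting any
site whose mutation would trigger an unplanned finding; the recorded
ground truth is the mutation itself.  Detector correctness is evidenced
independently by equality with naive exhaustive-scan oracles that share
no code with the detectors.

What the generator does **not** emulate: realistic morphometric
distributions (branch-order statistics, pathlength distributions,
tortuosity, type-specific taper), somatic contours, or spatially
correlated acquisition noise.  Passing tests therefore demonstrate
algorithmic correctness on well-formed and deliberately corrupted trees,
not recall on the full variety of real repository tracings.

## Problem sizes

Default test and acceptance runs use ~250–300-node morphologies over 20
seeds, 200 random polylines of up to 50 points for the simplification
oracles, and a single ~21,000-node morphology (5 neurites, depth 8) for
the catalog-runtime measurement — sizes chosen to mirror the scale of
curated single-neuron reconstructions while keeping the whole suite
interactive.

## Known limitations

* The writer renumbers nodes; files relying on original SWC ids for
  cross-referencing must keep their own mapping.
* The collision surrogate examines only the first nodes of sibling
  sections.
* Repair convergence is guaranteed only by the iteration limit;
  pathological configurations (mutually oversampled bifurcation pairs
  protected from removal) end with an explicit warning, not a fix.
* Meshes are unions of per-part closed surfaces, not a single watertight
  manifold.
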