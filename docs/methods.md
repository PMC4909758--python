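# Methods

## Problem

Probabilistic tractography of the basal ganglia produces hundreds of
thousands of streamlines ("tracks"): polylines in world-millimetre space
that proxy white-matter fibre paths. Given such a tractogram and a manual
segmentation of the subthalamic nucleus (STN), substantia nigra pars
compacta/reticulata (SNc, SNr) and external/internal globus pallidus
(GPe, GPi), `bgconnect` quantifies the connectivity pattern of these
nuclei in three complementary ways:

1. **Seed-target tables** — for each nucleus, the percentage of its tracks
   that also intersect each other structure or named fibre path.
2. **Direct-connection matrices** — tracks cut into segments that join two
   of the five nuclei without passing through a third, counted per
   unordered pair and column-normalised.
3. **Voxel projection maps** — for every voxel of a nucleus, the percentage
   of traversing tracks that reach a given target, localising where within
   the nucleus a projection originates.

## Counting model

### Visits

A track *visits* a structure iff at least one vertex maps into one of the
structure's voxels. Vertex membership uses the voxel-centre convention of
the NIfTI affine: index = round(inverse-affine · point), ties rounding half
away from zero. Vertex-based membership is exact when the tracking step is
well below the voxel size (0.05 mm steps against 0.5 mm voxels in the
intended regime); for coarser inputs `densify` interpolates vertices to a
requested spacing first. A corner-cutting diagonal crossing that places no
vertex inside a voxel is *not* a visit — a deliberate, documented property
of the vertex rule. A single-vertex touch counts as a visit by default; a
minimum dwell is available via `min_visit_vertices` but there is no
evidence a dwell criterion is appropriate, so the default is 1.

Each track is reduced to its run-length-compressed **label sequence**:
maximal runs of consecutive vertices inside one structure, background
omitted. All counting operates on this intermediate.

### Selection

Only tracks intersecting a seed structure — STN, SN (= SNc ∪ SNr) or GP
(= GPe ∪ GPi) — enter the analysis. Composite names always resolve to the
union of their member labels.

### Direct segments

A **direct connection** joins two of the five core nuclei without passing
through a third. Operationally: filter the label sequence to core labels
(auxiliary ROIs such as the internal capsule are transparent — they lie
between genuinely connected nuclei and must not break directness), then
emit one segment per consecutive pair of visits to *different* nuclei.
Consequences of this rule, all tested exhaustively:

* a path A→B→C yields (A,B) and (B,C), never (A,C);
* exit-and-re-entry into the same nucleus yields nothing (no diagonal);
* a track oscillating A→B→A yields two segments (each counted; a
  `dedupe_per_track` switch collapses repeats, default off, since the
  original analysis counted *segments*).

Segments are unordered pairs — tractography cannot infer direction — so
counts are symmetric. The percentage matrix divides each column by its
column total (each nucleus's share of direct connections), which makes the
percentage matrix asymmetric although counts are not; every nonzero column
sums to 100 by construction. Zero columns are left at zero and logged, not
NaN-filled.

To mirror the original compute-budget choice, the direct analysis can run
on a seeded random subsample (default in the pipeline: full population;
the historical value is 9000 tracks).

### Seed-target tables

A track *connects* seed s to target t iff it intersects both — endpoints
are not privileged and pass-throughs count, so the table mixes direct and
indirect connections by design. Each track counts once per (s, t) pair
even if it leaves s at two different borders, and once toward the seed
total; a track touching many targets therefore pushes a seed's column sum
past 100%. Composites use union semantics (touching SNc and SNr counts
once toward SN). Cells where target and seed label sets overlap are
blank (a structure is not its own projection site). A target row is
reported iff its percentage reaches the inclusion threshold (default 1%)
for at least one seed.

### Voxel maps

For every voxel of a chosen structure: denominator = tracks with ≥ 1
vertex in that voxel, numerator = those also intersecting the target,
value = 100·num/den. A track traversing a voxel twice counts once in both
terms. Untraversed voxels hold NaN — never 0 — so downstream statistics
are not biased. The denominator uses seed-selected tracks (configurable),
matching the population the rest of the analysis sees.

### Splitting

Anteromedial/posterolateral halves of a nucleus are produced by a plane
through the voxel-centroid, normal to the first principal axis of the
voxel-centre cloud (the direction of longest extent; axis-aligned plane
rules are available). The normal is oriented toward anterior (+y in RAS),
falling back to medial (−x) then superior (+z); centroid-plane ties go to
the anterior half. The split structure's name becomes a composite of its
halves, so it keeps union semantics everywhere, including as a core
nucleus in the direct analysis.

## Synthetic phantoms

The specimen behind the original analysis was never deposited, so
correctness is established on phantoms with *stated* connectivity:

* **Structures** are analytic ellipsoids/boxes rasterized onto a 0.5 mm
  isotropic grid (voxel centre inside geometry, boundary inclusive);
  overlapping geometries are a hard error.
* **Bundles** declare an ordered visit path and a route archetype:
  `straight` corridors, `arc-around-obstacle` (circular arcs that detour —
  anterior first — around a capsule-like obstacle, clearing every
  non-endpoint structure dilated by the half-voxel rasterization margin),
  and `through-obstacle` (straight crossings). These mirror the observed
  connection classes: arcs like the ansa lenticularis around the internal
  capsule, and straight trans-capsular crossings.
* **Jitter** is a per-streamline lateral offset (Gaussian, clipped at 2σ).
  Every generated streamline is verified against its declared visit path on
  the rasterized grid; violating offsets are re-drawn, and the unjittered
  base path is the final fallback. Generation fails loudly (e.g. an arc
  route with no free corridor) rather than silently changing connectivity.
* **Ground truth** is closed-form from the bundle declarations: core-
  filtered consecutive pairs give direct counts; the set of structures on
  the path (plus the obstacle for through-routes) gives seed-target
  counts with the counted-once rule. Pipeline output is compared by exact
  integer equality.

The **paper-like preset** reproduces the stated world: 0.5 mm voxels,
0.05 mm vertex spacing, five ellipsoidal nuclei whose analytic volumes
match the segmented specimen (STN 100.5, SNc 138.8, SNr 142.6, GPe 611.9,
GPi 271.8 mm³; rasterized ratios agree within a few percent), a capsule
slab separating GP from STN/SN, and one bundle per observed connection
class including a pass-through path (STN→SNc→SNr) and a double-exit path
(GPe→STN→SNr). Default jitter is 0.3 mm — comfortably inside the smallest
semi-axis (2 mm) so corridors stay intact. Bundle weights are a coarse
echo of the published relative magnitudes, not a fit to them.

What a green phantom test does **not** establish: phantoms have no
crossing-fibre ambiguity, no false-positive/false-negative tracking noise,
no partial-volume boundary effects, and bundles are geometrically clean.
Green means the *counting semantics* are correct, not that tractography
itself is validated.

## Numerical choices

* World space is RAS millimetres for both TCK and NIfTI; no implicit
  flips (TRK, which differs, is unsupported).
* TCK payloads: Float32LE/BE read, Float32LE written; round-trips are
  exact at 32-bit precision.
* Rounding ties (.5) in voxel lookup round half away from zero.
* Subsampling uses `numpy.random.default_rng` with an explicit seed;
  results are returned sorted so runs are reproducible bit-for-bit.
* Percent-column sums are exact up to float64 arithmetic (tests use an
  absolute tolerance of 1e-9).
* Randomized phantom specs vary voxel-grid alignment through a common
  rigid translation of the whole scene (±1.2 mm) plus ±0.1 mm
  per-structure jitter — within the tightest inter-structure gap, so
  structures remain disjoint by construction.

## Known limitations

* Vertex-based intersection undercounts for step sizes approaching the
  voxel size unless `densify` is applied.
* Named fibre paths (ansa lenticularis, sublenticular internal capsule,
  descriptive regions) are supported only as user-supplied ROI labels;
  no automatic bundle identification.
* No endpoint-restricted ("termination") connectivity mode.
* The anteromedial/posterolateral split plane is a geometric convention;
  the original work gives no construction for it.
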