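# Methods

`bunch3d` extracts grape bunch architecture traits from dense 3D point
clouds of whole bunches. This note documents the model behind each stage,
the parameters that matter, what the synthetic data generator does and does
not emulate, and the numerical choices made where the design was open.

## Problem and model

A ripe grape bunch is, to a good approximation, a set of near-spherical
berries (radius roughly 4.5–8.5 mm for wine grapes at maturity) attached by
short pedicels to a branched rachis. A handheld structured-light scanner
produces a surface point cloud of the visible berry surfaces plus rachis
fragments and, for lab scans, the mounting hook. The task is to recover the
individual berries and from them seven whole-bunch phenotypes:

1. berry number,
2. mean berry diameter (mm),
3. mean single-berry volume (mL),
4. total berry volume (mL),
5. convex hull volume of all berry-surface points (mL),
6. bunch width — maximal extent along x or z (mm),
7. bunch length — maximal vertical (y) extent (mm).

Coordinates are millimetres; a hanging bunch's vertical axis is y; volumes
use 1 mL = 1000 mm³.

## Pipeline

**Reduction.** The raw cloud (sub-0.1 mm mesh resolution) is voxel-grid
downsampled to a 0.4 mm working resolution: one centroid per occupied cubic
voxel, with bins `floor(coord/0.4)` anchored at the origin. Centroid
representatives are deterministic and order-independent; the operation is
idempotent. Berry-scale geometry is unaffected at 0.4 mm while RANSAC cost
drops by more than an order of magnitude.

**Normals and curvature.** Per-point PCA over the 30 nearest neighbors:
the normal is the smallest covariance eigenvector, curvature is
λ₀/(λ₀+λ₁+λ₂) ∈ [0, 1/3]. Normals are oriented away from the local
neighborhood centroid, which points outward on convex berry surfaces; no
sensor viewpoint is available in a PLY file, so a viewpoint-based
orientation is not an option. Sign for exactly planar patches is resolved
deterministically from the dominant normal component.

**Region growing.** Seeds are processed in ascending (curvature, index)
order. A breadth of growth crosses a k-NN edge (k = 30) when the angle
between the two normals is ≤ 15° (sign-insensitive); points with curvature
above 0.05 may join a region but do not recruit further, so growth stops at
the high-curvature creases where berries touch. Regions smaller than 50
points are returned as unassigned — stem fragments and specks, which the
sphere gates of the next stage would reject anyway. The partition is
deterministic and covers every point exactly once. The defaults were chosen
so that a noiseless sphere forms one region while touching spheres separate
or, at worst, merge (undersegmentation is tolerated by design — see next
stage).

**Berry detection.** Within each region, RANSAC fits sphere models: up to
1000 minimal 4-point samples, each solved by the 4×4 algebraic sphere
system (scaled determinant below 1e-9 flags coplanar samples as
degenerate). Hypotheses with radius outside [1, 9] mm are discarded;
remaining hypotheses are scored by inliers within 0.4 mm of the surface —
one working voxel of jitter. The winner is refined once by the linearized
algebraic least-squares sphere on its consensus set, inliers are recounted
once, and the refined model is accepted only if the radius stays in gate
and support is ≥ 100 points. Accepted inliers are removed from the region
and the search repeats until fewer than 100 points remain or no model is
found — this resolves undersegmentation. The refinement is a single pass
(no iterated reweighting) to keep results exactly reproducible.

**Overlap suppression.** Oversegmentation produces duplicate detections of
one berry from different regions. The overlap of two spheres is the
closed-form spherical-lens intersection volume

V(d; r₁, r₂) = π (r₁+r₂−d)² (d² + 2d(r₁+r₂) − 3(r₁−r₂)²) / (12 d)

normalized by the smaller sphere's volume, so a small duplicate buried in a
true berry registers a high overlap quickly. Models are visited by
descending inlier count (ties: larger radius, then lexicographic center)
and accepted only if they overlap every already accepted model by ≤ 25%.
Greedy suppression by support is the standard non-maximum-suppression
reading of "keep the one with the most inliers" and is well defined for
overlap chains.

**Traits.** Width and length are measured over berry *extents*
(center ± radius), not raw point extrema, so hook and stem points cannot
inflate them; length is the vertical distance spanned by the two extreme
berries, matching the convention of measuring bunch length between first
and last berry. The convex hull is taken over the union of all accepted
models' inlier points. Spurious spheres near the hook are deliberately not
removed manually; their effect is quantified on synthetic hook fixtures
instead (at most two spurious detections per bunch in the shipped test).

## Key parameters

| parameter | default | unit | role |
|---|---|---|---|
| resolution | 0.4 | mm | working voxel edge after reduction |
| k_neighbors | 30 | – | normal estimation and growth graph |
| angle_threshold | 15 | deg | smoothness gate for growth |
| curvature_threshold | 0.05 | – | recruiting gate (creases stop growth) |
| min_region_size | 50 | pts | below this a region is unassigned |
| min_radius / max_radius | 1 / 9 | mm | berry radius gates |
| min_supporters | 100 | pts | minimal inlier count per berry |
| inlier_distance | 0.4 | mm | RANSAC surface band (one voxel) |
| ransac_iterations | 1000 | – | hypotheses per region pass |
| overlap_threshold | 0.25 | – | suppression bar |

The radius gates, supporter count, working resolution and overlap bar are
the operating point of the original tool this package reimplements; the
segmentation thresholds, inlier band and iteration count are this package's
own choices, set once as documented above.

## Synthetic data generator

The generator produces ground-truthed stand-ins for scanner data; every
fixture in the test suite is generated at run time from a seed.

**Geometry.** Berry radii are drawn uniformly from 4.6–8.45 mm (the
diameter range of ripe berries in phenotypically diverse material,
9.2–16.9 mm) unless a truncated normal is requested. Centers start on a
golden-angle spiral around a vertical rachis — shell radius sized so the
lateral surface holds `n` berries at the requested packing, height ≈ 2.7 ×
shell radius, which reproduces realistic bunch aspect (a 100-berry bunch
comes out near 110 mm wide and 150 mm long) — then jittered and relaxed by
pairwise push-apart. The packing parameter `compactness` ∈ (0, 1] sets the
minimum center separation to (rᵢ+rⱼ)/compactness: 1 means berries may
touch, smaller is looser; berries never interpenetrate. Relaxation keeps
centers within the attachment region (heights on the rachis, bounded
lateral reach) and fails loudly after 500 sweeps if the requested packing
is infeasible, rather than silently loosening it. Berry surfaces are
sampled area-uniformly (points_per_berry, default 1000 ≈ the density of a
0.4 mm mesh on a 6.5 mm berry); optional rachis/pedicel cylinders
(1–1.5 mm radius) and a 2.5 mm hook cylinder are sampled at matching
surface density. Isotropic Gaussian noise (default σ = 0.1 mm,
sub-millimetre sensor-class accuracy) is added last.

**Partial scans.** `scan_mode="partial"` emulates a single-side scan with
a close-range structured-light sensor placed 250 mm in front of the bunch
centroid (handheld scanners of this class operate at a few hundred mm). A
point is kept only if its outward normal faces the camera within an
incidence limit (cos > 0.3, ≈ 72°; grazing surfaces return no usable
signal), and the segments to the camera and to *both* extreme projector
positions (±20° baseline) are unobstructed by other berries. Requiring
clearance of camera and both projector extremes is a deliberately
conservative triangulation model; it is what renders rear-side berries
almost entirely invisible (their collective leakage is below 10% of their
full-scan points), which in turn reproduces the empirical signature of
single-side scans — roughly half the berry count of a 360° scan at
unchanged mean berry diameter. A brute-force per-point visibility oracle in
the test suite verifies the vectorized implementation exactly.

**What the generator does not emulate.** Berries are perfect spheres (no
oblate table-grape shapes), there are no interior berries hidden inside the
bunch in full-scan mode (a real 360° scan cannot see them either, but here
they are absent rather than invisible), no color or texture, no scan
registration artifacts, no wind-induced tracking loss, and the skeleton is
a straight rachis with straight pedicels rather than a branched one.
Passing tests therefore demonstrate correctness of the geometry processing
under realistic densities, noise and occlusion — not robustness to every
artifact of field data.

## Compactness factors

Bunch compactness is visually scored on five ordinal classes (1 = very
loose … 9 = very dense, OIV descriptor 204). Quantitative candidate
factors are arithmetic expressions over the seven traits, kept in a
configurable registry because no single published formula set is canonical.
The shipped defaults — B = total_volume/(length·width),
C = total_volume/length, D = total_volume/convex_hull_volume,
E = convex_hull_volume/(length·width) — are labelled interpretations, not
authoritative definitions, and can be replaced by a plain-text config.
Factor values are rank-correlated with the ordinal classes by Spearman's ρ
with average-rank tie handling (ties are pervasive with five class levels);
a constant input raises an error rather than returning NaN.

## Numerical choices and degenerate inputs

- Sphere solvers flag coplanar/cocircular samples by a scaled determinant
  (minimal fit) or rank deficiency (least squares) and return a degenerate
  marker, never an exception.
- The algebraic least-squares sphere is used for refinement because it is
  direct and deterministic; on hemispheres (partial scans) it remains full
  rank. The geometric (nonlinear) fit serves as an independent oracle in
  tests, never in the pipeline.
- All randomness flows through explicit seeded generators; batch runs
  derive one RNG per scan from (master seed, CRC32 of scan name), so
  results are independent of folder contents and processing order.
- Empty inputs degrade gracefully: an empty cloud downsamples to an empty
  cloud, an empty model list yields all-zero traits, a hull over fewer than
  four non-coplanar points is reported as 0 mL with a warning.
- Export rounds to 4 decimals at write time only; in-memory values are full
  precision, and re-exports are byte-identical.

## Problem sizes in the shipped tests

The validation suite exercises bunches of 20–300 berries at 1000 points per
berry (clouds up to ≈ 500 k points), 20 matched full/partial scan pairs of
40-berry compact bunches, 100 random sphere pairs against 10⁷-sample Monte
Carlo integration, and 1000 random vectors against a brute-force rank
oracle. These sizes cover the berry-count range of real bunches while each
stage's cost stays linear in points per region.

## Known limitations

- Strongly ellipsoidal berries (some table grapes) violate the sphere
  model; radius estimates then approximate the mean semi-axis.
- Berries hidden inside very compact bunches are not externally visible and
  cannot be counted by any surface method; detected counts undercount such
  bunches.
- The convex hull mixes berry volume with inter-berry space; it is reported
  because it is part of the standard trait set, but it is a coarse proxy
  for bunch volume, and factors built on it rank compactness worse than
  volume-per-extent factors.
- Width from a single partial scan depends on the scanned side; the
  generator reproduces this (partial widths are biased low), and users
  averaging traits over sides should scan both.
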