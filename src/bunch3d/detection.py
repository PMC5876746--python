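"""RANSAC sphere detection inside segmented regions.

A berry is modelled as a sphere.  Within each region, 4-point minimal
samples propose sphere hypotheses; the hypothesis with most inliers (points
within ``inlier_distance`` of the surface) is refined by an algebraic
least-squares fit on its consensus set.  A model is accepted only if its
radius lies within the berry radius gates and it keeps at least
``min_supporters`` inliers.  Accepted inliers are removed from the region
and the search repeats, so one region can yield several berries
(undersegmentation).  Duplicated detections of the same berry from split
regions (oversegmentation) are suppressed afterwards: among models whose
spheres overlap by more than ``overlap_threshold`` only the one with the
most inliers survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SphereModel", "DetectionParams",
    "fit_sphere_minimal", "fit_sphere_least_squares",
    "ransac_sphere", "detect_berries_in_region",
    "sphere_overlap_fraction", "resolve_overlaps",
    "detect_berries", "export_spheres_ply",
]


@dataclass(frozen=True)
class SphereModel:
    """A detected berry: center (mm), radius (mm) and its supporting points."""

    center: np.ndarray
    radius: float
    inlier_indices: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=np.float64).reshape(3))
        object.__setattr__(self, "inlier_indices",
                           np.asarray(self.inlier_indices, dtype=np.int64).ravel())

    @property
    def n_inliers(self) -> int:
        return len(self.inlier_indices)

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius ** 3


@dataclass(frozen=True)
class DetectionParams:
    """Gates and search parameters for sphere detection.

    Radius gates default to the 1–9 mm berry radius range; an accepted model
    needs at least ``min_supporters`` (default 100) inliers within
    ``inlier_distance`` (default 0.4 mm, one working voxel of surface
    jitter) of its surface.  Sphere pairs overlapping by more than
    ``overlap_threshold`` (default 0.25 of the smaller sphere's volume)
    collapse to the better supported one.
    """

    min_radius: float = 1.0
    max_radius: float = 9.0
    min_supporters: int = 100
    inlier_distance: float = 0.4
    ransac_iterations: int = 1000
    overlap_threshold: float = 0.25
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_radius < self.max_radius:
            raise ValueError("need 0 < min_radius < max_radius")
        if self.min_supporters < 4:
            raise ValueError("min_supporters must be >= 4")
        if not 0 < self.overlap_threshold < 1:
            raise ValueError("overlap_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# Sphere solvers

def _solve_algebraic(points: np.ndarray):
    """Least-squares solution of |p|^2 = 2 p.c + (r^2 - |c|^2)."""
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = np.einsum("ij,ij->i", points, points)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        return None
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        return None
    return center, float(np.sqrt(r2))


def fit_sphere_minimal(p1, p2, p3, p4):
    """Exact sphere through four points, or ``None`` when (near-)coplanar.

    Solves the 4x4 linear system of the algebraic sphere equation; a scaled
    determinant below 1e-9 flags degeneracy (coplanar or cocircular points).
    """
    pts = np.asarray([p1, p2, p3, p4], dtype=np.float64)
    A = np.column_stack([2.0 * pts, np.ones(4)])
    scale = np.abs(A[:, :3]).max() or 1.0
    if np.abs(np.linalg.det(A / scale)) < 1e-9:
        return None
    b = np.einsum("ij,ij->i", pts, pts)
    sol = np.linalg.solve(A, b)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        return None
    return center, float(np.sqrt(r2))


def fit_sphere_least_squares(points):
    """Algebraic least-squares sphere through >= 4 non-coplanar points.

    Minimizes sum(|p|^2 - 2 p.c - (r^2 - |c|^2))^2, the linearized sphere
    fit; returns ``None`` on a rank-deficient (coplanar) system.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(points) < 4:
        return None
    return _solve_algebraic(points)


# ---------------------------------------------------------------------------
# RANSAC

def _count_inliers(points, center, radius, tol):
    dist = np.abs(np.linalg.norm(points - center, axis=1) - radius)
    return dist <= tol


def ransac_sphere(points, params: DetectionParams, rng: np.random.Generator) -> SphereModel | None:
    """Best RANSAC sphere in ``points``, or ``None`` if no model passes the gates.

    Up to ``ransac_iterations`` minimal 4-point samples are drawn; degenerate
    and out-of-radius hypotheses are skipped, the rest are scored by inlier
    count.  The winner is refined once by :func:`fit_sphere_least_squares`
    on its inliers and its inliers recounted; the refined model is returned
    iff the radius stays within the gates and support stays >=
    ``min_supporters``.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    n = len(points)
    if n < max(4, params.min_supporters):
        return None
    iters = params.ransac_iterations
    samples = rng.integers(0, n, size=(iters, 4))
    # reject samples with repeated points
    ok = (samples[:, :, None] != samples[:, None, :]).sum(axis=(1, 2)) == 12
    samples = samples[ok]
    pts = points[samples]                                     # (m, 4, 3)
    A = np.concatenate([2.0 * pts, np.ones((len(pts), 4, 1))], axis=2)
    scale = np.abs(pts).max() or 1.0
    dets = np.linalg.det(A / scale)
    nondeg = np.abs(dets) > 1e-9
    if not nondeg.any():
        return None
    A = A[nondeg]
    pts = pts[nondeg]
    b = np.einsum("mij,mij->mi", pts, pts)
    sol = np.linalg.solve(A, b[..., None])[..., 0]            # (m, 4)
    centers = sol[:, :3]
    r2 = sol[:, 3] + np.einsum("mi,mi->m", centers, centers)
    valid = r2 > 0
    centers, r2 = centers[valid], r2[valid]
    radii = np.sqrt(r2)
    in_range = (radii >= params.min_radius) & (radii <= params.max_radius)
    centers, radii = centers[in_range], radii[in_range]
    if len(centers) == 0:
        return None

    best_count, best_idx = -1, -1
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, len(centers), chunk):
        c = centers[start:start + chunk]
        r = radii[start:start + chunk]
        d = np.linalg.norm(points[None, :, :] - c[:, None, :], axis=2)
        counts = (np.abs(d - r[:, None]) <= params.inlier_distance).sum(axis=1)
        i = int(np.argmax(counts))
        if counts[i] > best_count:
            best_count, best_idx = int(counts[i]), start + i
    if best_count < params.min_supporters:
        return None

    mask = _count_inliers(points, centers[best_idx], radii[best_idx], params.inlier_distance)
    refined = fit_sphere_least_squares(points[mask])
    if refined is None:
        center, radius = centers[best_idx], float(radii[best_idx])
    else:
        center, radius = refined
    if not params.min_radius <= radius <= params.max_radius:
        return None
    mask = _count_inliers(points, center, radius, params.inlier_distance)
    if mask.sum() < params.min_supporters:
        return None
    return SphereModel(center=center, radius=radius, inlier_indices=np.flatnonzero(mask))


def detect_berries_in_region(points, params: DetectionParams,
                             rng: np.random.Generator) -> list[SphereModel]:
    """Iterative RANSAC with inlier removal inside one region.

    Accepted models' inliers are extracted from the region and the search
    repeats on the remainder until fewer than ``min_supporters`` points are
    left or no further model is found.  Inlier indices refer to the region's
    point array and are pairwise disjoint across the returned models.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    remaining = np.arange(len(points))
    models: list[SphereModel] = []
    while len(remaining) >= params.min_supporters:
        model = ransac_sphere(points[remaining], params, rng)
        if model is None:
            break
        global_inliers = remaining[model.inlier_indices]
        models.append(SphereModel(center=model.center, radius=model.radius,
                                  inlier_indices=global_inliers))
        keep = np.ones(len(remaining), dtype=bool)
        keep[model.inlier_indices] = False
        remaining = remaining[keep]
    return models


# ---------------------------------------------------------------------------
# Overlap suppression

def sphere_overlap_fraction(s1: SphereModel, s2: SphereModel) -> float:
    """Overlap of two spheres as lens volume / volume of the smaller sphere.

    0 when the spheres are disjoint or tangent, 1 when one contains the
    other; in between, the closed-form sphere-sphere intersection (spherical
    lens) volume

        V = pi (r1+r2-d)^2 (d^2 + 2d(r1+r2) - 3(r1-r2)^2) / (12 d)

    normalized by min(V1, V2).
    """
    r1, r2 = float(s1.radius), float(s2.radius)
    if r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive")
    d = float(np.linalg.norm(np.asarray(s1.center, float) - np.asarray(s2.center, float)))
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return 1.0
    lens = (np.pi * (r1 + r2 - d) ** 2
            * (d * d + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2) / (12 * d))
    v_small = 4.0 / 3.0 * np.pi * min(r1, r2) ** 3
    return float(min(1.0, lens / v_small))


def resolve_overlaps(models: list[SphereModel],
                     overlap_threshold: float = 0.25) -> list[SphereModel]:
    """Greedy non-maximum suppression of overlapping sphere models.

    Models are visited by descending inlier count (ties: larger radius, then
    lexicographic center) and accepted only if they overlap every already
    accepted model by at most ``overlap_threshold``; so of two duplicates of
    one berry only the better-supported model is kept.
    """
    def key(m: SphereModel):
        return (-m.n_inliers, -m.radius, m.center[0], m.center[1], m.center[2])

    accepted: list[SphereModel] = []
    for model in sorted(models, key=key):
        if all(sphere_overlap_fraction(model, a) <= overlap_threshold for a in accepted):
            accepted.append(model)
    return accepted


def export_spheres_ply(models: list[SphereModel], path,
                       points_per_sphere: int = 400) -> None:
    """Diagnostic: write detected berries as green sampled sphere surfaces."""
    from .io import PointCloud, write_ply

    rng = np.random.default_rng(0)  # cosmetic sampling only
    parts = []
    for m in models:
        u = rng.normal(size=(points_per_sphere, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        parts.append(m.center + m.radius * u)
    pts = np.vstack(parts) if parts else np.empty((0, 3))
    colors = np.tile(np.array([[0, 200, 0]], dtype=np.uint8), (len(pts), 1))
    write_ply(PointCloud(pts, colors=colors), path)


# ---------------------------------------------------------------------------
# Region-list driver

def detect_berries(cloud_points, regions, params: DetectionParams | None = None,
                   rng: np.random.Generator | None = None) -> list[SphereModel]:
    """Detect berries across a list of regions and suppress duplicates.

    ``regions`` is an iterable of index arrays (or ``Region`` objects) into
    ``cloud_points``; returned models carry inlier indices into the full
    cloud.  A single seeded RNG drives all regions in their given order, so
    results are deterministic for a fixed ``params.random_seed``.
    """
    if params is None:
        params = DetectionParams()
    if rng is None:
        rng = np.random.default_rng(params.random_seed)
    cloud_points = np.asarray(cloud_points, dtype=np.float64).reshape(-1, 3)
    models: list[SphereModel] = []
    for region in regions:
        idx = np.asarray(getattr(region, "indices", region), dtype=np.int64)
        for m in detect_berries_in_region(cloud_points[idx], params, rng):
            models.append(SphereModel(center=m.center, radius=m.radius,
                                      inlier_indices=idx[m.inlier_indices]))
    return resolve_overlaps(models, params.overlap_threshold)
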