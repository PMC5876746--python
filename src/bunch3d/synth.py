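"""Ground-truthed synthetic grape-bunch point clouds.

Berries are spheres arranged on a cylindrical spiral shell around a vertical
(y-axis) rachis, with radii drawn from the diameter range of ripe wine-grape
berries (about 9–17 mm).  A packing parameter controls looseness: the
minimum allowed center separation of two berries is (r_i + r_j) divided by
``compactness``, so 1 means berries may touch and smaller values spread
them out.  Berry surfaces are sampled area-uniformly, optionally with a
rachis/pedicel skeleton and a hanging hook, plus isotropic Gaussian sensor
noise.

Two scan modes emulate the acquisition geometries: ``full`` (a 360° turn
sees every berry surface) and ``partial`` (a single-side scan).  The
partial model places a structured-light sensor at close range in front of
the bunch (handheld scanners of this class work at a few hundred mm) and
keeps a point only if (a) its outward normal faces the camera within an
incidence limit, and (b) the camera ray and projector rays at +/- the
sensor baseline angle all reach it without crossing another berry.
Requiring clearance of camera and both extreme projector positions is a
deliberately conservative triangulation model; it is what makes rear-side
berries almost entirely invisible, reproducing the roughly halved berry
counts of real single-side scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .detection import SphereModel
from .io import PointCloud, write_ply

__all__ = ["SyntheticBunchSpec", "GroundTruth", "MatchReport", "GenerationError",
           "generate_bunch", "match_detections", "write_fixture",
           "STEM_LABEL", "HOOK_LABEL"]

STEM_LABEL = -1
HOOK_LABEL = -2

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class GenerationError(RuntimeError):
    """Infeasible generator parameters (packing could not be relaxed)."""


@dataclass(frozen=True)
class SyntheticBunchSpec:
    """Generative parameters of one synthetic bunch.

    ``radius_range`` draws berry radii uniformly (mm); set ``radius_mean_sd``
    instead for a truncated normal.  ``rachis_length`` of ``None`` sizes the
    bunch automatically from the berry count, mean radius and compactness so
    the shell has room for every berry at the requested packing.
    """

    n_berries: int = 100
    radius_range: tuple[float, float] = (4.6, 8.45)
    radius_mean_sd: tuple[float, float] | None = None
    rachis_length: float | None = None
    compactness: float = 0.9
    points_per_berry: int = 1000
    noise_sigma: float = 0.1
    include_stem: bool = True
    include_hook: bool = False
    scan_mode: str = "full"
    view_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    sensor_distance: float = 250.0   # mm from bunch centroid, partial mode
    baseline_angle: float = 20.0     # camera-projector separation, degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_berries < 1:
            raise ValueError("n_berries must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 < self.compactness <= 1:
            raise ValueError("compactness must be in (0, 1]")
        if self.scan_mode not in ("full", "partial"):
            raise ValueError("scan_mode must be 'full' or 'partial'")
        lo, hi = self.radius_range
        if not 1.0 <= lo <= hi <= 9.0:
            raise ValueError("radius_range must lie within [1, 9] mm")


@dataclass(frozen=True)
class GroundTruth:
    """True spheres and a per-point provenance label.

    ``labels[i]`` is the berry index of point i, or ``STEM_LABEL`` /
    ``HOOK_LABEL`` for skeleton points; every generated point carries
    exactly one label.
    """

    centers: np.ndarray          # (n_berries, 3) mm
    radii: np.ndarray            # (n_berries,) mm
    labels: np.ndarray           # (n_points,) int

    @property
    def n_berries(self) -> int:
        return len(self.radii)

    @property
    def total_berry_volume_ml(self) -> float:
        return float((4.0 / 3.0 * np.pi * self.radii ** 3).sum() / 1000.0)

    def spheres(self) -> list[tuple[np.ndarray, float]]:
        return [(self.centers[i], float(self.radii[i])) for i in range(self.n_berries)]


# ---------------------------------------------------------------------------
# Generation

def _draw_radii(spec: SyntheticBunchSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.radius_range
    if spec.radius_mean_sd is not None:
        mean, sd = spec.radius_mean_sd
        radii = rng.normal(mean, sd, size=spec.n_berries)
        return np.clip(radii, lo, hi)
    return rng.uniform(lo, hi, size=spec.n_berries)


def _layout(spec: SyntheticBunchSpec, radii: np.ndarray, rng: np.random.Generator):
    """Initial spiral-shell placement plus separation relaxation."""
    n = spec.n_berries
    r_mean = float(radii.mean())
    sep = 2.0 * r_mean / spec.compactness          # target neighbor spacing
    area = 1.15 * n * sep ** 2                     # shell area with slack
    # bunches are longer than wide: shell height about 2.7 x shell radius;
    # an explicit rachis_length only overrides the height
    shell_r = max(r_mean, np.sqrt(area / (2.0 * np.pi * 2.7)))
    length = 2.7 * shell_r if spec.rachis_length is None else float(spec.rachis_length)
    if n == 1:
        return np.zeros((1, 3)), length, shell_r

    t = (np.arange(n) + 0.5) / n
    theta = np.arange(n) * GOLDEN_ANGLE + rng.uniform(0, 2 * np.pi)
    rho = shell_r + rng.normal(0, 0.05 * shell_r, size=n)
    centers = np.column_stack([rho * np.cos(theta), t * length, rho * np.sin(theta)])
    centers += rng.normal(0, 0.1 * r_mean, size=(n, 3))

    # pairwise push-apart until no two berries are closer than
    # (ri+rj)/compactness, keeping centers in the attachment region around
    # the rachis (heights on the rachis, bounded pedicel reach)
    min_sep_max = (2.0 * radii.max()) / spec.compactness
    rho_max = shell_r + 3.0 * r_mean
    for _ in range(500):
        tree = cKDTree(centers)
        pairs = np.array(sorted(tree.query_pairs(min_sep_max)))
        if len(pairs):
            i, j = pairs.T
            delta = centers[j] - centers[i]
            dist = np.linalg.norm(delta, axis=1)
            need = (radii[i] + radii[j]) / spec.compactness
            viol = dist < need - 1e-3
        else:
            viol = np.zeros(0, dtype=bool)
        if not viol.any():
            break
        i, j, delta, dist, need = i[viol], j[viol], delta[viol], dist[viol], need[viol]
        dist[dist < 1e-9] = 1e-9
        push = (need - dist) / 2.0 + 1e-3
        step = delta / dist[:, None] * push[:, None]
        np.add.at(centers, j, step)
        np.add.at(centers, i, -step)
        centers[:, 1] = np.clip(centers[:, 1], 0.0, length)
        rho = np.linalg.norm(centers[:, [0, 2]], axis=1)
        over = rho > rho_max
        if over.any():
            scale = rho_max / rho[over]
            centers[over, 0] *= scale
            centers[over, 2] *= scale
    else:
        raise GenerationError(
            "packing relaxation did not converge; lower compactness, reduce "
            "n_berries or increase rachis_length")
    return centers, length, shell_r


def _sample_cylinder(p0, p1, radius, density, rng):
    """Area-uniform samples of a cylinder lateral surface with outward normals."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length < 1e-9:
        return np.empty((0, 3)), np.empty((0, 3))
    axis = axis / length
    m = max(1, int(round(density * 2 * np.pi * radius * length)))
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    t = rng.uniform(0, length, size=m)
    phi = rng.uniform(0, 2 * np.pi, size=m)
    normals = np.outer(np.cos(phi), u) + np.outer(np.sin(phi), v)
    points = p0 + np.outer(t, axis) + radius * normals
    return points, normals


def generate_bunch(spec: SyntheticBunchSpec) -> tuple[PointCloud, GroundTruth]:
    """Generate one synthetic bunch scan and its ground truth.

    Fully deterministic given ``spec.seed``.  Raises
    :class:`GenerationError` when the requested packing cannot be realised.
    """
    rng = np.random.default_rng(spec.seed)
    radii = _draw_radii(spec, rng)
    centers, length, shell_r = _layout(spec, radii, rng)

    points_parts, normals_parts, labels_parts = [], [], []
    for i in range(spec.n_berries):
        u = rng.normal(size=(spec.points_per_berry, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        points_parts.append(centers[i] + radii[i] * u)
        normals_parts.append(u)
        labels_parts.append(np.full(spec.points_per_berry, i, dtype=np.int64))

    density = spec.points_per_berry / (4.0 * np.pi * radii.mean() ** 2)  # pts / mm^2
    y_top = centers[:, 1].max() + radii.max()
    if spec.include_stem:
        rachis_lo = np.array([0.0, centers[:, 1].min() - radii.mean(), 0.0])
        rachis_hi = np.array([0.0, y_top, 0.0])
        pts, nrm = _sample_cylinder(rachis_lo, rachis_hi, 1.5, density, rng)
        points_parts.append(pts)
        normals_parts.append(nrm)
        labels_parts.append(np.full(len(pts), STEM_LABEL, dtype=np.int64))
        for i in range(spec.n_berries):
            anchor = np.array([0.0, centers[i, 1], 0.0])
            direction = centers[i] - anchor
            dist = np.linalg.norm(direction)
            if dist <= radii[i] + 1e-6:
                continue
            end = anchor + direction / dist * (dist - radii[i])
            pts, nrm = _sample_cylinder(anchor, end, 1.0, density, rng)
            points_parts.append(pts)
            normals_parts.append(nrm)
            labels_parts.append(np.full(len(pts), STEM_LABEL, dtype=np.int64))
    if spec.include_hook:
        hook_lo = np.array([0.0, y_top, 0.0])
        hook_hi = np.array([0.0, y_top + 40.0, 0.0])
        pts, nrm = _sample_cylinder(hook_lo, hook_hi, 2.5, density, rng)
        points_parts.append(pts)
        normals_parts.append(nrm)
        labels_parts.append(np.full(len(pts), HOOK_LABEL, dtype=np.int64))

    points = np.concatenate(points_parts)
    normals = np.concatenate(normals_parts)
    labels = np.concatenate(labels_parts)

    if spec.scan_mode == "partial":
        visible = _partial_visibility(points, normals, labels, centers, radii, spec)
        points, normals, labels = points[visible], normals[visible], labels[visible]

    if spec.noise_sigma > 0:
        points = points + rng.normal(0, spec.noise_sigma, size=points.shape)

    cloud = PointCloud(points, normals=normals)
    truth = GroundTruth(centers=centers, radii=radii, labels=labels)
    return cloud, truth


# structured-light incidence limit: surfaces tilted more than ~72 deg from
# the camera ray return no usable signal
_FACING_COS = 0.3


def _rays_blocked(points, labels, target, centers, radii) -> np.ndarray:
    """True where the segment from a point to ``target`` crosses any berry
    other than the point's own."""
    d = target - points
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    blocked = np.zeros(len(points), dtype=bool)
    for j in range(len(radii)):
        w = centers[j] - points
        b = np.einsum("ij,ij->i", d, w)
        disc = b * b - (np.einsum("ij,ij->i", w, w) - radii[j] ** 2)
        hit = (disc > 0) & (b - np.sqrt(np.maximum(disc, 0)) > 1e-6)
        blocked |= hit & (labels != j)
    return blocked


def _partial_visibility(points, normals, labels, centers, radii, spec) -> np.ndarray:
    """Close-range structured-light visibility: camera-facing within the
    incidence limit and unobstructed toward the camera and both extreme
    projector positions of the baseline."""
    view = np.asarray(spec.view_direction, dtype=np.float64)
    view = view / np.linalg.norm(view)
    centroid = centers.mean(axis=0)
    camera = centroid - view * spec.sensor_distance
    helper = np.array([0.0, 1.0, 0.0]) if abs(view[1]) < 0.9 else np.array([1.0, 0.0, 0.0])
    side = np.cross(-view, helper)
    side /= np.linalg.norm(side)
    offset = spec.sensor_distance * np.tan(np.radians(spec.baseline_angle))

    cam_dirs = camera - points
    cam_dirs /= np.linalg.norm(cam_dirs, axis=1, keepdims=True)
    visible = np.einsum("ij,ij->i", normals, cam_dirs) > _FACING_COS
    idx = np.flatnonzero(visible)
    blocked = _rays_blocked(points[idx], labels[idx], camera, centers, radii)
    for sgn in (+1.0, -1.0):
        blocked |= _rays_blocked(points[idx], labels[idx],
                                 camera + sgn * offset * side, centers, radii)
    visible[idx[blocked]] = False
    return visible


# ---------------------------------------------------------------------------
# Detection-truth matching

@dataclass(frozen=True)
class MatchReport:
    n_truth: int
    n_detected: int
    n_matched: int
    precision: float
    recall: float
    mean_radius_error: float     # mm, over matched pairs
    mean_center_error: float     # mm, over matched pairs
    pairs: list = field(default_factory=list)   # (truth_idx, detection_idx)


def match_detections(truth: GroundTruth, models: list[SphereModel],
                     max_center_distance: float = 2.0) -> MatchReport:
    """Optimal one-to-one truth/detection assignment by center distance.

    Pairs farther apart than ``max_center_distance`` stay unmatched.  The
    report is independent of the ordering of ``models``.
    """
    n_t, n_d = truth.n_berries, len(models)
    if n_t == 0 or n_d == 0:
        return MatchReport(n_t, n_d, 0,
                           0.0 if n_d else 1.0, 0.0 if n_t else 1.0,
                           float("nan"), float("nan"), [])
    det_centers = np.array([m.center for m in models])
    cost = np.linalg.norm(truth.centers[:, None, :] - det_centers[None, :, :], axis=2)
    big = 1e6
    masked = np.where(cost <= max_center_distance, cost, big)
    rows, cols = linear_sum_assignment(masked)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] <= max_center_distance]
    n_m = len(pairs)
    r_err = [abs(models[c].radius - truth.radii[r]) for r, c in pairs]
    c_err = [cost[r, c] for r, c in pairs]
    return MatchReport(
        n_truth=n_t, n_detected=n_d, n_matched=n_m,
        precision=n_m / n_d, recall=n_m / n_t,
        mean_radius_error=float(np.mean(r_err)) if pairs else float("nan"),
        mean_center_error=float(np.mean(c_err)) if pairs else float("nan"),
        pairs=pairs)


# ---------------------------------------------------------------------------
# Fixture export

def write_fixture(spec: SyntheticBunchSpec, out_dir, name: str = "bunch",
                  binary: bool = False) -> tuple[Path, Path, Path]:
    """Write PLY scan, ground-truth CSV (berry id, cx, cy, cz, r) and a JSON
    sidecar with the generating spec; returns the three paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cloud, truth = generate_bunch(spec)
    ply = out_dir / f"{name}.ply"
    write_ply(cloud, ply, binary=binary)
    csv = out_dir / f"{name}_truth.csv"
    with open(csv, "w", encoding="ascii", newline="\n") as fh:
        fh.write("berry_id,cx_mm,cy_mm,cz_mm,radius_mm\n")
        for i in range(truth.n_berries):
            c = truth.centers[i]
            fh.write(f"{i},{c[0]:.6f},{c[1]:.6f},{c[2]:.6f},{truth.radii[i]:.6f}\n")
    meta = out_dir / f"{name}_spec.json"
    meta.write_text(json.dumps(asdict(spec), indent=2) + "\n")
    return ply, csv, meta
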