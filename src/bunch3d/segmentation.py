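"""Region growing over a point cloud with normals and curvature.

Berry candidate patches are smoothly connected regions: growth crosses a
k-NN edge only when the two normals agree to within an angle threshold, and
only low-curvature points recruit further neighbors, so the high-curvature
creases between touching berries stop growth.  Undersegmentation (several
berries in one region) is tolerated here and resolved downstream by
iterative sphere fitting; oversegmentation is resolved by overlap
suppression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import PointCloud

__all__ = ["Region", "SegmentationParams", "SegmentationResult",
           "region_growing", "export_segmentation_ply"]


@dataclass(frozen=True)
class Region:
    """An index set into a point cloud, grown from ``seed_index``."""

    indices: np.ndarray
    seed_index: int

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class SegmentationParams:
    """Region-growing thresholds.

    angle_threshold (deg): maximum angle between the normal of a point and
    that of the neighbor recruiting it.  curvature_threshold: PCA curvature
    above which a point may still join a region but no longer recruits,
    which confines growth at berry-berry creases.  min_region_size: regions
    smaller than this are returned as unassigned points.
    """

    k_neighbors: int = 30
    angle_threshold: float = 15.0
    curvature_threshold: float = 0.05
    min_region_size: int = 50

    def __post_init__(self) -> None:
        if self.k_neighbors < 3:
            raise ValueError("k_neighbors must be >= 3")
        if not 0 < self.angle_threshold < 90:
            raise ValueError("angle_threshold must be in (0, 90) degrees")
        if self.min_region_size < 1:
            raise ValueError("min_region_size must be >= 1")


@dataclass(frozen=True)
class SegmentationResult:
    regions: list[Region]
    unassigned: np.ndarray  # indices in no region of size >= min_region_size


def region_growing(cloud: PointCloud, params: SegmentationParams | None = None) -> SegmentationResult:
    """Partition ``cloud`` into smoothly connected regions.

    Seeds are processed in ascending (curvature, index) order, giving a
    deterministic partition; each BFS wave adds an unassigned k-NN neighbor
    when the angle between its normal and the recruiting point's normal is
    within ``angle_threshold`` (normal sign ignored).  Regions smaller than
    ``min_region_size`` are dissolved into the unassigned set, so region
    sizes plus unassigned count always equals the cloud size.
    """
    if params is None:
        params = SegmentationParams()
    if cloud.normals is None or cloud.curvature is None:
        raise ValueError("region growing requires normals and curvature; run estimate_normals first")
    n = len(cloud)
    if n == 0:
        return SegmentationResult([], np.empty(0, dtype=np.int64))
    k = min(params.k_neighbors, n - 1)
    tree = cKDTree(cloud.points)
    _, knn = tree.query(cloud.points, k=k + 1, workers=-1)
    knn = np.atleast_2d(knn)[:, 1:]                 # drop self

    normals = cloud.normals
    curvature = cloud.curvature
    cos_thr = np.cos(np.radians(params.angle_threshold))
    order = np.lexsort((np.arange(n), curvature))   # curvature asc, index tiebreak

    labels = np.full(n, -1, dtype=np.int64)
    seeds: list[int] = []
    n_labels = 0
    for seed in order:
        if labels[seed] != -1:
            continue
        label = n_labels
        n_labels += 1
        seeds.append(int(seed))
        labels[seed] = label
        frontier = [int(seed)]
        while frontier:
            i = frontier.pop()
            # high-curvature members join but do not recruit (except the seed,
            # which must be allowed to start its own region)
            if curvature[i] > params.curvature_threshold and i != seed:
                continue
            nb = knn[i]
            free = labels[nb] == -1
            if not free.any():
                continue
            cand = nb[free]
            smooth = np.abs(normals[cand] @ normals[i]) >= cos_thr
            joined = cand[smooth]
            if joined.size:
                labels[joined] = label
                frontier.extend(int(j) for j in joined)

    regions: list[Region] = []
    unassigned: list[np.ndarray] = []
    for label, seed in enumerate(seeds):
        members = np.flatnonzero(labels == label)
        if len(members) >= params.min_region_size:
            regions.append(Region(indices=members, seed_index=seed))
        else:
            unassigned.append(members)
    una = np.sort(np.concatenate(unassigned)) if unassigned else np.empty(0, dtype=np.int64)
    return SegmentationResult(regions=regions, unassigned=una)


def export_segmentation_ply(cloud: PointCloud, result: SegmentationResult, path) -> None:
    """Write a diagnostic PLY with one color per region (unassigned in gray)."""
    from .io import write_ply

    rng = np.random.default_rng(0)  # fixed palette, independent of data
    colors = np.full((len(cloud), 3), 128, dtype=np.uint8)
    for region in result.regions:
        colors[region.indices] = rng.integers(32, 255, size=3, dtype=np.uint8)
    write_ply(PointCloud(cloud.points, normals=cloud.normals, colors=colors), path)
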