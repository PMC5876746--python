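"""End-to-end analysis of one bunch scan.

read -> downsample -> normal estimation -> region growing -> per-region
RANSAC sphere detection -> overlap suppression -> trait extraction.
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass

import numpy as np

from .detection import (DetectionParams, SphereModel, detect_berries_in_region,
                        resolve_overlaps)
from .io import PointCloud, downsample, estimate_normals
from .segmentation import SegmentationParams, SegmentationResult, region_growing
from .traits import BunchTraits, compute_traits

__all__ = ["PipelineResult", "analyze_cloud", "scan_rng_seed"]


@dataclass(frozen=True)
class PipelineResult:
    models: list[SphereModel]          # accepted berries (inliers index `working`)
    traits: BunchTraits
    working: PointCloud                # downsampled cloud with normals
    segmentation: SegmentationResult
    n_points_in: int
    n_candidates: int                  # models before overlap suppression
    runtime_s: float


def scan_rng_seed(master_seed: int, scan_id: str) -> int:
    """Per-scan RNG seed derived from the master seed and the scan name,
    so batch order and folder contents do not affect a scan's result."""
    return (int(master_seed) ^ zlib.crc32(scan_id.encode("utf-8"))) % (2 ** 31)


def analyze_cloud(cloud: PointCloud,
                  resolution: float = 0.4,
                  seg_params: SegmentationParams | None = None,
                  det_params: DetectionParams | None = None,
                  rng: np.random.Generator | None = None) -> PipelineResult:
    """Run the full berry-detection workflow on one point cloud.

    Deterministic for fixed parameters and RNG seed.  ``resolution`` is the
    working voxel edge (mm) of the pre-processing reduction.
    """
    t0 = time.perf_counter()
    if seg_params is None:
        seg_params = SegmentationParams()
    if det_params is None:
        det_params = DetectionParams()
    if rng is None:
        rng = np.random.default_rng(det_params.random_seed)

    n_in = len(cloud)
    working = downsample(cloud, resolution)
    if len(working) > seg_params.k_neighbors:
        working = estimate_normals(working, k=seg_params.k_neighbors)
        seg = region_growing(working, seg_params)
    else:
        seg = SegmentationResult([], np.arange(len(working)))

    candidates: list[SphereModel] = []
    for region in seg.regions:
        for m in detect_berries_in_region(working.points[region.indices], det_params, rng):
            candidates.append(SphereModel(center=m.center, radius=m.radius,
                                          inlier_indices=region.indices[m.inlier_indices]))
    models = resolve_overlaps(candidates, det_params.overlap_threshold)
    traits = compute_traits(models, working)
    return PipelineResult(models=models, traits=traits, working=working,
                          segmentation=seg, n_points_in=n_in,
                          n_candidates=len(candidates),
                          runtime_s=time.perf_counter() - t0)
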