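"""Bunch architecture traits computed from accepted sphere models.

The seven exported phenotypes: berry number, mean berry diameter (mm), mean
and total berry volume (mL), convex hull volume of all berry inlier points
(mL), bunch width and bunch length (mm).  Length is the maximal vertical
(y-axis) extent between the two extreme berries, width the maximal extent
along x or z — both measured over berry extents (center ± radius) so that
stray stem or hook points cannot inflate them.  1 mL = 1000 mm³.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .detection import SphereModel
from .io import PointCloud

__all__ = ["BunchTraits", "compute_traits", "export_traits", "TRAIT_COLUMNS"]

MM3_PER_ML = 1000.0

TRAIT_COLUMNS = ["scan_id", "n_berries", "mean_diameter_mm", "mean_volume_mL",
                 "total_volume_mL", "convex_hull_mL", "width_mm", "length_mm"]


@dataclass(frozen=True)
class BunchTraits:
    n_berries: int
    mean_diameter: float   # mm
    mean_volume: float     # mL
    total_volume: float    # mL
    convex_hull_volume: float  # mL
    width: float           # mm
    length: float          # mm

    def as_dict(self) -> dict:
        return asdict(self)


def compute_traits(models: list[SphereModel], cloud: PointCloud | None = None) -> BunchTraits:
    """Derive :class:`BunchTraits` from accepted models and their inliers.

    The convex hull is taken over the union of all models' inlier points in
    ``cloud`` (the points "lying inside a detected berry"); with fewer than
    4 non-coplanar inlier points the hull volume is 0 with a warning.  An
    empty model list yields all-zero traits.
    """
    if not models:
        return BunchTraits(0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    radii = np.array([m.radius for m in models], dtype=np.float64)
    centers = np.array([m.center for m in models], dtype=np.float64)
    volumes_ml = 4.0 / 3.0 * np.pi * radii ** 3 / MM3_PER_ML

    hull_volume = 0.0
    if cloud is not None:
        idx = np.unique(np.concatenate([m.inlier_indices for m in models]))
        pts = cloud.points[idx] if len(idx) else np.empty((0, 3))
        hull_volume = _hull_volume_ml(pts)
    else:
        warnings.warn("no cloud given: convex hull volume reported as 0", stacklevel=2)

    lo = centers - radii[:, None]
    hi = centers + radii[:, None]
    length = float(hi[:, 1].max() - lo[:, 1].min())
    width = float(max(hi[:, 0].max() - lo[:, 0].min(), hi[:, 2].max() - lo[:, 2].min()))
    return BunchTraits(
        n_berries=len(models),
        mean_diameter=float(2.0 * radii.mean()),
        mean_volume=float(volumes_ml.mean()),
        total_volume=float(volumes_ml.sum()),
        convex_hull_volume=hull_volume,
        width=width,
        length=length,
    )


def _hull_volume_ml(points: np.ndarray) -> float:
    if len(points) < 4:
        warnings.warn("fewer than 4 inlier points: convex hull volume set to 0", stacklevel=3)
        return 0.0
    try:
        return float(ConvexHull(points).volume) / MM3_PER_ML
    except QhullError:
        warnings.warn("degenerate (coplanar) inlier points: convex hull volume set to 0",
                      stacklevel=3)
        return 0.0


def export_traits(traits: BunchTraits, path, scan_id: str) -> None:
    """Write one tab-separated record with header (the per-scan .txt export).

    Values are rounded to 4 decimals at export only; re-exporting identical
    traits produces a byte-identical file.
    """
    row = _format_row(traits, scan_id)
    with open(Path(path), "w", encoding="ascii", newline="\n") as fh:
        fh.write("\t".join(TRAIT_COLUMNS) + "\n")
        fh.write("\t".join(row) + "\n")


def _format_row(traits: BunchTraits, scan_id: str) -> list[str]:
    return [scan_id, str(traits.n_berries)] + [
        format(v, ".4f") for v in (traits.mean_diameter, traits.mean_volume,
                                   traits.total_volume, traits.convex_hull_volume,
                                   traits.width, traits.length)]


def append_traits_csv(traits: BunchTraits, path, scan_id: str) -> None:
    """Append one row to a combined CSV (header written on first use)."""
    path = Path(path)
    new = not path.exists()
    with open(path, "a", encoding="ascii", newline="\n") as fh:
        if new:
            fh.write(",".join(TRAIT_COLUMNS) + "\n")
        fh.write(",".join(_format_row(traits, scan_id)) + "\n")
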