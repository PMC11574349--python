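"""Expression-domain area from pooled transcription-site centroids.

Centroids detected over a nuclear-cycle time window are pooled
(duplicates from persistent foci kept), cleaned with a per-axis median
absolute deviation (MAD) filter — a conservative rule that strips
isolated, transient or spurious detections — then enclosed in a convex
hull whose area (px^2) measures the spatial extent of expression.  The
nc13 area is subtracted from the nc14 area to report the change while
cancelling embryo-orientation differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .foci import FociFrame


@dataclass
class PointCloud2D:
    points: np.ndarray          # (n, 2) float (y, x)
    source_window: tuple        # (start, stop) frames, stop exclusive

    def __len__(self):
        return len(self.points)


@dataclass
class AreaResult:
    area_nc13: float
    area_nc14: float
    delta_area: float
    n_points_removed: int


def pool_centroids(foci: list[FociFrame], window) -> PointCloud2D:
    """Concatenate all centroids whose frame falls in ``window``."""
    lo, hi = int(window[0]), int(window[1])
    pts = [f.centroids for f in foci if lo <= f.frame < hi and len(f)]
    points = np.concatenate(pts, axis=0) if pts else np.empty((0, 2))
    return PointCloud2D(points=points, source_window=(lo, hi))


def mad_filter(cloud: PointCloud2D, k: float = 2.0) -> PointCloud2D:
    """Remove points more than ``k`` MADs from the median, per axis.

    The MAD is unscaled (no normal-consistency factor).  A point is
    removed iff strictly ``|y - med_y| > k*MAD_y`` or
    ``|x - med_x| > k*MAD_x``; an axis whose MAD is zero contributes no
    removals.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    pts = cloud.points
    if len(pts) == 0:
        return PointCloud2D(points=pts.copy(),
                            source_window=cloud.source_window)
    med = np.median(pts, axis=0)
    mad = np.median(np.abs(pts - med), axis=0)
    keep = np.ones(len(pts), dtype=bool)
    for ax in range(2):
        if mad[ax] > 0:
            keep &= np.abs(pts[:, ax] - med[ax]) <= k * mad[ax]
    return PointCloud2D(points=pts[keep], source_window=cloud.source_window)


def hull_area(cloud: PointCloud2D) -> float:
    """Convex-hull area in px^2; 0 for degenerate (collinear/tiny) sets."""
    pts = np.asarray(cloud.points, dtype=float)
    if len(pts) < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0   # collinear input
    return float(hull.volume)   # 2-D: "volume" is the area


def delta_area(foci: list[FociFrame], window13, window14,
               k: float = 2.0) -> AreaResult:
    """nc14 minus nc13 convex-hull area of MAD-filtered pooled centroids."""
    if not (window13[1] <= window14[0]):
        raise ValueError("windows must be disjoint and ordered (nc13 first)")
    removed = 0
    areas = []
    for window in (window13, window14):
        cloud = pool_centroids(foci, window)
        filtered = mad_filter(cloud, k=k)
        removed += len(cloud) - len(filtered)
        areas.append(hull_area(filtered))
    return AreaResult(area_nc13=areas[0], area_nc14=areas[1],
                      delta_area=areas[1] - areas[0],
                      n_points_removed=removed)
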