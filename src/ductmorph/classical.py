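"""The twelve classical morphometric features.

All lengths are reported in micrometres (areas in um^2) using the image
resolution; the dimensionless shape factors (Circularity, AspectRatio,
Roundness, Solidity, Skewness) are scale-free.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import skew
from skimage import measure

from .geometry import Boundary, Region

__all__ = ["ClassicalFeatures", "FEATURE_NAMES", "region_features", "feret_diameter"]

FEATURE_NAMES = [
    "Area",
    "Perimeter",
    "Width",
    "Height",
    "MajorAxis",
    "MinorAxis",
    "Circularity",
    "FeretDiameter",
    "AspectRatio",
    "Skewness",
    "Roundness",
    "Solidity",
]


@dataclass
class ClassicalFeatures:
    Area: float          # um^2
    Perimeter: float     # um
    Width: float         # um
    Height: float        # um
    MajorAxis: float     # um
    MinorAxis: float     # um
    Circularity: float
    FeretDiameter: float  # um
    AspectRatio: float
    Skewness: float
    Roundness: float
    Solidity: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def feret_diameter(boundary_points: np.ndarray) -> float:
    """Longest distance between any two boundary points.

    Evaluated exactly over the convex hull vertices (the maximum pairwise
    distance of a point set is attained on its hull).
    """
    pts = np.asarray(boundary_points, dtype=float)
    if len(pts) > 3:
        from scipy.spatial import ConvexHull

        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear input: fall back to all points
            pass
    return float(pdist(pts).max()) if len(pts) > 1 else 0.0


def region_features(
    region: Region,
    intensity: np.ndarray | None = None,
    resolution: float | None = None,
) -> ClassicalFeatures:
    """Compute the classical feature vector for one region.

    The perimeter is the traced-contour polygon length; the axes come from
    the second-central-moment best-fit ellipse; Skewness is the third
    standardised moment of the pixel intensities inside the region (0 when
    no intensity raster is supplied).
    """
    res = region.resolution if resolution is None else resolution
    mask = region.mask
    if mask.sum() < 3:
        raise ValueError("region of fewer than 3 pixels: ellipse undefined")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    boundary = Boundary.from_mask(mask)

    area_px = float(mask.sum())
    perim_px = boundary.smoothed(5).perimeter
    r0, c0, r1, c1 = props.bbox
    major_px = float(props.axis_major_length)
    minor_px = float(props.axis_minor_length)
    if minor_px <= 0:
        raise ValueError("degenerate region: minor axis is zero")
    feret_px = feret_diameter(boundary.points)

    if intensity is not None:
        vals = np.asarray(intensity, dtype=float)[mask]
        skewness = float(skew(vals)) if np.ptp(vals) > 0 else 0.0
    else:
        skewness = 0.0

    return ClassicalFeatures(
        Area=area_px * res**2,
        Perimeter=perim_px * res,
        Width=(c1 - c0) * res,
        Height=(r1 - r0) * res,
        MajorAxis=major_px * res,
        MinorAxis=minor_px * res,
        Circularity=4 * np.pi * area_px / perim_px**2,
        FeretDiameter=feret_px * res,
        AspectRatio=major_px / minor_px,
        Skewness=skewness,
        Roundness=4 * area_px / (np.pi * major_px**2),
        Solidity=float(props.solidity),
    )
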