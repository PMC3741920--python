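"""Shared geometric primitives: closed boundaries, regions, nuclei.

Conventions
-----------
* Image rasters are indexed ``(row, col)``, 0-based.
* Boundary points are stored as an ``(n, 2)`` float array of ``(row, col)``
  coordinates, implicitly closed (last point connects back to the first).
* Boundaries are normalised to counter-clockwise orientation in the
  ``(x=col, y=row)`` plane with the start point at the topmost-then-leftmost
  position, so that downstream 1-D signatures are deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw
from shapely.geometry import LinearRing, Point, Polygon
from skimage import measure

__all__ = ["Boundary", "Region", "Nucleus", "NucleusSet", "rasterize_polygon"]


def _shoelace(points: np.ndarray) -> float:
    """Signed area of a closed (row, col) point sequence, in the (col, row) plane."""
    y, x = points[:, 0], points[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


@dataclass
class Boundary:
    """An ordered, implicitly closed sequence of 2-D points.

    Used for the traced lumen boundary, its convex hull, and the
    area-preserving ideal boundary derived from the hull.
    """

    points: np.ndarray
    orientation: str = "ccw"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("boundary needs at least 3 (row, col) points")
        # drop a duplicated closing point if present
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValueError("boundary needs at least 3 distinct points")
        self.points = pts
        self._normalize()

    def _normalize(self) -> None:
        if _shoelace(self.points) < 0:
            self.points = self.points[::-1].copy()
        # start at topmost (min row), then leftmost (min col)
        idx = np.lexsort((self.points[:, 1], self.points[:, 0]))[0]
        self.points = np.roll(self.points, -idx, axis=0)
        self.orientation = "ccw"

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        """Points as (x=col, y=row) pairs for shapely interop."""
        return self.points[:, ::-1]

    def polygon(self) -> Polygon:
        return Polygon(self.xy)

    def ring(self) -> LinearRing:
        return LinearRing(self.xy)

    def is_simple(self) -> bool:
        return self.ring().is_simple

    @property
    def area(self) -> float:
        return abs(_shoelace(self.points))

    @property
    def perimeter(self) -> float:
        seg = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def segment_lengths(self) -> np.ndarray:
        seg = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return np.hypot(seg[:, 0], seg[:, 1])

    def smoothed(self, window: int = 5) -> "Boundary":
        """Circular moving average of the vertices.

        Suppresses the half-pixel stair-stepping of traced contours so that
        polygon length estimates the true perimeter (a raw marching-squares
        chain overestimates a disk's perimeter by several percent).
        """
        if window < 3 or len(self.points) <= window:
            return Boundary(self.points.copy())
        kernel = np.ones(window) / window
        padded = np.vstack(
            [self.points[-(window // 2):], self.points, self.points[: window // 2]]
        )
        rows = np.convolve(padded[:, 0], kernel, mode="valid")
        cols = np.convolve(padded[:, 1], kernel, mode="valid")
        return Boundary(np.c_[rows, cols])

    def resample(self, spacing: float = 1.0) -> "Boundary":
        """Resample to uniform arc-length spacing <= ``spacing`` pixels."""
        if spacing <= 0:
            raise ValueError("spacing must be positive")
        closed = np.vstack([self.points, self.points[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        m = max(int(np.ceil(total / spacing)), 3)
        targets = np.linspace(0.0, total, m, endpoint=False)
        rows = np.interp(targets, cum, closed[:, 0])
        cols = np.interp(targets, cum, closed[:, 1])
        return Boundary(np.c_[rows, cols])

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "Boundary":
        """Trace the outer boundary of the largest foreground component.

        Uses the half-level marching-squares contour, so consecutive points
        are at most sqrt(2) px apart and the traced polygon reproduces the
        mask within one pixel.
        """
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask has no boundary")
        padded = np.pad(mask.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            raise ValueError("no contour found")
        outer = max(contours, key=lambda c: abs(_shoelace(c)))
        return cls(outer - 1.0)

    @classmethod
    def from_polygon(cls, poly: Polygon) -> "Boundary":
        xy = np.asarray(poly.exterior.coords)
        return cls(xy[:, ::-1])


def rasterize_polygon(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a shapely polygon ((x=col, y=row) coords) onto a grid."""
    img = Image.new("1", (shape[1], shape[0]), 0)
    drw = ImageDraw.Draw(img)
    drw.polygon([(x, y) for x, y in poly.exterior.coords], fill=1)
    for ring in poly.interiors:
        drw.polygon([(x, y) for x, y in ring.coords], fill=0)
    return np.asarray(img, dtype=bool)


@dataclass
class Region:
    """A binary raster region with physical area bookkeeping."""

    mask: np.ndarray
    resolution: float = 1.0  # um / pixel

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not self.mask.any():
            raise ValueError("region must be non-empty")

    @property
    def area_px2(self) -> float:
        return float(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px2 * self.resolution**2

    def boundary(self) -> Boundary:
        return Boundary.from_mask(self.mask)

    @classmethod
    def from_boundary(
        cls, boundary: Boundary, shape: tuple[int, int], resolution: float = 1.0
    ) -> "Region":
        return cls(rasterize_polygon(boundary.polygon(), shape), resolution)


@dataclass
class Nucleus:
    """One segmented nucleus: a local mask plus its global placement."""

    mask: np.ndarray          # local boolean patch
    offset: tuple[int, int]   # (row, col) of patch origin in the image
    centroid: tuple[float, float]  # global (row, col)
    area_px2: float

    def global_coords(self) -> tuple[np.ndarray, np.ndarray]:
        rr, cc = np.nonzero(self.mask)
        return rr + self.offset[0], cc + self.offset[1]


@dataclass
class NucleusSet:
    """A labelled collection of nuclei (all / epithelial / non-epithelial)."""

    nuclei: list[Nucleus] = field(default_factory=list)
    role: str = "all"  # "all" | "epithelial" | "non-epithelial"

    def __len__(self) -> int:
        return len(self.nuclei)

    def __iter__(self):
        return iter(self.nuclei)

    def __getitem__(self, i: int) -> Nucleus:
        return self.nuclei[i]

    @property
    def centroids(self) -> np.ndarray:
        if not self.nuclei:
            return np.zeros((0, 2))
        return np.array([n.centroid for n in self.nuclei], dtype=float)

    def subset(self, indices, role: str) -> "NucleusSet":
        return NucleusSet([self.nuclei[i] for i in indices], role=role)
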