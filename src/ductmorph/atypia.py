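"""Duct-atypia features from the lumen boundary and epithelial nuclei.

The actual lumen boundary B_O is compared with an *ideal* boundary B_I: the
convex hull of B_O rescaled about the hull centroid so that the enclosed
area is preserved.  A signed orthogonal-distance signature A(t) along B_I
(positive where B_O lies outside B_I) then yields

* RMSAA   - root-mean-squared atypia amplitude, sqrt(mean A(t)^2);
* TSAV    - total turning angle at the perceptually important points (PIPs)
            of the (L, A) signature, a volatility measure;
* AtypiaRatio / NumAtypiaRegions - area fraction and supra-threshold count
            of the components of the symmetric difference between the
            actual and ideal lumen regions;
* CytoplasmLength (mean, SD) - orthogonal nucleus-to-lumen distances.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely import affinity
from shapely.geometry import LinearRing, Point, Polygon

from .geometry import Boundary, NucleusSet, Region

__all__ = [
    "AtypiaSignature",
    "PIPSequence",
    "AtypiaRegion",
    "AtypiaRegionSet",
    "DuctFeatureVector",
    "ideal_boundary",
    "atypia_signature",
    "rmsaa",
    "detect_pips",
    "tsav",
    "atypia_regions",
    "cytoplasm_features",
    "extract_duct_features",
]

DEFAULT_AREA_THRESHOLD_UM2 = 300.0  # counting threshold for atypia regions


@dataclass
class AtypiaSignature:
    """The 1-D boundary signature: arc length L(t) and amplitude A(t), px."""

    L: np.ndarray
    A: np.ndarray
    total_length: float | None = None  # full closed perimeter of B_I

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.L.shape != self.A.shape or self.L.ndim != 1:
            raise ValueError("L and A must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return len(self.L)

    @property
    def points(self) -> np.ndarray:
        return np.c_[self.L, self.A]

    def rolled_to(self, start: int) -> "AtypiaSignature":
        """The same closed signature re-indexed to begin at ``start``.

        Requires ``total_length`` (the closed perimeter) so the arc lengths
        can be rebuilt across the seam.  Used to anchor PIP detection at an
        intrinsic point instead of the arbitrary trace start.
        """
        if self.total_length is None:
            raise ValueError("rolled_to needs total_length")
        m = len(self)
        start = int(start) % m
        seg = np.diff(np.concatenate([self.L, [self.total_length]]))
        seg = np.roll(seg, -start)
        L = np.concatenate([[0.0], np.cumsum(seg[:-1])])
        return AtypiaSignature(
            L=L, A=np.roll(self.A, -start), total_length=self.total_length
        )


@dataclass
class PIPSequence:
    """Indices of the perceptually important points of a signature."""

    indices: list[int]
    points: np.ndarray  # (m, 2) of (L, A) at the indices

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class AtypiaRegion:
    side: str          # "outside" | "inside" (relative to B_I)
    area_px2: float
    area_um2: float
    centroid: tuple[float, float]


@dataclass
class AtypiaRegionSet:
    regions: list[AtypiaRegion] = field(default_factory=list)
    threshold_um2: float = DEFAULT_AREA_THRESHOLD_UM2

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def total_area_px2(self) -> float:
        return sum(r.area_px2 for r in self.regions)

    def supra_threshold(self) -> list[AtypiaRegion]:
        return [r for r in self.regions if r.area_um2 > self.threshold_um2]


@dataclass
class DuctFeatureVector:
    RMSAA: float                 # um
    TSAV: float                  # rad
    AtypiaRatio: float
    NumAtypiaRegions: int
    CytoplasmLength_mean: float  # um
    CytoplasmLength_SD: float    # um

    def as_dict(self) -> dict[str, float]:
        return {
            "RMSAA": self.RMSAA,
            "TSAV": self.TSAV,
            "AtypiaRatio": self.AtypiaRatio,
            "#AtypiaRegions": self.NumAtypiaRegions,
            "CytoplasmLength": self.CytoplasmLength_mean,
            "CytoplasmLength_SD": self.CytoplasmLength_SD,
        }


def ideal_boundary(
    B_O: Boundary, spacing: float = 1.0
) -> tuple[Boundary, Boundary, float]:
    """Convex hull B_C of the lumen boundary and its area-preserving rescale.

    The scaling factor s = sqrt(Area(R_O) / Area(R_C)) shrinks the hull
    about the hull centroid so that Area(R_I) = Area(R_O); B_I is resampled
    to uniform arc-length spacing <= ``spacing`` px.
    """
    poly = B_O.polygon()
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type != "Polygon" or poly.is_empty:
            raise ValueError("boundary does not enclose a valid region")
    hull = poly.convex_hull
    if hull.geom_type != "Polygon" or hull.area <= 0:
        raise ValueError("degenerate (collinear) boundary")
    s = float(np.sqrt(poly.area / hull.area))
    c = hull.centroid
    scaled = affinity.scale(hull, xfact=s, yfact=s, origin=(c.x, c.y))
    B_C = Boundary.from_polygon(hull)
    B_I = Boundary.from_polygon(scaled).resample(spacing)
    return B_C, B_I, s


def _ray_core_py(origins, normals, seg_a, seg_d, max_range):
    out = np.full(len(origins), np.nan)
    chunk = 256
    for lo in range(0, len(origins), chunk):
        p = origins[lo : lo + chunk]          # (c, 2)
        n = normals[lo : lo + chunk]
        ap = seg_a[None, :, :] - p[:, None, :]  # (c, nseg, 2)
        denom = n[:, None, 0] * seg_d[None, :, 1] - n[:, None, 1] * seg_d[None, :, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (ap[..., 0] * seg_d[None, :, 1] - ap[..., 1] * seg_d[None, :, 0]) / denom
            u = (ap[..., 0] * n[:, None, 1] - ap[..., 1] * n[:, None, 0]) / denom
        valid = (np.abs(denom) > 1e-12) & (u >= 0.0) & (u <= 1.0)
        valid &= np.abs(t) <= max_range
        t = np.where(valid, t, np.nan)
        absT = np.where(np.isnan(t), np.inf, np.abs(t))
        best = np.argmin(absT, axis=1)
        rows = np.arange(len(p))
        chosen = t[rows, best]
        chosen[np.isinf(absT[rows, best])] = np.nan
        out[lo : lo + chunk] = chosen
    return out


def _ray_core_loops(origins, normals, seg_a, seg_d, max_range):
    m = origins.shape[0]
    out = np.full(m, np.nan)
    n = seg_a.shape[0]
    for i in range(m):
        px, py = origins[i, 0], origins[i, 1]
        nx, ny = normals[i, 0], normals[i, 1]
        best = max_range
        found = False
        bt = 0.0
        for j in range(n):
            dx, dy = seg_d[j, 0], seg_d[j, 1]
            den = nx * dy - ny * dx
            if abs(den) < 1e-12:
                continue
            apx = seg_a[j, 0] - px
            apy = seg_a[j, 1] - py
            t = (apx * dy - apy * dx) / den
            at = abs(t)
            if at > best or (found and at == best):
                continue
            u = (apx * ny - apy * nx) / den
            if u < 0.0 or u > 1.0:
                continue
            best = at
            bt = t
            found = True
        if found:
            out[i] = bt
    return out


try:  # optional JIT; the numpy path is the reference implementation
    from numba import njit as _njit

    _ray_core_fast = _njit(cache=True, fastmath=False)(_ray_core_loops)
except Exception:  # pragma: no cover
    _ray_core_fast = None


def _ray_polygon_signed_distance(
    origins: np.ndarray,
    normals: np.ndarray,
    seg_a: np.ndarray,
    seg_d: np.ndarray,
    max_range: float,
) -> np.ndarray:
    """Signed parameter t of the nearest intersection of each ray with the
    polygon (NaN where no intersection lies within ``max_range``)."""
    if _ray_core_fast is not None:
        return _ray_core_fast(
            np.ascontiguousarray(origins),
            np.ascontiguousarray(normals),
            np.ascontiguousarray(seg_a),
            np.ascontiguousarray(seg_d),
            float(max_range),
        )
    return _ray_core_py(origins, normals, seg_a, seg_d, max_range)


def atypia_signature(
    B_I: Boundary, B_O: Boundary, max_range: float | None = None
) -> AtypiaSignature:
    """Signed orthogonal-distance signature of B_O measured along B_I.

    For each point p_t of (uniformly resampled) B_I, a line is cast along
    the outward normal of B_I at p_t; the nearest intersection q with the
    B_O polygon gives |A(t)| = dist(p_t, q), with positive sign when q lies
    outside the region enclosed by B_I and negative inside.  When the line
    misses B_O within ``max_range``, the nearest point of B_O is used with
    a point-in-region sign test.  L(t) is the cumulative arc length of B_I
    from its start point, L(0) = 0.
    """
    if len(B_I) < 3 or len(B_O) < 3:
        raise ValueError("boundaries must have at least 3 points")
    pts = B_I.xy  # (m, 2) in (x, y)
    m = len(pts)
    # outward normal from central-difference tangents (B_I is convex, CCW)
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    norm = np.c_[tang[:, 1], -tang[:, 0]]
    nn = np.hypot(norm[:, 0], norm[:, 1])
    nn[nn == 0] = 1.0
    norm /= nn[:, None]

    overy = B_O.xy
    seg_a = overy
    seg_b = np.roll(overy, -1, axis=0)
    seg_d = seg_b - seg_a
    if max_range is None:
        span = overy.max(axis=0) - overy.min(axis=0)
        max_range = float(np.hypot(*span))

    t = _ray_polygon_signed_distance(pts, norm, seg_a, seg_d, max_range)
    A = t.copy()
    missing = np.isnan(A)
    if missing.any():
        ring = LinearRing(overy)
        poly_i = Polygon(B_I.xy)
        for i in np.nonzero(missing)[0]:
            p = Point(pts[i])
            d = p.distance(ring)
            q = ring.interpolate(ring.project(p))
            sign = 1.0 if not poly_i.contains(q) else -1.0
            A[i] = sign * d

    seg = np.hypot(*(np.roll(pts, -1, axis=0) - pts).T)
    L = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    return AtypiaSignature(L=L, A=A, total_length=float(seg.sum()))


def rmsaa(sig: AtypiaSignature) -> float:
    """Root-mean-squared atypia amplitude, sqrt((1/m) sum A(t)^2)."""
    if len(sig) == 0:
        raise ValueError("empty signature")
    return float(np.sqrt(np.mean(sig.A**2)))


def _chord_distances(points: np.ndarray, s: int, e: int) -> np.ndarray:
    """Perpendicular distances of points s+1..e-1 from the chord s -> e."""
    p, q = points[s], points[e]
    d = q - p
    L = np.hypot(*d)
    mid = points[s + 1 : e]
    if L == 0:
        return np.hypot(*(mid - p).T)
    return np.abs(d[0] * (mid[:, 1] - p[1]) - d[1] * (mid[:, 0] - p[0])) / L


def _turning_angle(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.hypot(*a), np.hypot(*b)
    if na == 0 or nb == 0:
        raise ValueError("zero-length vector between PIPs")
    return float(np.arccos(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)))


def detect_pips(
    sig: AtypiaSignature, T: float = 1.0, theta_min: float = np.deg2rad(5.0)
) -> PIPSequence:
    """All perceptually important points with significance above T.

    Recursive bisection: within the current PIP pair the point of maximum
    perpendicular distance (VD) from the chord in the (L, A) plane becomes
    a new PIP whenever that distance exceeds T, and both sub-intervals are
    processed in turn.  The first and last signature points are always
    PIPs.  Post-processing then removes near-collinear interior PIPs whose
    turning angle falls below ``theta_min`` (smallest-angle first).
    """
    if T < 0:
        raise ValueError("T must be non-negative")
    points = sig.points
    m = len(points)
    if m < 2:
        raise ValueError("signature needs at least 2 points")
    pips = {0, m - 1}
    stack = [(0, m - 1)]
    while stack:
        s, e = stack.pop()
        if e - s < 2:
            continue
        vd = _chord_distances(points, s, e)
        j = int(np.argmax(vd))  # ties: smallest index
        if vd[j] > T:
            k = s + 1 + j
            pips.add(k)
            stack.append((s, k))
            stack.append((k, e))
    idx = sorted(pips)
    # prune near-collinear interior PIPs, smallest turning angle first
    while len(idx) > 2:
        angles = []
        for pos in range(1, len(idx) - 1):
            a = points[idx[pos]] - points[idx[pos - 1]]
            b = points[idx[pos + 1]] - points[idx[pos]]
            angles.append(_turning_angle(a, b))
        worst = int(np.argmin(angles))
        if angles[worst] >= theta_min:
            break
        del idx[worst + 1]
    return PIPSequence(indices=idx, points=points[idx])


def tsav(pips: PIPSequence) -> float:
    """Total sum of atypia volatilities: turning angles at interior PIPs."""
    if len(pips) < 2:
        raise ValueError("need at least 2 PIPs")
    pts = pips.points
    total = 0.0
    for i in range(1, len(pts) - 1):
        total += _turning_angle(pts[i] - pts[i - 1], pts[i + 1] - pts[i])
    return float(total)


def atypia_regions(
    R_O: Region,
    R_I: Region,
    threshold_um2: float = DEFAULT_AREA_THRESHOLD_UM2,
    resolution: float | None = None,
) -> tuple[AtypiaRegionSet, float, int]:
    """Components of the symmetric difference of the actual and ideal lumen.

    The symmetric difference is separated by B_I into parts outside and
    inside the ideal boundary; 8-connected components of each side are the
    atypia regions.  AtypiaRatio uses all regions; NumAtypiaRegions counts
    only those larger than ``threshold_um2``.
    """
    if threshold_um2 < 0:
        raise ValueError("threshold must be non-negative")
    res = R_O.resolution if resolution is None else resolution
    if R_O.mask.shape != R_I.mask.shape:
        raise ValueError("region rasters must share a shape")
    regions: list[AtypiaRegion] = []
    eight = np.ones((3, 3))
    for side, mask in (
        ("outside", R_O.mask & ~R_I.mask),
        ("inside", R_I.mask & ~R_O.mask),
    ):
        labels, n = ndimage.label(mask, structure=eight)
        if n == 0:
            continue
        areas = ndimage.sum_labels(mask, labels, index=range(1, n + 1))
        cents = ndimage.center_of_mass(mask, labels, index=range(1, n + 1))
        for a, c in zip(areas, cents):
            regions.append(
                AtypiaRegion(
                    side=side,
                    area_px2=float(a),
                    area_um2=float(a) * res**2,
                    centroid=tuple(map(float, c)),
                )
            )
    ar = AtypiaRegionSet(regions, threshold_um2=threshold_um2)
    ratio = ar.total_area_px2 / R_O.area_px2
    count = len(ar.supra_threshold())
    return ar, float(ratio), count


def cytoplasm_features(
    N_E: NucleusSet, B_O: Boundary, resolution: float = 1.0
) -> tuple[np.ndarray, float, float]:
    """Orthogonal nucleus-centroid-to-lumen-boundary distances, in um.

    Returns (per-nucleus lengths, mean, SD); the SD uses the population
    divisor m = |N_E|.  An empty set yields zeros with a warning.
    """
    if len(N_E) == 0:
        warnings.warn("empty epithelial set: cytoplasm features set to 0")
        return np.zeros(0), 0.0, 0.0
    ring = LinearRing(B_O.xy)
    lengths = np.array(
        [ring.distance(Point(c[1], c[0])) for c in N_E.centroids], dtype=float
    )
    lengths *= resolution
    return lengths, float(lengths.mean()), float(lengths.std())


def extract_duct_features(
    B_O: Boundary,
    shape: tuple[int, int],
    N_E: NucleusSet,
    resolution: float,
    pip_threshold: float = 1.0,
    theta_min: float = np.deg2rad(5.0),
    area_threshold_um2: float = DEFAULT_AREA_THRESHOLD_UM2,
) -> DuctFeatureVector:
    """All six duct features for one image (lengths reported in um)."""
    _, B_I, _ = ideal_boundary(B_O)
    sig = atypia_signature(B_I, B_O)
    # anchor the PIP recursion at the maximum-amplitude point so the result
    # does not depend on where the boundary trace happened to start
    sig_c = sig.rolled_to(int(np.argmax(sig.A)))
    pips = detect_pips(sig_c, T=pip_threshold, theta_min=theta_min)
    R_O = Region.from_boundary(B_O, shape, resolution)
    R_I = Region.from_boundary(B_I, shape, resolution)
    _, ratio, count = atypia_regions(R_O, R_I, area_threshold_um2, resolution)
    _, cyto_mean, cyto_sd = cytoplasm_features(N_E, B_O, resolution)
    return DuctFeatureVector(
        RMSAA=rmsaa(sig) * resolution,
        TSAV=tsav(pips),
        AtypiaRatio=ratio,
        NumAtypiaRegions=count,
        CytoplasmLength_mean=cyto_mean,
        CytoplasmLength_SD=cyto_sd,
    )
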