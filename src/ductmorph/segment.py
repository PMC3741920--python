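"""Lumen and nucleus segmentation for single-duct H&E crops.

The lumen is found by binarising the illumination-corrected luminance with a
maximum-entropy threshold, locating seed points at the peaks of a direction
cumulative map, and growing a region from the seeds; nuclei come from
k-means colour clustering followed by hole filling and a watershed split.
Epithelial nuclei are the ones nearest to the lumen boundary.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage import filters, measure, morphology
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .geometry import Boundary, Nucleus, NucleusSet

logger = logging.getLogger(__name__)

__all__ = [
    "luminance",
    "kapur_threshold",
    "preprocess_binarize",
    "direction_cumulative_map",
    "detect_seed_points",
    "segment_lumen",
    "segment_nuclei",
    "split_epithelial",
]


def luminance(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luma of an 8-bit RGB image, as float in [0, 255]."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(float)
    return (
        0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2]
    ).astype(float)


def kapur_threshold(gray: np.ndarray) -> int | None:
    """Kapur's maximum-entropy threshold over a 256-bin histogram.

    Returns the threshold maximising the summed Shannon entropies of the
    two classes, or None when the histogram is degenerate (constant image).
    """
    hist, _ = np.histogram(np.clip(gray, 0, 255), bins=256, range=(0, 256))
    p = hist.astype(float) / max(hist.sum(), 1)
    nz = np.nonzero(p)[0]
    if len(nz) < 2:
        return None
    cum = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    cum_plogp = np.cumsum(plogp)
    best_t, best_h = None, -np.inf
    for t in range(nz[0], nz[-1]):
        w0, w1 = cum[t], 1.0 - cum[t]
        if w0 <= 0 or w1 <= 0:
            continue
        h0 = np.log(w0) - cum_plogp[t] / w0
        h1 = np.log(w1) - (cum_plogp[-1] - cum_plogp[t]) / w1
        if h0 + h1 > best_h:
            best_h, best_t = h0 + h1, t
    return best_t


def _median(gray: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return gray
    return filters.median(gray, footprint=morphology.disk(radius))


def background_correct(gray: np.ndarray, degree: int = 1) -> np.ndarray:
    """Flatten slow illumination gradients with a robust polynomial fit.

    A low-order 2-D polynomial is fitted to the luminance, iteratively
    excluding high-residual (highlight) pixels, so the bright lumen never
    contaminates the background estimate — a prerequisite when the object
    of interest can fill half the crop.  The fitted field is subtracted
    and its mean added back to preserve grey levels.
    """
    if degree <= 0:
        return gray
    h, w = gray.shape
    yy, xx = np.mgrid[0:h, 0:w]
    yn = (yy - h / 2) / max(h, 1)
    xn = (xx - w / 2) / max(w, 1)
    terms = [np.ones_like(gray)]
    for d in range(1, degree + 1):
        for p in range(d + 1):
            terms.append(xn ** (d - p) * yn**p)
    A = np.stack([t.ravel() for t in terms], axis=1)
    g = gray.ravel()
    # iteratively refit without high-residual (highlight) pixels so a bright
    # lumen, however large, cannot tilt the illumination estimate
    keep = np.ones(len(g), dtype=bool)
    for _ in range(3):
        coef, *_ = np.linalg.lstsq(A[keep], g[keep], rcond=None)
        resid = g - A @ coef
        med = np.median(resid)
        mad = np.median(np.abs(resid - med))
        keep = resid <= med + max(4.0 * 1.4826 * mad, 2.0)
        if not keep.any():  # pathological: fall back to all pixels
            keep = np.ones(len(g), dtype=bool)
            break
    bg = (A @ coef).reshape(gray.shape)
    return np.clip(gray - bg + bg.ravel()[keep].mean(), 0, 255)


def _drop_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    out = sizes[lab] >= min_size
    out[lab == 0] = False
    return out


def preprocess_binarize(
    image: np.ndarray,
    median_radius: int = 2,
    bg_degree: int = 1,
    min_object: int = 64,
) -> np.ndarray:
    """Median-filter, illumination-correct and max-entropy-threshold an image.

    Returns the binary matrix with 1 marking bright, lumen-like pixels.
    Speckle smaller than ``min_object`` px (threshold-tail noise in the
    stroma) is removed, as are equally small holes.  A constant image
    yields an all-zero mask and a logged warning.
    """
    gray = _median(luminance(image), median_radius)
    gray = background_correct(gray, bg_degree)
    t = kapur_threshold(gray)
    if t is None:
        warnings.warn("constant image: maximum-entropy threshold undefined")
        return np.zeros(gray.shape, dtype=np.uint8)
    # hierarchical application: on sharply multimodal images a single
    # entropy split isolates the dark chromatin phase; while the bright
    # class is still the majority, re-threshold within it so that the
    # foreground ends up being the bright lumen-like minority phase
    for _ in range(3):
        mask = np.floor(gray) > t
        if mask.mean() <= 0.5:
            break
        t2 = kapur_threshold(gray[mask])
        if t2 is None or t2 <= t:
            break
        t = t2
    logger.info("max-entropy threshold: %d", t)
    mask = np.floor(gray) > t
    if min_object > 1 and mask.any():
        # threshold-tail speckle in the stroma is orders of magnitude smaller
        # than any lumen-like area: drop components below an absolute floor
        # and below 1% of the largest bright component, and fill equally
        # small holes
        lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
        sizes = np.bincount(lab.ravel())
        largest = sizes[1:].max() if n else 0
        floor = max(min_object, int(0.01 * largest))
        mask = _drop_small(mask, floor)
        mask = ~_drop_small(~mask, floor)
    return mask.astype(np.uint8)


def _runs_excl(white: np.ndarray) -> np.ndarray:
    """Run length of contiguous white pixels strictly left of each pixel."""
    out = np.zeros(white.shape, dtype=np.int64)
    for j in range(1, white.shape[1]):
        out[:, j] = (out[:, j - 1] + 1) * white[:, j - 1]
    return out


def direction_cumulative_map(A: np.ndarray) -> np.ndarray:
    """Sum of square roots of 4-directional white runs at each white pixel.

    For a white pixel the run in a direction counts the contiguous white
    pixels strictly beyond it (self excluded), stopping at the first black
    pixel or the image border; the map is zero on black pixels.  Peaks mark
    the centres of wide white areas and serve as seed candidates.
    """
    W = np.asarray(A, dtype=bool)
    left = _runs_excl(W)
    right = _runs_excl(W[:, ::-1])[:, ::-1]
    up = _runs_excl(W.T).T
    down = _runs_excl(W[::-1].T).T[::-1]
    H = np.sqrt(left) + np.sqrt(right) + np.sqrt(up) + np.sqrt(down)
    H[~W] = 0.0
    return H


def detect_seed_points(H: np.ndarray) -> list[tuple[float, float]]:
    """Local maxima of the Otsu-thresholded cumulative map.

    Pixels below the Otsu threshold of the map's nonzero values are zeroed
    first (suppresses narrow corridors); a plateau of equal maxima yields a
    single seed at its centroid.  Returns (row, col) seed points.
    """
    H = np.asarray(H, dtype=float)
    nz = H[H > 0]
    if nz.size == 0:
        return []
    if np.ptp(nz) == 0:
        thresh = nz.flat[0]
    else:
        thresh = filters.threshold_otsu(nz)
    HT = np.where(H >= thresh, H, 0.0)
    logger.info("seed map Otsu threshold: %.3f", thresh)
    maxima = morphology.local_maxima(HT, connectivity=2, allow_borders=True)
    maxima &= HT > 0
    labels, n = ndimage.label(maxima, structure=np.ones((3, 3)))
    if n == 0:
        return []
    cents = ndimage.center_of_mass(maxima, labels, index=range(1, n + 1))
    return [tuple(map(float, c)) for c in cents]


def segment_lumen(
    image: np.ndarray,
    seeds: list[tuple[float, float]],
    tolerance: float = 25.0,
    median_radius: int = 2,
) -> Boundary:
    """Grow the lumen from seed points and trace its outer boundary.

    Seeded region growing with a region-mean similarity criterion: the
    region statistics are estimated from small neighbourhoods of the seeds,
    then every pixel within ``tolerance`` grey levels of the region mean
    that is 4-connected to a seed joins the region.  Regions grown from
    different seeds merge when they touch; the largest merged region is
    taken as the lumen.  The result is independent of seed order.
    """
    if not seeds:
        raise ValueError("segment_lumen requires at least one seed")
    gray = _median(luminance(image), median_radius)
    h, w = gray.shape
    seed_px = [(int(round(r)), int(round(c))) for r, c in seeds]
    for r, c in seed_px:
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"seed {(r, c)} outside image")
    # region statistic from 11x11 neighbourhoods of the seeds
    vals = []
    for r, c in seed_px:
        patch = gray[max(0, r - 5) : r + 6, max(0, c - 5) : c + 6]
        vals.append(patch.ravel())
    mean = float(np.mean(np.concatenate(vals)))
    similar = np.abs(gray - mean) <= tolerance
    labels, _ = ndimage.label(similar)  # 4-connectivity
    keep = {labels[r, c] for r, c in seed_px if labels[r, c] != 0}
    if not keep:
        raise ValueError("no seed lies in a region similar to its own mean")
    grown = np.isin(labels, sorted(keep))
    comp, n = ndimage.label(grown)
    sizes = np.bincount(comp.ravel())[1:]
    region = comp == (1 + int(np.argmax(sizes)))
    region = ndimage.binary_fill_holes(region)
    border = np.concatenate(
        [region[0, :], region[-1, :], region[:, 0], region[:, -1]]
    )
    if border.mean() > 0.5:
        warnings.warn("grown region touches most of the image border "
                      "(likely background leak)")
    return Boundary.from_mask(region)


def segment_nuclei(
    image: np.ndarray,
    k: int = 3,
    median_radius: int = 2,
    min_area: int = 10,
    min_separation: int = 7,
    random_state: int = 0,
) -> NucleusSet:
    """Segment all nuclei by k-means colour thresholding plus watershed.

    Pipeline: median filter -> k-means clustering of RGB pixels (the
    darkest-luminance cluster is taken as nuclear chromatin) -> hole
    filling -> marker-based watershed split of touching nuclei -> discard
    components below ``min_area`` px^2.
    """
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValueError("k must be >= 2")
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError("expected an RGB image")
    med = np.stack(
        [_median(image[..., c].astype(float), median_radius) for c in range(3)],
        axis=-1,
    )
    pixels = med.reshape(-1, 3)
    rng = np.random.default_rng(random_state)
    sub = pixels[rng.choice(len(pixels), min(len(pixels), 50_000), replace=False)]
    km = KMeans(n_clusters=k, n_init=4, random_state=random_state).fit(sub)
    centers = km.cluster_centers_
    lum_centers = centers @ np.array([0.299, 0.587, 0.114])
    dark = int(np.argmin(lum_centers))
    # darkest cluster must be clearly darker than the tissue at large,
    # otherwise there are no stained nuclei in the image
    if np.median(lum_centers) - lum_centers[dark] < 25:
        warnings.warn("no distinctly dark cluster: returning empty nucleus set")
        return NucleusSet([], role="all")
    assign = km.predict(pixels.astype(centers.dtype))
    mask = (assign == dark).reshape(med.shape[:2])
    mask = ndimage.binary_fill_holes(mask)
    lab, nlab = ndimage.label(mask)
    if nlab:
        sizes = np.bincount(lab.ravel())
        mask = sizes[lab] >= max(min_area, 2)
        mask[lab == 0] = False
    if not mask.any():
        warnings.warn("no nucleus-sized dark components found")
        return NucleusSet([], role="all")
    distance = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=min_separation, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask)
    nuclei: list[Nucleus] = []
    for prop in measure.regionprops(labels):
        if prop.area < min_area:
            continue
        r0, c0, _, _ = prop.bbox
        nuclei.append(
            Nucleus(
                mask=prop.image.copy(),
                offset=(r0, c0),
                centroid=tuple(map(float, prop.centroid)),
                area_px2=float(prop.area),
            )
        )
    nuclei.sort(key=lambda n: n.centroid)
    return NucleusSet(nuclei, role="all")


def split_epithelial(
    N: NucleusSet, B_O: Boundary
) -> tuple[NucleusSet, NucleusSet]:
    """Partition nuclei into epithelial and non-epithelial sets.

    For every point of the lumen boundary the nearest nucleus centroid is
    selected; the union of selections is the epithelial set, the rest is
    non-epithelial.  Distance ties go to the smallest nucleus index.
    """
    if len(N) == 0:
        warnings.warn("empty nucleus set: nothing to split")
        return NucleusSet([], "epithelial"), NucleusSet([], "non-epithelial")
    d = cdist(B_O.points, N.centroids)
    nearest = np.argmin(d, axis=1)  # first minimum = smallest index
    epi_idx = sorted(set(int(i) for i in nearest))
    non_idx = [i for i in range(len(N)) if i not in set(epi_idx)]
    return N.subset(epi_idx, "epithelial"), N.subset(non_idx, "non-epithelial")
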