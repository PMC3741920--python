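"""End-to-end per-image feature extraction.

Two paths produce identical feature rows:

* :func:`run_pipeline` segments a tissue image from scratch (lumen, nuclei,
  epithelial split) and measures every feature;
* :func:`features_from_truth` measures the same features directly on a
  phantom's ground-truth objects — the fast path for cohort-level
  experiments where segmentation accuracy is not the question.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import atypia, classical, segment
from .geometry import Boundary, Nucleus, NucleusSet, Region
from .phantom import PhantomTruth

logger = logging.getLogger(__name__)

__all__ = ["FeatureParams", "extract_features", "features_from_truth", "run_pipeline"]


@dataclass
class FeatureParams:
    """Tunables of the measurement stage (see docs/methods.md)."""

    resolution: float = 0.492            # um / pixel
    pip_threshold: float = 1.0           # px, PIP significance T
    theta_min_deg: float = 5.0           # PIP pruning angle
    atypia_threshold_um2: float = 300.0  # counting threshold
    median_radius: int = 2
    bg_degree: int = 1                   # illumination-fit polynomial degree
    kmeans_k: int = 3
    min_nucleus_area: int = 10
    nucleus_min_separation: int = 7
    seed: int = 0


def _nucleus_mean_features(
    nuclei: NucleusSet, gray: np.ndarray, res: float, prefix: str
) -> dict[str, float]:
    """Average classical features over a nucleus set (NaN when empty)."""
    if len(nuclei) == 0:
        return {f"{prefix}_{n}": float("nan") for n in classical.FEATURE_NAMES}
    rows = []
    h, w = gray.shape
    for nuc in nuclei:
        r0, c0 = nuc.offset
        ph, pw = nuc.mask.shape
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1, cc1 = min(r0 + ph, h), min(c0 + pw, w)
        local = nuc.mask[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
        if local.sum() < 3:
            continue
        feats = classical.region_features(
            Region(local, res), intensity=gray[rr0:rr1, cc0:cc1]
        )
        rows.append(feats.as_dict())
    if not rows:
        return {f"{prefix}_{n}": float("nan") for n in classical.FEATURE_NAMES}
    out = {}
    for name in classical.FEATURE_NAMES:
        out[f"{prefix}_{name}"] = float(np.mean([r[name] for r in rows]))
    return out


def extract_features(
    image: np.ndarray,
    B_O: Boundary,
    N_E: NucleusSet,
    N_NE: NucleusSet,
    params: FeatureParams,
) -> dict[str, float]:
    """One feature row from already-identified objects (42 features)."""
    gray = segment.luminance(image)
    res = params.resolution
    row: dict[str, float] = {}
    lumen_region = Region.from_boundary(B_O, gray.shape, res)
    lumen = classical.region_features(lumen_region, intensity=gray)
    row.update({f"Lumen_{k}": v for k, v in lumen.as_dict().items()})
    row.update(_nucleus_mean_features(N_E, gray, res, "EN"))
    row.update(_nucleus_mean_features(N_NE, gray, res, "NEN"))
    duct = atypia.extract_duct_features(
        B_O,
        gray.shape,
        N_E,
        resolution=res,
        pip_threshold=params.pip_threshold,
        theta_min=np.deg2rad(params.theta_min_deg),
        area_threshold_um2=params.atypia_threshold_um2,
    )
    row.update(duct.as_dict())
    return row


def _truth_nucleus_sets(truth: PhantomTruth) -> tuple[NucleusSet, NucleusSet]:
    def convert(nuclei, role):
        out = [
            Nucleus(
                mask=n.mask,
                offset=n.offset,
                centroid=n.centroid,
                area_px2=float(n.mask.sum()),
            )
            for n in nuclei
        ]
        return NucleusSet(out, role=role)

    return (
        convert(truth.epithelial, "epithelial"),
        convert(truth.stromal, "non-epithelial"),
    )


def features_from_truth(
    image: np.ndarray, truth: PhantomTruth, params: FeatureParams
) -> dict[str, float]:
    """Feature row measured on a phantom's ground-truth objects."""
    B_O = Boundary.from_mask(truth.lumen_mask)
    N_E, N_NE = _truth_nucleus_sets(truth)
    row = extract_features(image, B_O, N_E, N_NE, params)
    row["status"] = "ok"
    return row


def run_pipeline(
    image: np.ndarray, params: FeatureParams | None = None
) -> dict[str, float]:
    """Full segmentation + measurement of a single-duct RGB image.

    Returns the feature row with a ``status`` flag; when no lumen can be
    found the duct features are missing (NaN) and status records why.
    """
    params = params or FeatureParams()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image")
    logger.info("run_pipeline params: %s", params)
    A = segment.preprocess_binarize(
        image, median_radius=params.median_radius, bg_degree=params.bg_degree
    )
    H = segment.direction_cumulative_map(A)
    seeds = segment.detect_seed_points(H)
    nan_row = {
        name: float("nan")
        for name in (
            [f"Lumen_{n}" for n in classical.FEATURE_NAMES]
            + ["RMSAA", "TSAV", "AtypiaRatio", "#AtypiaRegions",
               "CytoplasmLength", "CytoplasmLength_SD"]
        )
    }
    if not seeds:
        logger.warning("no lumen seed points found")
        gray = segment.luminance(image)
        N = segment.segment_nuclei(
            image,
            k=params.kmeans_k,
            median_radius=params.median_radius,
            min_area=params.min_nucleus_area,
            min_separation=params.nucleus_min_separation,
            random_state=params.seed,
        )
        row = dict(nan_row)
        row.update(_nucleus_mean_features(N, gray, params.resolution, "EN"))
        row.update(_nucleus_mean_features(
            NucleusSet([], "non-epithelial"), gray, params.resolution, "NEN"
        ))
        row["status"] = "lumen-not-found"
        return row
    B_O = segment.segment_lumen(image, seeds, median_radius=params.median_radius)
    N = segment.segment_nuclei(
        image,
        k=params.kmeans_k,
        median_radius=params.median_radius,
        min_area=params.min_nucleus_area,
        min_separation=params.nucleus_min_separation,
        random_state=params.seed,
    )
    N_E, N_NE = segment.split_epithelial(N, B_O)
    row = extract_features(image, B_O, N_E, N_NE, params)
    row["status"] = "ok"
    return row
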