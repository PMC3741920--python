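"""Image and table I/O plus pipeline configuration.

Images are 24-bit RGB TIFF or PNG; the physical resolution comes from an
explicit configuration value when given, otherwise from the TIFF
resolution tags, otherwise the 0.492 um/px slide default.
"""
from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .geometry import Boundary
from .pipeline import FeatureParams

DEFAULT_RESOLUTION = 0.492  # um / pixel

__all__ = [
    "PipelineConfig",
    "load_image",
    "save_image",
    "save_mask",
    "load_mask",
    "boundary_to_json",
    "boundary_from_json",
]


@dataclass
class PipelineConfig:
    """Serialisable configuration of the whole pipeline."""

    resolution: float = DEFAULT_RESOLUTION
    median_radius: int = 2
    bg_degree: int = 1
    kmeans_k: int = 3
    min_nucleus_area: int = 10
    nucleus_min_separation: int = 7
    pip_threshold: float = 1.0
    theta_min_deg: float = 5.0
    atypia_threshold_um2: float = 300.0
    svm_reps: int = 10
    svm_cv_folds: int = 10
    svm_train_fraction: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "resolution", "pip_threshold", "theta_min_deg",
            "atypia_threshold_um2", "svm_train_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def feature_params(self) -> FeatureParams:
        return FeatureParams(
            resolution=self.resolution,
            pip_threshold=self.pip_threshold,
            theta_min_deg=self.theta_min_deg,
            atypia_threshold_um2=self.atypia_threshold_um2,
            median_radius=self.median_radius,
            bg_degree=self.bg_degree,
            kmeans_k=self.kmeans_k,
            min_nucleus_area=self.min_nucleus_area,
            nucleus_min_separation=self.nucleus_min_separation,
            seed=self.seed,
        )

    def to_toml(self, path: str | Path) -> None:
        lines = ["[pipeline]"]
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name} = {json.dumps(v)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        data = tomllib.loads(Path(path).read_text()).get("pipeline", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _tiff_resolution_um(path: Path) -> float | None:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is None:
            return None
        num, den = xres.value
        if num == 0:
            return None
        per_px = den / num  # unit per pixel
        unit_val = getattr(unit, "value", 2)
        unit_name = getattr(unit_val, "name", str(unit_val))
        if unit_name in ("CENTIMETER", "3") or unit_val == 3:
            return per_px * 1e4
        if unit_name in ("INCH", "2") or unit_val == 2:
            return per_px * 25400.0
        return None


def load_image(
    path: str | Path, resolution: float | None = None
) -> tuple[np.ndarray, float]:
    """Load an RGB image; returns (uint8 array, resolution um/px).

    An explicit ``resolution`` wins over TIFF metadata; PNGs fall back to
    the 0.492 um/px default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    meta_res = None
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        meta_res = _tiff_resolution_um(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected 3 channels, got shape {arr.shape}")
    res = resolution if resolution is not None else (meta_res or DEFAULT_RESOLUTION)
    return arr.astype(np.uint8), float(res)


def save_image(path: str | Path, image: np.ndarray,
               resolution: float | None = None) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        kwargs = {}
        if resolution:
            px_per_cm = 1e4 / resolution
            kwargs = {"resolution": (px_per_cm, px_per_cm),
                      "resolutionunit": "CENTIMETER"}
        tifffile.imwrite(path, image, **kwargs)
    else:
        Image.fromarray(image).save(path)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 127


def boundary_to_json(boundary: Boundary, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"points_rc": boundary.points.tolist()})
    )


def boundary_from_json(path: str | Path) -> Boundary:
    data = json.loads(Path(path).read_text())
    return Boundary(np.asarray(data["points_rc"]))
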