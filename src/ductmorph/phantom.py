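"""Synthetic duct phantoms with known ground truth.

A phantom emulates a single H&E duct crop: a bright lumen cavity ringed by
dark, radially oriented (columnar) epithelial nuclei on pink stroma, with
scattered stromal nuclei further out.  Morphology is parametric:

* ``n_lobes`` papillary fronds project *into* the lumen (papillae grow into
  the cavity), each of a prescribed physical area.  Papillary phantoms also
  carry a fine, deterministic scalloping of the rim between fronds — the
  microvillous border that accompanies papillary growth.  The scalloping is
  dimensioned so that each individual scallop stays below the 300 um^2
  atypia-region counting threshold while the fronds stay well above it, which
  makes the expected supra-threshold atypia-region count exactly ``n_lobes``.
* ``boundary_noise_amp`` adds a smooth random radial perturbation, the knob
  for overall boundary irregularity (drives RMSAA / TSAV upward).
* ``cytoplasm_offset_mean`` / ``_sd`` place epithelial nuclei at a controlled
  orthogonal distance from the lumen boundary; the jitter models loss of
  nuclear polarity and directly drives the cytoplasm-length spread.

Identical seeds give bit-identical output.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from shapely import affinity
from shapely.geometry import Point, Polygon

from .geometry import Boundary, rasterize_polygon

__all__ = [
    "PhantomConfig",
    "PhantomNucleus",
    "PhantomTruth",
    "generate_duct_phantom",
    "generate_cohort",
    "grade_configs",
]

# H&E-like palette: near-white lumen, hematoxylin-dark nuclei, eosin stroma.
LUMEN_RGB = (245, 245, 245)
NUCLEUS_RGB = (60, 40, 120)
STROMA_RGB = (230, 180, 200)

# Scalloping of the rim between papillary fronds, relative to lumen radius.
# Wavelength ~29 px and depth ~0.27 R (at the reference R = 300 px) keep each
# scallop's symmetric-difference fragment below the 300 um^2 count threshold
# at 0.492 um/px while leaving room for the area balance of the ideal
# boundary (see docs/methods.md).
_SCALLOP_WAVELENGTH_PX = 29.0
_SCALLOP_DEPTH_FRAC = 80.0 / 300.0
_FROND_ASPECT = 2.0          # radial : tangential semi-axis ratio of fronds
_FROND_PENETRATION_PX = 12.0  # how far a frond breaches the rim circle


@dataclass
class PhantomConfig:
    """Parameters of one synthetic duct image."""

    image_size: tuple[int, int] = (768, 768)   # (h, w) pixels
    lumen_radius: float = 300.0                # px
    n_lobes: int = 0                           # papillary fronds
    lobe_area: float = 2000.0                  # um^2 per frond
    boundary_noise_amp: float = 0.0            # px radial perturbation
    n_epithelial: int = 32
    cytoplasm_offset_mean: float = 8.0         # um, nucleus-to-lumen gap
    cytoplasm_offset_sd: float = 0.0           # um
    n_stromal: int = 25
    nucleus_axes: tuple[float, float] = (18.0, 10.0)  # px (major, minor)
    resolution: float = 0.492                  # um / pixel
    rng_seed: int = 0
    noise_sigma: float = 3.0                   # additive Gaussian image noise

    def validate(self) -> None:
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError("image too small")
        if self.lumen_radius <= 0 or self.resolution <= 0:
            raise ValueError("radii and resolution must be positive")
        if min(self.n_lobes, self.n_epithelial, self.n_stromal) < 0:
            raise ValueError("counts must be non-negative")
        if self.lobe_area <= 0 or self.cytoplasm_offset_mean <= 0:
            raise ValueError("areas and offsets must be positive")
        if self.cytoplasm_offset_sd < 0 or self.boundary_noise_amp < 0:
            raise ValueError("spreads must be non-negative")
        margin = self.lumen_radius + self.cytoplasm_offset_mean / self.resolution
        margin += self.nucleus_axes[0] + 4
        if 2 * margin > min(h, w):
            raise ValueError(
                f"lumen (radius {self.lumen_radius} px plus epithelial ring) "
                f"does not fit in a {h}x{w} image"
            )


@dataclass
class PhantomNucleus:
    centroid: tuple[float, float]       # (row, col)
    mask: np.ndarray                    # local boolean patch
    offset: tuple[int, int]             # patch origin (row, col)
    is_epithelial: bool
    cytoplasm_offset_px: float = 0.0    # placed distance to lumen boundary

    def global_coords(self) -> tuple[np.ndarray, np.ndarray]:
        rr, cc = np.nonzero(self.mask)
        return rr + self.offset[0], cc + self.offset[1]


@dataclass
class PhantomTruth:
    lumen_mask: np.ndarray
    nuclei: list[PhantomNucleus] = field(default_factory=list)
    expected_n_atypia_lobes: int = 0
    lumen_polygon: Polygon | None = None

    @property
    def epithelial(self) -> list[PhantomNucleus]:
        return [n for n in self.nuclei if n.is_epithelial]

    @property
    def stromal(self) -> list[PhantomNucleus]:
        return [n for n in self.nuclei if not n.is_epithelial]


def _smooth_radial_noise(theta: np.ndarray, amp: float, rng) -> np.ndarray:
    """Band-limited radial perturbation with RMS amplitude ``amp`` px."""
    if amp == 0:
        return np.zeros_like(theta)
    out = np.zeros_like(theta)
    for h in range(2, 9):
        a, b = rng.normal(size=2)
        out += a * np.cos(h * theta) + b * np.sin(h * theta)
    rms = np.sqrt(np.mean(out**2))
    return amp * out / rms if rms > 0 else out


def _lumen_polygon(cfg: PhantomConfig, rng) -> tuple[Polygon, np.ndarray]:
    """Build the lumen outline; returns (polygon, frond angles)."""
    h, w = cfg.image_size
    cy, cx = h / 2.0, w / 2.0
    R = cfg.lumen_radius
    n_pts = max(1024, int(8 * np.pi * R))
    theta = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    r = np.full_like(theta, R)
    if cfg.n_lobes > 0:
        m_scallop = max(16, int(round(2 * np.pi * R / _SCALLOP_WAVELENGTH_PX)))
        depth = _SCALLOP_DEPTH_FRAC * R
        r = R - 0.5 * depth * (1 - np.cos(m_scallop * theta))
    r = r + _smooth_radial_noise(theta, cfg.boundary_noise_amp, rng)
    poly = Polygon(np.c_[cx + r * np.cos(theta), cy + r * np.sin(theta)])

    frond_angles = np.array([])
    if cfg.n_lobes > 0:
        area_px = cfg.lobe_area / cfg.resolution**2
        b_t = np.sqrt(area_px / (np.pi * _FROND_ASPECT))
        a_r = _FROND_ASPECT * b_t
        phase = rng.uniform(0, 2 * np.pi)
        spacing = 2 * np.pi / cfg.n_lobes
        jitter = rng.uniform(-0.12, 0.12, size=cfg.n_lobes) * spacing
        frond_angles = phase + spacing * np.arange(cfg.n_lobes) + jitter
        c_r = R + _FROND_PENETRATION_PX - a_r
        for ang in frond_angles:
            e = Point(cx + c_r * np.cos(ang), cy + c_r * np.sin(ang)).buffer(
                1.0, quad_segs=48
            )
            e = affinity.scale(e, a_r, b_t)
            e = affinity.rotate(e, np.degrees(ang))
            poly = poly.difference(e)
        if poly.geom_type != "Polygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        poly = Polygon(poly.exterior)  # fronds must not punch holes
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type != "Polygon":
            poly = max(poly.geoms, key=lambda g: g.area)
    return poly, np.mod(frond_angles, 2 * np.pi)


def _ellipse_patch(major: float, minor: float, angle_rad: float) -> np.ndarray:
    """Boolean raster of a rotated ellipse, tightly cropped."""
    a, b = major / 2.0, minor / 2.0
    ext = int(np.ceil(max(a, b))) + 2
    yy, xx = np.mgrid[-ext : ext + 1, -ext : ext + 1]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = xx * ca + yy * sa
    v = -xx * sa + yy * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_epithelial(
    cfg: PhantomConfig, poly: Polygon, frond_angles: np.ndarray, rng
) -> list[PhantomNucleus]:
    """Ring of columnar nuclei anchored on convex rim points.

    Anchors sit on scallop tops (or, for smooth rims, uniformly on the
    circle), which are locally convex, so moving a nucleus centroid out along
    the radial normal by d px makes its distance to the boundary polyline
    exactly d.
    """
    if cfg.n_epithelial == 0:
        return []
    h, w = cfg.image_size
    cy, cx = h / 2.0, w / 2.0
    R = cfg.lumen_radius
    major, minor = cfg.nucleus_axes

    if cfg.n_lobes > 0:
        m_scallop = max(16, int(round(2 * np.pi * R / _SCALLOP_WAVELENGTH_PX)))
        tops = 2 * np.pi * np.arange(m_scallop) / m_scallop
        # keep tops clear of fronds
        area_px = cfg.lobe_area / cfg.resolution**2
        b_t = np.sqrt(area_px / (np.pi * _FROND_ASPECT))
        half_span = 1.6 * np.arcsin(min(0.99, b_t / R)) + np.pi / m_scallop
        ok = np.ones(len(tops), bool)
        for ang in frond_angles:
            d = np.abs((tops - ang + np.pi) % (2 * np.pi) - np.pi)
            ok &= d > half_span
        anchors = tops[ok]
    else:
        anchors = 2 * np.pi * np.arange(4 * cfg.n_epithelial) / (4 * cfg.n_epithelial)
        anchors = anchors + rng.uniform(0, 2 * np.pi)

    min_sep = (minor + 4.0) / R  # angular separation to avoid overlap
    chosen: list[float] = []
    order = rng.permutation(len(anchors))
    for i in order:
        ang = float(anchors[i])
        if all(
            np.abs((ang - c + np.pi) % (2 * np.pi) - np.pi) >= min_sep for c in chosen
        ):
            chosen.append(ang)
        if len(chosen) == cfg.n_epithelial:
            break
    if len(chosen) < cfg.n_epithelial:
        raise ValueError(
            f"cannot place {cfg.n_epithelial} epithelial nuclei without overlap "
            f"({len(chosen)} fit on the rim)"
        )

    boundary_xy = np.asarray(poly.exterior.coords)
    floor_px = major / 2.0 + 1.0
    nuclei = []
    for ang in sorted(chosen):
        off_um = cfg.cytoplasm_offset_mean
        if cfg.cytoplasm_offset_sd > 0:
            off_um += cfg.cytoplasm_offset_sd * rng.standard_normal()
        off_px = max(off_um / cfg.resolution, floor_px)
        # anchor = nearest exterior vertex to the nominal rim point
        nominal = np.array([cx + R * np.cos(ang), cy + R * np.sin(ang)])
        d2 = np.sum((boundary_xy - nominal) ** 2, axis=1)
        ax, ay = boundary_xy[np.argmin(d2)]
        nx, ny = ax - cx, ay - cy
        nn = np.hypot(nx, ny)
        nx, ny = nx / nn, ny / nn
        px, py = ax + off_px * nx, ay + off_px * ny
        patch = _ellipse_patch(major, minor, np.arctan2(ny, nx))
        ext = patch.shape[0] // 2
        r0, c0 = int(round(py)) - ext, int(round(px)) - ext
        nuclei.append(
            PhantomNucleus(
                centroid=(py, px),
                mask=patch,
                offset=(r0, c0),
                is_epithelial=True,
                cytoplasm_offset_px=off_px,
            )
        )
    return nuclei


def _place_stromal(
    cfg: PhantomConfig, poly: Polygon, occupied: list[PhantomNucleus], rng
) -> list[PhantomNucleus]:
    if cfg.n_stromal == 0:
        return []
    h, w = cfg.image_size
    major, minor = cfg.nucleus_axes
    clearance = 60.0 + cfg.cytoplasm_offset_mean / cfg.resolution
    margin = major / 2 + 2
    centers = [n.centroid for n in occupied]
    placed: list[PhantomNucleus] = []
    tries = 0
    while len(placed) < cfg.n_stromal:
        tries += 1
        if tries > 400 * cfg.n_stromal:
            raise ValueError("cannot place stromal nuclei: image too crowded")
        py = rng.uniform(margin, h - margin)
        px = rng.uniform(margin, w - margin)
        if poly.exterior.distance(Point(px, py)) < clearance or poly.contains(
            Point(px, py)
        ):
            continue
        if any(np.hypot(py - c[0], px - c[1]) < major + 2 for c in centers):
            continue
        ang = rng.uniform(0, np.pi)
        patch = _ellipse_patch(major, minor, ang)
        ext = patch.shape[0] // 2
        nuc = PhantomNucleus(
            centroid=(py, px),
            mask=patch,
            offset=(int(round(py)) - ext, int(round(px)) - ext),
            is_epithelial=False,
        )
        placed.append(nuc)
        centers.append((py, px))
    return placed


def _render(cfg: PhantomConfig, lumen_mask: np.ndarray,
            nuclei: list[PhantomNucleus], rng) -> np.ndarray:
    h, w = cfg.image_size
    img = np.empty((h, w, 3), dtype=float)
    img[:] = STROMA_RGB
    img[lumen_mask] = LUMEN_RGB
    for nuc in nuclei:
        rr, cc = nuc.global_coords()
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        img[rr[keep], cc[keep]] = NUCLEUS_RGB
    if cfg.noise_sigma > 0:
        img += rng.normal(0, cfg.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_duct_phantom(cfg: PhantomConfig) -> tuple[np.ndarray, PhantomTruth]:
    """Render one duct phantom and its ground truth.

    Returns
    -------
    image : (h, w, 3) uint8 RGB raster
    truth : PhantomTruth with the lumen mask, nucleus list and the expected
        number of supra-threshold atypia regions (== ``cfg.n_lobes``).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    poly, frond_angles = _lumen_polygon(cfg, rng)
    lumen_mask = rasterize_polygon(poly, cfg.image_size)
    epithelial = _place_epithelial(cfg, poly, frond_angles, rng)
    # clip any nucleus pixel that would fall inside the lumen (should not
    # happen by construction; enforced to keep the truth invariant strict)
    h, w = cfg.image_size
    for nuc in epithelial:
        rr, cc = nuc.global_coords()
        inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        bad = np.zeros(len(rr), bool)
        bad[inside] = lumen_mask[rr[inside], cc[inside]]
        if bad.any():
            local = np.nonzero(nuc.mask)
            m = nuc.mask.copy()
            m[local[0][bad], local[1][bad]] = False
            nuc.mask = m
    stromal = _place_stromal(cfg, poly, epithelial, rng)
    nuclei = epithelial + stromal
    image = _render(cfg, lumen_mask, nuclei, rng)
    truth = PhantomTruth(
        lumen_mask=lumen_mask,
        nuclei=nuclei,
        expected_n_atypia_lobes=cfg.n_lobes,
        lumen_polygon=poly,
    )
    return image, truth


def grade_configs() -> dict[str, PhantomConfig]:
    """Reference phantom parameters for the three tissue classes.

    Lumen sizes, cytoplasm offsets and their spreads, and papillary lobe
    counts follow the per-class means reported for normal ducts and
    well/moderately differentiated PDAC (lumen area ~3.8e4 / 6.8e4 / 1.2e5
    um^2 scaled to fit single-duct crops; cytoplasm length 6.2 / 12.9 /
    15.9 um with SD 2.1 / 5.8 / 8.5 um; ~0 / 2.5 / 4.8 atypia regions).
    """
    return {
        "normal": PhantomConfig(
            image_size=(768, 768), lumen_radius=220, n_lobes=0,
            boundary_noise_amp=2.0, n_epithelial=32,
            cytoplasm_offset_mean=6.2, cytoplasm_offset_sd=2.1,
            n_stromal=25,
        ),
        "grade1": PhantomConfig(
            image_size=(896, 896), lumen_radius=300, n_lobes=2,
            lobe_area=2000.0, boundary_noise_amp=5.0, n_epithelial=32,
            cytoplasm_offset_mean=12.9, cytoplasm_offset_sd=5.8,
            n_stromal=25,
        ),
        "grade2": PhantomConfig(
            image_size=(896, 896), lumen_radius=330, n_lobes=5,
            lobe_area=2000.0, boundary_noise_amp=9.0, n_epithelial=32,
            cytoplasm_offset_mean=15.9, cytoplasm_offset_sd=8.5,
            n_stromal=25,
        ),
    }


def _epithelial_capacity(cfg: PhantomConfig) -> int:
    """Conservative estimate of how many epithelial nuclei fit on the rim."""
    R = cfg.lumen_radius
    min_sep = (cfg.nucleus_axes[1] + 4.0) / R
    if cfg.n_lobes == 0:
        return int(2 * np.pi / min_sep)
    m_scallop = max(16, int(round(2 * np.pi * R / _SCALLOP_WAVELENGTH_PX)))
    spacing = 2 * np.pi / m_scallop
    area_px = cfg.lobe_area / cfg.resolution**2
    b_t = np.sqrt(area_px / (np.pi * _FROND_ASPECT))
    half_span = 1.6 * np.arcsin(min(0.99, b_t / R)) + np.pi / m_scallop
    blocked = cfg.n_lobes * (2 * half_span / spacing + 2)
    free = max(0.0, m_scallop - blocked)
    per_anchor = max(1, int(np.ceil(min_sep / spacing)))
    return int(free / per_anchor)


def _perturb(cfg: PhantomConfig, rng) -> PhantomConfig:
    """Within-class variation for cohort generation.

    Lumen radius gets a ~8% lognormal factor; the lobe count is Poisson
    around the class mean (kept >= 1 for papillary classes); noise amplitude
    and the cytoplasm offset get modest relative jitter.  This emulates the
    biological spread within a grade so that neighbouring grades overlap.
    """
    new = dataclasses.replace(cfg)
    radius_draw = float(cfg.lumen_radius * rng.lognormal(0, 0.08))
    if cfg.n_lobes > 0:
        # a duct section carries at most a handful of discrete fronds
        new.n_lobes = int(np.clip(rng.poisson(cfg.n_lobes), 1, 6))
    new.boundary_noise_amp = float(
        max(0.0, cfg.boundary_noise_amp * rng.lognormal(0, 0.25))
    )
    new.cytoplasm_offset_mean = float(
        max(2.0, cfg.cytoplasm_offset_mean * rng.lognormal(0, 0.12))
    )
    # clamp the radius so the lumen plus the (jittered) epithelial ring
    # always fits the image, mirroring PhantomConfig.validate()
    h, w = cfg.image_size
    r_max = min(h, w) / 2 - new.cytoplasm_offset_mean / cfg.resolution
    r_max -= cfg.nucleus_axes[0] + 8
    new.lumen_radius = float(np.clip(radius_draw, 20.0, r_max))
    cap = _epithelial_capacity(new)
    new.n_epithelial = int(max(6, min(cfg.n_epithelial, int(0.85 * cap))))
    return new


def generate_cohort(
    n_per_class: int,
    class_cfgs: dict[str, PhantomConfig],
    seed: int,
    vary: bool = True,
) -> list[tuple[str, np.ndarray, PhantomTruth, PhantomConfig]]:
    """Generate ``n_per_class`` labelled phantoms per class.

    Per-image seeds are derived reproducibly from the master seed; with
    ``vary=True`` each image also receives within-class parameter jitter.
    Returns a list of ``(label, image, truth, cfg)`` tuples.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    master = np.random.default_rng(seed)
    out = []
    for label in sorted(class_cfgs):
        base = class_cfgs[label]
        for _ in range(n_per_class):
            img_seed = int(master.integers(0, 2**31 - 1))
            cfg = _perturb(base, master) if vary else dataclasses.replace(base)
            cfg.rng_seed = img_seed
            image, truth = generate_duct_phantom(cfg)
            out.append((label, image, truth, cfg))
    return out
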