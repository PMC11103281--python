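"""Procedural multi-phase abdominal CT phantoms.

Stands in for a clinical renal-cryoablation dataset: each study pairs a
non-contrast (NCE) source volume with two contrast-enhanced targets at the
corticomedullary phase (normalised time t = 1, ~35 s post-injection) and the
nephrographic phase (t = 2, ~80 s).  The scene contains an aorta, two
kidneys with distinct cortex/medulla compartments and a tumour; each region
follows a time-dependent enhancement curve between the two phases, with
additive Gaussian noise, optional inter-phase rigid misalignment, and
optional needle / photon-starvation artefacts.

Ground truth (masks and curves) is exact by construction, which is what
makes desk-scale recovery experiments checkable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volio import Volume

AIR_HU = -1000.0
WINDOW_TOP_HU = 2500.0

#: Baseline (non-contrast) tissue intensities, HU.
DEFAULT_NCE_HU = {
    "tumour": 35.0,
    "cortex": 44.0,
    "medulla": 44.0,
    "aorta": 40.0,
    "background": 30.0,
    "air": AIR_HU,
}

ROI_NAMES = ("aorta", "cortex", "medulla", "tumour")


class GeometryError(ValueError):
    """ROI geometry does not fit the configured grid."""


@dataclass
class EnhancementCurve:
    """Piecewise-linear enhancement of one region over normalised time.

    ``anchors`` maps normalised time t in [1, 2] to absolute HU.  The NCE
    baseline is carried for reference; targets replace the region intensity
    by the curve value at the requested phase.
    """

    roi_label: str
    baseline: float
    anchors: dict[float, float]

    def __post_init__(self):
        if not all(1.0 <= t <= 2.0 for t in self.anchors):
            raise ValueError("curve anchors must lie in t ∈ [1, 2]")
        if len(self.anchors) < 2 or 1.0 not in self.anchors or 2.0 not in self.anchors:
            raise ValueError("curve needs anchors at t = 1 and t = 2")

    def value_at(self, t: float) -> float:
        if not 1.0 <= t <= 2.0:
            raise ValueError(f"normalised time {t} outside [1, 2]")
        ts = np.array(sorted(self.anchors))
        vs = np.array([self.anchors[x] for x in ts])
        return float(np.interp(t, ts, vs))


def evaluate_curve(curve: EnhancementCurve, t: float) -> float:
    """Absolute HU of the region at normalised time t (linear between anchors)."""
    return curve.value_at(t)


def default_curves() -> dict[str, EnhancementCurve]:
    """Fixture enhancement curves reproducing the qualitative clinical
    pattern: aortic washout, cortex brighter than medulla at t=1, near-equal
    cortex/medulla at t=2, mild tumour enhancement."""
    base = DEFAULT_NCE_HU
    return {
        "aorta": EnhancementCurve("aorta", base["aorta"], {1.0: 290.0, 2.0: 190.0}),
        "cortex": EnhancementCurve("cortex", base["cortex"], {1.0: 224.0, 2.0: 164.0}),
        "medulla": EnhancementCurve("medulla", base["medulla"], {1.0: 144.0, 2.0: 159.0}),
        "tumour": EnhancementCurve("tumour", base["tumour"], {1.0: 85.0, 2.0: 90.0}),
    }


@dataclass
class RoiGeometry:
    """Centres/axes in voxel units for the analytic scene (2D or 3D)."""

    body_centre: tuple[float, ...]
    body_axes: tuple[float, ...]
    aorta_centre: tuple[float, ...]
    aorta_radius: float
    kidney_centres: tuple[tuple[float, ...], ...]
    kidney_axes: tuple[float, ...]
    medulla_axes: tuple[float, ...]
    tumour_centre: tuple[float, ...]
    tumour_radius: float


def default_geometry(grid_shape: tuple[int, ...]) -> RoiGeometry:
    nx, ny = grid_shape[0], grid_shape[1]
    sx, sy = nx / 64.0, ny / 64.0

    def pt(x, y):
        return (x * sx, y * sy)

    return RoiGeometry(
        body_centre=pt(32, 32),
        body_axes=(30 * sx, 30 * sy),
        aorta_centre=pt(32, 18),
        aorta_radius=6.5 * min(sx, sy),
        kidney_centres=(pt(17, 38), pt(47, 38)),
        kidney_axes=(9 * sx, 12 * sy),
        medulla_axes=(5 * sx, 7 * sy),
        tumour_centre=pt(47, 29),
        tumour_radius=5.0 * min(sx, sy),
    )


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, ...] = (64, 64, 32)
    voxel_spacing: tuple[float, ...] | None = None
    roi_geometry: RoiGeometry | None = None
    nce_intensities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NCE_HU))
    enhancement_curves: dict[str, EnhancementCurve] = field(default_factory=default_curves)
    noise_sd: float = 15.0
    misalignment_mm: float = 0.0
    jitter_voxels: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.voxel_spacing is None:
            self.voxel_spacing = (1.0,) * len(self.grid_shape)
        for name, hu in self.nce_intensities.items():
            if name != "air" and not (-500.0 <= hu <= 2500.0):
                raise ValueError(f"NCE intensity for {name} outside CT window: {hu}")

    @property
    def ndim(self) -> int:
        return len(self.grid_shape)


@dataclass
class RegionMaskSet:
    """Binary, mutually disjoint region indicators plus the body outline."""

    aorta: np.ndarray
    cortex: np.ndarray
    medulla: np.ndarray
    tumour: np.ndarray
    body: np.ndarray

    def rois(self) -> dict[str, np.ndarray]:
        return {"aorta": self.aorta, "cortex": self.cortex,
                "medulla": self.medulla, "tumour": self.tumour}

    @property
    def foreground(self) -> np.ndarray:
        return self.aorta | self.cortex | self.medulla | self.tumour

    @property
    def background(self) -> np.ndarray:
        return ~self.foreground

    def shifted(self, offset_voxels) -> "RegionMaskSet":
        def sh(m):
            return ndimage.shift(m.astype(np.float64), offset_voxels,
                                 order=0, cval=0.0) > 0.5
        return RegionMaskSet(sh(self.aorta), sh(self.cortex), sh(self.medulla),
                             sh(self.tumour), sh(self.body))


@dataclass
class PairedStudy:
    source: Volume
    targets: dict[float, Volume]
    masks: RegionMaskSet
    truth: PhantomConfig
    meta: dict = field(default_factory=dict)


# -- analytic geometry -------------------------------------------------------


def _coords(grid_shape):
    return np.indices(grid_shape).astype(np.float64)


def _ellipsoid(coords, centre, axes) -> np.ndarray:
    """In-plane ellipse extruded along any remaining (axial) axes."""
    ndim_plane = len(axes)
    acc = np.zeros(coords.shape[1:])
    for i in range(ndim_plane):
        acc += ((coords[i] - centre[i]) / axes[i]) ** 2
    return acc <= 1.0


def _build_masks(cfg: PhantomConfig) -> RegionMaskSet:
    geo = cfg.roi_geometry or default_geometry(cfg.grid_shape)
    coords = _coords(cfg.grid_shape)
    body = _ellipsoid(coords, geo.body_centre, geo.body_axes)
    aorta = _ellipsoid(coords, geo.aorta_centre, (geo.aorta_radius,) * 2)
    kidney = np.zeros(cfg.grid_shape, dtype=bool)
    medulla = np.zeros(cfg.grid_shape, dtype=bool)
    for kc in geo.kidney_centres:
        kidney |= _ellipsoid(coords, kc, geo.kidney_axes)
        medulla |= _ellipsoid(coords, kc, geo.medulla_axes)
    tumour = _ellipsoid(coords, geo.tumour_centre, (geo.tumour_radius,) * 2)

    for name, region in (("aorta", aorta), ("kidney", kidney), ("tumour", tumour)):
        if not (region <= body).all():
            raise GeometryError(f"{name} extends outside the body outline")
        for ax in range(min(2, region.ndim)):
            if np.take(region, 0, axis=ax).any() or np.take(region, -1, axis=ax).any():
                raise GeometryError(f"{name} touches the grid boundary")

    # precedence: tumour > aorta > medulla > cortex
    medulla &= kidney
    cortex = kidney & ~medulla
    for m in (aorta, cortex, medulla):
        m &= ~tumour
    cortex &= ~aorta
    medulla &= ~aorta
    return RegionMaskSet(aorta, cortex, medulla, tumour, body)


def _jittered_config(cfg: PhantomConfig, rng: np.random.Generator) -> PhantomConfig:
    if cfg.jitter_voxels <= 0:
        return cfg
    geo = cfg.roi_geometry or default_geometry(cfg.grid_shape)
    j = cfg.jitter_voxels

    def wiggle(pt):
        return tuple(p + rng.uniform(-j, j) for p in pt)

    geo = replace(
        geo,
        aorta_centre=wiggle(geo.aorta_centre),
        kidney_centres=tuple(wiggle(k) for k in geo.kidney_centres),
        tumour_centre=wiggle(geo.tumour_centre),
    )
    return replace(cfg, roi_geometry=geo)


def _paint(cfg: PhantomConfig, masks: RegionMaskSet,
           values: dict[str, float]) -> np.ndarray:
    img = np.full(cfg.grid_shape, cfg.nce_intensities["air"])
    img[masks.body] = values["background"]
    for name, mask in masks.rois().items():
        img[mask] = values[name]
    return img


def generate_phantom(config: PhantomConfig) -> PairedStudy:
    """Build one paired study (NCE source + targets at t = 1 and t = 2).

    Deterministic for a fixed config/seed.  With ``noise_sd = 0`` the region
    means of each target equal the configured curve values exactly.
    """
    rng = np.random.default_rng(config.seed)
    cfg = _jittered_config(config, rng)
    masks = _build_masks(cfg)

    base = {name: cfg.nce_intensities[name] for name in ROI_NAMES}
    base["background"] = cfg.nce_intensities["background"]

    def noisy(img: np.ndarray) -> np.ndarray:
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
        return img

    spacing = cfg.voxel_spacing
    source = Volume(noisy(_paint(cfg, masks, base)), spacing=spacing)
    targets: dict[float, Volume] = {}
    for t in (1.0, 2.0):
        vals = dict(base)
        for name in ROI_NAMES:
            vals[name] = cfg.enhancement_curves[name].value_at(t)
        targets[t] = Volume(noisy(_paint(cfg, masks, vals)), spacing=spacing)

    study = PairedStudy(source=source, targets=targets, masks=masks, truth=cfg)
    if cfg.misalignment_mm > 0:
        study = apply_misalignment(study, cfg.misalignment_mm,
                                   rng.integers(0, 2**31 - 1))
    return study


def shift_volume(data: np.ndarray, offset_voxels, cval: float = AIR_HU) -> np.ndarray:
    """Rigid translation by (possibly fractional) voxel offsets."""
    return ndimage.shift(data, offset_voxels, order=1, cval=cval, mode="constant")


def apply_misalignment(study: PairedStudy, max_mm: float,
                       seed: int | None = None) -> PairedStudy:
    """Shift the targets (and masks, consistently) by a seeded random rigid
    offset of at most ``max_mm`` per axis; the source is left untouched."""
    if max_mm < 0:
        raise ValueError("max_mm must be non-negative")
    if max_mm == 0:
        return study
    rng = np.random.default_rng(seed)
    spacing = np.asarray(study.source.spacing)
    offset_mm = rng.uniform(-max_mm, max_mm, size=len(spacing))
    offset_vox = offset_mm / spacing
    targets = {
        t: replace(v, data=shift_volume(v.data, offset_vox))
        for t, v in study.targets.items()
    }
    masks = study.masks.shifted(offset_vox)
    meta = dict(study.meta, misalignment_offset_vox=tuple(offset_vox))
    return PairedStudy(source=study.source, targets=targets, masks=masks,
                       truth=study.truth, meta=meta)


def add_needle_artifacts(volume: Volume, n_needles: int,
                         seed: int | None = None,
                         streak_drop_hu: float = 120.0) -> Volume:
    """Insert hyperdense needle tracks (clipped at the window top, 2500 HU)
    with dark photon-starvation streak fans emanating from each tip."""
    if n_needles < 0:
        raise ValueError("n_needles must be non-negative")
    if n_needles == 0:
        return volume.copy()
    rng = np.random.default_rng(seed)
    data = volume.data.copy()
    shape = data.shape
    nd = data.ndim

    def raster_line(p0, p1):
        n = int(np.ceil(np.linalg.norm(np.subtract(p1, p0)))) * 2 + 1
        pts = np.linspace(p0, p1, n)
        idx = np.round(pts).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        return tuple(idx[ok].T)

    for _ in range(n_needles):
        # entry on the first-axis edge, tip in the central third
        entry = np.array([0.0] + [rng.uniform(0, s - 1) for s in shape[1:]])
        tip = np.array([rng.uniform(s / 3, 2 * s / 3) for s in shape])
        data[raster_line(entry, tip)] = WINDOW_TOP_HU
        for _ray in range(6):
            direction = rng.normal(size=nd)
            direction /= np.linalg.norm(direction)
            end = tip + direction * max(shape) / 3
            ray_idx = raster_line(tip, end)
            data[ray_idx] = np.maximum(data[ray_idx] - streak_drop_hu, AIR_HU)
    return replace(volume, data=data)


def roi_means(volume: Volume, masks: RegionMaskSet) -> dict[str, float]:
    """Mean intensity of each region; convenience for recovery checks."""
    out = {}
    for name, mask in masks.rois().items():
        if mask.any():
            out[name] = float(volume.data[mask].mean())
        else:
            warnings.warn(f"ROI {name} is empty")
            out[name] = float("nan")
    return out
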