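"""Volume containers, NIfTI I/O, intensity windowing and patch geometry.

Conventions used everywhere in the package: 0-based voxel indices with the
origin at the array corner, axis order ``(x, y, z)`` (or ``(x, y)`` in 2D
desk-scale mode), intensities either in Hounsfield units (HU) or window-
normalised to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: CT display window applied before normalisation, HU.
WINDOW_HU = (-500.0, 2500.0)
#: Width of the window, HU per unit normalised intensity.
WINDOW_WIDTH = WINDOW_HU[1] - WINDOW_HU[0]


class VolumeStateError(RuntimeError):
    """Raised when an operation is applied to the wrong intensity state."""


@dataclass
class Volume:
    """A 2D or 3D intensity image with voxel spacing metadata."""

    data: np.ndarray
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0)
    units: str = "HU"  # "HU" | "norm"
    origin: tuple[float, ...] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.units not in ("HU", "norm"):
            raise ValueError(f"unknown units {self.units!r}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI volume; a single-slice 3D file is collapsed back to 2D."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    zooms = img.header.get_zooms()[: data.ndim]
    # single-slice files are the 2D storage convention (see write_volume)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
        zooms = zooms[:2]
    return Volume(data=data, spacing=tuple(zooms))


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write as NIfTI (.nii or .nii.gz); 2D data is stored as single-slice 3D."""
    data = volume.data
    spacing = volume.spacing
    is_2d = data.ndim == 2
    if is_2d:
        data = data[:, :, None]
        spacing = tuple(spacing[:2]) + (1.0,)
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms(spacing)
    if is_2d:
        img.header["dim"][0] = 2  # remember the native rank for round-trips
    nib.save(img, str(path))


def window_normalise(volume: Volume) -> Volume:
    """Clip HU to the CT window [-500, 2500] and map linearly onto [0, 1]."""
    if volume.units != "HU":
        raise VolumeStateError("window_normalise expects a HU volume")
    lo, hi = WINDOW_HU
    data = (np.clip(volume.data, lo, hi) - lo) / WINDOW_WIDTH
    return replace(volume, data=data, units="norm")


def denormalise_hu(volume: Volume, tol: float = 1e-6) -> Volume:
    """Exact inverse of :func:`window_normalise` on [0, 1]."""
    if volume.units != "norm":
        raise VolumeStateError("denormalise_hu expects a normalised volume")
    d = volume.data
    if d.min() < -tol or d.max() > 1.0 + tol:
        raise VolumeStateError(
            f"normalised intensities outside [0, 1]: [{d.min():g}, {d.max():g}]"
        )
    lo, _ = WINDOW_HU
    return replace(volume, data=np.clip(d, 0.0, 1.0) * WINDOW_WIDTH + lo, units="HU")


def sample_subvolume(volume: Volume, depth: int,
                     rng: np.random.Generator | int | None = None) -> Volume:
    """Random contiguous axial block of ``depth`` slices, full in-plane extent.

    The origin along the last (axial) axis is uniform over all admissible
    positions.  2D volumes with ``depth`` along the second axis are handled
    the same way.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    extent = volume.shape[-1]
    if depth > extent:
        raise ValueError(f"volume depth {extent} smaller than requested {depth}")
    z0 = int(rng.integers(0, extent - depth + 1))
    return replace(volume, data=volume.data[..., z0:z0 + depth].copy())


@dataclass
class PatchGrid:
    """Sliding-window plan: origins at multiples of ``stride`` plus a flush
    final origin per axis, guaranteeing full coverage without padding."""

    volume_shape: tuple[int, ...]
    patch_size: tuple[int, ...]
    stride: int
    positions: list[tuple[int, ...]] = field(default_factory=list)

    def coverage(self) -> np.ndarray:
        """Per-voxel count of covering patches (brute-force accumulation)."""
        cov = np.zeros(self.volume_shape, dtype=np.int64)
        for pos in self.positions:
            sl = tuple(slice(p, p + k) for p, k in zip(pos, self.patch_size))
            cov[sl] += 1
        return cov

    def to_dict(self) -> dict:
        return {
            "volume_shape": list(self.volume_shape),
            "patch_size": list(self.patch_size),
            "stride": self.stride,
            "positions": [list(p) for p in self.positions],
        }


def _axis_origins(extent: int, patch: int, stride: int) -> list[int]:
    origins = list(range(0, extent - patch + 1, stride))
    flush = extent - patch
    if origins[-1] != flush:
        origins.append(flush)
    return origins


def plan_patches(volume_shape, patch_size, stride: int = 16) -> PatchGrid:
    """Lexicographically sorted patch origins covering every voxel."""
    volume_shape = tuple(int(s) for s in volume_shape)
    if np.isscalar(patch_size):
        patch_size = (int(patch_size),) * len(volume_shape)
    patch_size = tuple(int(p) for p in patch_size)
    if stride <= 0:
        raise ValueError(f"stride must be positive, got {stride}")
    if stride > min(patch_size):
        # a stride wider than the patch leaves uncovered gaps between origins
        raise ValueError(f"stride {stride} exceeds patch size {patch_size}")
    for extent, patch in zip(volume_shape, patch_size):
        if patch > extent:
            raise ValueError(
                f"patch size {patch_size} exceeds volume shape {volume_shape}"
            )
    axes = [_axis_origins(e, p, stride) for e, p in zip(volume_shape, patch_size)]
    positions = [tuple(p) for p in np.stack(
        np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, len(axes))]
    return PatchGrid(volume_shape, patch_size, stride, positions)
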