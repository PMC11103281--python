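"""Inference: full-volume and sliding-window synthesis at arbitrary phase.

The normalised phase axis maps linearly onto seconds after contrast
injection: t = 1 is the corticomedullary phase at 35 s, t = 2 the
nephrographic phase at 80 s, so seconds = 35 + 45 (t - 1).

Sliding-window reconstruction follows the training-time patch geometry:
the model is passed over the volume with a given stride and overlapping
patch predictions are combined by uniform (unweighted) averaging.  The
dropout noise z is seeded once per volume so that overlapping patches
average coherent realisations; a per-patch seed policy is available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import autodiff as ad
from .hyper import HyperGenerator, MaterializedGenerator
from .nets import Generator
from .volio import Volume, plan_patches

PHASE_T0_SECONDS = 35.0
PHASE_T1_SECONDS = 80.0


@dataclass(frozen=True)
class PhasePoint:
    """A normalised time t in [1, 2] and its wall-clock label in seconds."""

    t: float

    def __post_init__(self):
        if not 1.0 <= self.t <= 2.0:
            raise ValueError(f"normalised time {self.t} outside [1, 2]")

    @property
    def seconds(self) -> float:
        return PHASE_T0_SECONDS + (PHASE_T1_SECONDS - PHASE_T0_SECONDS) * (self.t - 1.0)


def _forward(generator, x, t, rng, dropout):
    if isinstance(generator, HyperGenerator):
        return generator.forward(x, t, rng=rng, dropout=dropout)
    if isinstance(generator, MaterializedGenerator):
        return generator.forward(x, rng=rng, dropout=dropout)
    if isinstance(generator, Generator) and generator.spec.conditioning == "concat":
        return generator.forward(x, t=t, rng=rng, dropout=dropout)
    return generator.forward(x, t=None, rng=rng, dropout=dropout)


def predict_full(generator, volume: Volume, t: float,
                 dropout_seed: int | None = 0,
                 dropout: bool = True) -> Volume:
    """Whole-volume prediction; deterministic given ``dropout_seed``."""
    if volume.units != "norm":
        raise ValueError("predict_full expects a window-normalised volume")
    PhasePoint(t)
    with ad.no_grad():
        out = _forward(generator, volume.data,
                       t, np.random.default_rng(dropout_seed), dropout)
    return replace(volume, data=out.data[0])


def predict_sliding(generator, volume: Volume, t: float,
                    patch_size: int = 64, stride: int = 16,
                    dropout_seed: int | None = 0, dropout: bool = True,
                    seed_per_patch: bool = False) -> Volume:
    """Stride-and-average reconstruction.

    Every voxel's value is the arithmetic mean of all covering patch
    predictions, accumulated in lexicographic patch order (streamed sum
    divided by exact coverage counts).
    """
    if volume.units != "norm":
        raise ValueError("predict_sliding expects a window-normalised volume")
    PhasePoint(t)
    grid = plan_patches(volume.shape, patch_size, stride)
    acc = np.zeros(volume.shape)
    cov = np.zeros(volume.shape, dtype=np.int64)
    with ad.no_grad():
        for i, pos in enumerate(grid.positions):
            sl = tuple(slice(p, p + k) for p, k in zip(pos, grid.patch_size))
            rng = np.random.default_rng(
                (dropout_seed or 0) + i if seed_per_patch else dropout_seed)
            pred = _forward(generator, volume.data[sl], t, rng, dropout)
            acc[sl] += pred.data[0]
            cov[sl] += 1
    return replace(volume, data=acc / cov)


def interpolate_phases(generator, volume: Volume, times,
                       mode: str = "full", dropout_seed: int | None = 0,
                       dropout: bool = True, **kwargs) -> list[Volume]:
    """One prediction per requested phase with a shared dropout seed, so the
    phase is the only factor varying across the returned volumes."""
    out = []
    for t in times:
        if mode == "sliding":
            out.append(predict_sliding(generator, volume, t,
                                       dropout_seed=dropout_seed,
                                       dropout=dropout, **kwargs))
        else:
            out.append(predict_full(generator, volume, t,
                                    dropout_seed=dropout_seed, dropout=dropout))
    return out
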