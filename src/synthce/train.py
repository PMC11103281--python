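"""Losses, differentiable augmentation and the adversarial training loop.

Four model variants are supported: the phase-concatenation baseline
(P2P) and the HyperNetwork variant (HP2P), each either with a full
receptive field ("full": the network sees the whole image or a random
depth-64 sub-volume) or operating on 64^d patches ("patch").

The supervised term splits the L1 image difference into foreground
(aorta, kidney compartments, tumour) and background parts using the
segmentation masks,

    L_F = |1_F (y_t - f(x, z, t))|_1,   L_B = |1_B (y_t - f(x, z, t))|_1,
    L_ROI = mu L_F + (1 - mu) L_B,

and is added to the generator's non-saturating adversarial loss with
weight lambda.  The adversarial losses are the usual binary cross-entropy
on the PatchGAN logit map,

    L_D = -E ln sigma(real) - E ln(1 - sigma(fake)),
    L_G = -E ln sigma(fake) + lambda L_ROI,

with expectations taken as means over the patch-logit map, computed via
stabilised softplus so they stay finite for any finite logit.

By default the two L1 terms are means over their region's voxel count;
the raw-sum form is available via ``normalise=False``.  One discriminator
update is followed by one generator update per minibatch (of size one),
and the phase t is drawn uniformly from {1, 2} each step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nets import (Discriminator, DiscriminatorSpec, Generator, GeneratorSpec)
from .hyper import HyperGenerator, HyperNetSpec
from .phantom import PairedStudy
from .volio import window_normalise


@dataclass
class LossWeights:
    mu: float = 0.1
    lam: float = 720.0

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class AugmentationPolicy:
    translate: bool = True
    cutout: bool = True
    intensity: bool = True
    contrast: bool = True
    translation_frac: float = 0.125
    cutout_frac: float = 0.25
    intensity_range: float = 0.1
    contrast_range: tuple[float, float] = (0.8, 1.2)

    @classmethod
    def disabled(cls) -> "AugmentationPolicy":
        return cls(translate=False, cutout=False, intensity=False, contrast=False)


@dataclass
class TrainConfig:
    variant: str = "p2p"              # "p2p" | "hp2p"
    mode: str = "full"                # "full" | "patch"
    dims: int = 3
    steps: int = 1000
    seed: int = 0
    lr_d: float | None = None
    lr_g: float | None = None
    betas: tuple[float, float] = (0.5, 0.999)
    mu: float = 0.1
    lam: float | None = None
    patch_size: int = 64
    subvolume_depth: int = 64
    gen_layers: int = 7
    gen_channels: int = 32
    disc_layers: int = 3
    disc_channels: int = 16
    embed_dim: int = 64
    hidden_width: int = 128
    chunk_size: int | None = 3456
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    val_every: int = 100
    val_fraction: float = 0.0

    def __post_init__(self):
        if self.variant not in ("p2p", "hp2p"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.mode not in ("full", "patch"):
            raise ValueError(f"unknown mode {self.mode!r}")
        # tuned defaults per variant
        if self.lr_d is None:
            self.lr_d = 2.0e-5 if self.variant == "p2p" else 1.0e-4
        if self.lr_g is None:
            self.lr_g = 3.5e-4 if self.variant == "p2p" else 5.6e-4
        if self.lam is None:
            self.lam = 720.0 if self.variant == "p2p" else 630.0
        if self.lr_d <= 0 or self.lr_g <= 0:
            raise ValueError("learning rates must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["augmentation"] = asdict(self.augmentation)
        return d


# -- losses ------------------------------------------------------------------


def loss_roi(y, y_hat: Tensor, fg_mask: np.ndarray, bg_mask: np.ndarray,
             mu: float, normalise: bool = True):
    """Foreground/background-split supervised L1 loss.

    Returns ``(l_roi, l_f, l_b)`` where ``l_roi`` stays in the graph and the
    component terms are python floats for logging.  An empty foreground
    contributes zero (with a warning) rather than dividing by zero.
    """
    y_arr = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=np.float64)
    fg = np.asarray(fg_mask, dtype=np.float64)
    bg = np.asarray(bg_mask, dtype=np.float64)
    if fg.shape != y_arr.shape[-fg.ndim:]:
        raise ValueError("mask shape does not match image shape")
    diff = ad.absolute(y_hat - Tensor(y_arr))
    n_f, n_b = fg.sum(), bg.sum()
    if n_f == 0:
        warnings.warn("empty foreground mask; L_F set to 0")
        l_f = Tensor(0.0)
    else:
        l_f = (diff * Tensor(fg)).sum() / (n_f if normalise else 1.0)
    l_b = (diff * Tensor(bg)).sum() / (n_b if normalise else 1.0)
    l = mu * l_f + (1.0 - mu) * l_b
    return l, float(l_f.data), float(l_b.data)


def loss_discriminator(real_logits: Tensor, fake_logits: Tensor) -> Tensor:
    """L_D = -E ln sigma(real) - E ln(1 - sigma(fake)), means over the map."""
    return ad.softplus(-real_logits).mean() + ad.softplus(fake_logits).mean()


def loss_generator(fake_logits: Tensor, l_roi: Tensor | float,
                   lam: float) -> Tensor:
    """L_G = -E ln sigma(fake) + lambda * L_ROI (non-saturating form)."""
    adv = ad.softplus(-fake_logits).mean()
    return adv + lam * l_roi if lam else adv


# -- differentiable augmentation ---------------------------------------------


def _sample_realisation(shape_spatial, policy: AugmentationPolicy,
                        rng: np.random.Generator) -> dict:
    r = {}
    if policy.translate:
        r["shift"] = tuple(
            int(rng.integers(-int(policy.translation_frac * s),
                             int(policy.translation_frac * s) + 1))
            for s in shape_spatial)
    if policy.cutout:
        sizes = tuple(int(policy.cutout_frac * s) for s in shape_spatial)
        origins = tuple(int(rng.integers(0, s - c + 1))
                        for s, c in zip(shape_spatial, sizes))
        r["cutout"] = (origins, sizes)
    if policy.intensity:
        r["intensity"] = float(rng.uniform(-policy.intensity_range,
                                           policy.intensity_range))
    if policy.contrast:
        r["contrast"] = float(rng.uniform(*policy.contrast_range))
    return r


def _apply_realisation(img: Tensor, r: dict) -> Tensor:
    out = img
    if "contrast" in r:
        m = out.mean()
        out = (out - m) * r["contrast"] + m
    if "intensity" in r:
        out = out + r["intensity"]
    if "shift" in r:
        shift = r["shift"]
        pw = [(0, 0)] + [(max(s, 0), max(-s, 0)) for s in shift]
        out = ad.pad(out, pw)
        sl = (slice(None),) + tuple(
            slice(max(-s, 0), max(-s, 0) + n)
            for s, n in zip(shift, img.shape[1:]))
        out = out[sl]
    if "cutout" in r:
        origins, sizes = r["cutout"]
        mask = np.ones(img.shape)
        sl = (slice(None),) + tuple(slice(o, o + c) for o, c in zip(origins, sizes))
        mask[sl] = 0.0
        out = out * Tensor(mask)
    return out


def diff_augment(images: list[Tensor], policy: AugmentationPolicy,
                 rng: np.random.Generator | int | None = None) -> list[Tensor]:
    """Apply one shared random realisation of the policy to every image.

    All transforms are differentiable with respect to the image input, so
    the generator receives gradients through the augmented discriminator
    view.  Real and generated images within a step must share the
    realisation -- pass them together.
    """
    if not images:
        return images
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    images = [img if isinstance(img, Tensor) else Tensor(img) for img in images]
    r = _sample_realisation(images[0].shape[1:], policy, rng)
    return [_apply_realisation(img, r) for img in images]


# -- training loop -----------------------------------------------------------


@dataclass
class TrainState:
    config: TrainConfig
    generator: Generator | HyperGenerator
    discriminator: Discriminator
    opt_g: ad.Adam
    opt_d: ad.Adam
    rng: np.random.Generator
    step: int = 0
    log: list[dict] = field(default_factory=list)
    best_val: float = np.inf
    best_params: dict | None = None

    def generator_forward(self, x, t, rng=None, dropout=True,
                          paramset=None) -> Tensor:
        if isinstance(self.generator, HyperGenerator):
            return self.generator.forward(x, t, rng=rng, dropout=dropout,
                                          paramset=paramset)
        return self.generator.forward(x, t=t, rng=rng, dropout=dropout)


def build_models(config: TrainConfig, seed: int | None = None):
    seed = config.seed if seed is None else seed
    gspec = GeneratorSpec(
        n_layers=config.gen_layers, base_channels=config.gen_channels,
        dims=config.dims,
        conditioning="concat" if config.variant == "p2p" else "hyper")
    if config.variant == "p2p":
        gen: Generator | HyperGenerator = Generator(gspec, seed=seed)
    else:
        hspec = HyperNetSpec(embed_dim=config.embed_dim,
                             hidden_width=config.hidden_width,
                             chunk_size=config.chunk_size)
        gen = HyperGenerator(gspec, hspec, seed=seed)
    disc = Discriminator(
        DiscriminatorSpec(n_layers=config.disc_layers,
                          base_channels=config.disc_channels, dims=config.dims),
        seed=seed + 1)
    return gen, disc


def _normalised_arrays(study: PairedStudy):
    x = window_normalise(study.source).data
    ys = {t: window_normalise(v).data for t, v in study.targets.items()}
    return x, ys, study.masks.foreground, study.masks.background


def _crop(arrs, origin, size):
    sl = tuple(slice(o, o + s) for o, s in zip(origin, size))
    return [a[sl] for a in arrs]


def _sample_view(x, y, fg, bg, config: TrainConfig, rng: np.random.Generator):
    """Random sub-volume (full mode, 3D) or random patch (patch mode)."""
    shape = x.shape
    if config.mode == "patch":
        size = (min(config.patch_size, s) for s in shape)
        size = tuple(size)
        origin = tuple(int(rng.integers(0, s - c + 1)) for s, c in zip(shape, size))
        return _crop([x, y, fg, bg], origin, size)
    if len(shape) == 3 and shape[-1] > config.subvolume_depth:
        z0 = int(rng.integers(0, shape[-1] - config.subvolume_depth + 1))
        sl = (slice(None), slice(None), slice(z0, z0 + config.subvolume_depth))
        return [a[sl] for a in (x, y, fg, bg)]
    return [x, y, fg, bg]


def train_step(state: TrainState, study_arrays) -> dict:
    """One discriminator update followed by one generator update."""
    config = state.config
    rng = state.rng
    x, ys, fg, bg = study_arrays
    t = float(rng.choice([1.0, 2.0]))
    y = ys[t]
    x, y, fg_v, bg_v = _sample_view(x, y, fg, bg, config, rng)

    step_seed = int(rng.integers(0, 2**31 - 1))
    aug_rng = np.random.default_rng(step_seed)

    # hyper variant: materialise theta(t) once per step; the detached
    # discriminator pass reuses it without touching its graph
    paramset = None
    if isinstance(state.generator, HyperGenerator):
        paramset = state.generator.kernels_at(t)

    # --- discriminator update (generator output detached) ---
    with ad.no_grad():
        fake = state.generator_forward(x, t, rng=np.random.default_rng(step_seed + 1),
                                       paramset=paramset)
    real_aug, fake_aug = diff_augment(
        [Tensor(y[None]), Tensor(fake.data)], config.augmentation, aug_rng)
    l_d = loss_discriminator(state.discriminator(real_aug, t),
                             state.discriminator(fake_aug, t))
    if not np.isfinite(l_d.data):
        raise RuntimeError(f"non-finite discriminator loss at step {state.step}")
    l_d.backward()
    state.opt_d.step()
    state.opt_d.zero_grad()

    # --- generator update (discriminator parameters held fixed) ---
    fake = state.generator_forward(x, t, rng=np.random.default_rng(step_seed + 1),
                                   paramset=paramset)
    (fake_aug,) = diff_augment([fake], config.augmentation,
                               np.random.default_rng(step_seed))
    l_roi, l_f, l_b = loss_roi(y[None], fake, fg_v[None], bg_v[None], config.mu)
    l_g = loss_generator(state.discriminator(fake_aug, t), l_roi, config.lam)
    if not np.isfinite(l_g.data):
        raise RuntimeError(f"non-finite generator loss at step {state.step}")
    l_g.backward()
    state.opt_g.step()
    state.opt_g.zero_grad()
    state.opt_d.zero_grad()  # grads reached D through the G objective

    rec = {"step": state.step, "t": t, "L_D": float(l_d.data),
           "L_G": float(l_g.data), "L_F": l_f, "L_B": l_b,
           "L_ROI": float(l_roi.data)}
    state.log.append(rec)
    state.step += 1
    return rec


def _validation_l_roi(state: TrainState, val_arrays) -> float:
    config = state.config
    total = 0.0
    with ad.no_grad():
        for x, ys, fg, bg in val_arrays:
            for t in (1.0, 2.0):
                xv, yv, fgv, bgv = _sample_view(x, ys[t], fg, bg, config,
                                                np.random.default_rng(0))
                pred = state.generator_forward(xv, t, rng=np.random.default_rng(0))
                l, _, _ = loss_roi(yv[None], pred, fgv[None], bgv[None], config.mu)
                total += float(l.data)
    return total


def _snapshot_params(state: TrainState) -> dict:
    gen = state.generator
    params = gen.parameters() if isinstance(gen, HyperGenerator) else gen.parameters()
    return {"g": [p.data.copy() for p in params]}


def _restore_params(state: TrainState, snap: dict) -> None:
    params = state.generator.parameters()
    for p, d in zip(params, snap["g"]):
        p.data[...] = d


def fit(config: TrainConfig, dataset: list[PairedStudy],
        val_dataset: list[PairedStudy] | None = None,
        callback=None) -> TrainState:
    """Train one variant on a list of paired studies.

    Sampling, initialisation, augmentation and dropout all derive from
    ``config.seed``; identical configs and datasets reproduce the loss
    trace bit-for-bit.  The state keeps the best-validation-L_ROI
    parameter snapshot when a validation set is supplied.
    """
    gen, disc = build_models(config)
    opt_g = ad.Adam(gen.parameters(), lr=config.lr_g, betas=config.betas)
    opt_d = ad.Adam(disc.parameters(), lr=config.lr_d, betas=config.betas)
    state = TrainState(config=config, generator=gen, discriminator=disc,
                       opt_g=opt_g, opt_d=opt_d,
                       rng=np.random.default_rng(config.seed))
    arrays = [_normalised_arrays(s) for s in dataset]
    val_arrays = [_normalised_arrays(s) for s in (val_dataset or [])]
    for i in range(config.steps):
        idx = int(state.rng.integers(0, len(arrays)))
        train_step(state, arrays[idx])
        if val_arrays and (i + 1) % config.val_every == 0:
            v = _validation_l_roi(state, val_arrays)
            if v < state.best_val:
                state.best_val = v
                state.best_params = _snapshot_params(state)
        if callback is not None:
            callback(state)
    if state.best_params is not None:
        _restore_params(state, state.best_params)
    return state


def log_to_csv(state: TrainState, path) -> None:
    import pandas as pd
    pd.DataFrame(state.log).to_csv(path, index=False)


# -- checkpointing -----------------------------------------------------------


def save_checkpoint(state: TrainState, path) -> None:
    """Full training snapshot: parameters, Adam moments, RNG state, step.

    Resuming from a checkpoint continues the run bit-for-bit.
    """
    import json

    arrays: dict[str, np.ndarray] = {}
    for tag, params in (("g", state.generator.parameters()),
                        ("d", state.discriminator.parameters())):
        for i, p in enumerate(params):
            arrays[f"{tag}{i}"] = p.data
    for tag, opt in (("og", state.opt_g), ("od", state.opt_d)):
        for i, (m, v) in enumerate(zip(opt._m, opt._v)):
            arrays[f"{tag}m{i}"] = m
            arrays[f"{tag}v{i}"] = v
    meta = {"config": state.config.to_dict(), "step": state.step,
            "opt_t": [state.opt_g.t, state.opt_d.t],
            "rng_state": state.rng.bit_generator.state,
            "best_val": None if not np.isfinite(state.best_val)
            else state.best_val}
    np.savez(path, _meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> TrainState:
    """Rebuild a TrainState ready to continue training."""
    import json

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["_meta"]))
        cfg_dict = meta["config"]
        cfg_dict["augmentation"] = AugmentationPolicy(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in cfg_dict["augmentation"].items()})
        config = TrainConfig(**cfg_dict)
        gen, disc = build_models(config)
        opt_g = ad.Adam(gen.parameters(), lr=config.lr_g, betas=config.betas)
        opt_d = ad.Adam(disc.parameters(), lr=config.lr_d, betas=config.betas)
        for tag, params in (("g", gen.parameters()), ("d", disc.parameters())):
            for i, p in enumerate(params):
                p.data[...] = z[f"{tag}{i}"]
        for tag, opt in (("og", opt_g), ("od", opt_d)):
            for i in range(len(opt.params)):
                opt._m[i][...] = z[f"{tag}m{i}"]
                opt._v[i][...] = z[f"{tag}v{i}"]
        opt_g.t, opt_d.t = meta["opt_t"]
        rng = np.random.default_rng()
        rng.bit_generator.state = meta["rng_state"]
        state = TrainState(config=config, generator=gen, discriminator=disc,
                           opt_g=opt_g, opt_d=opt_d, rng=rng,
                           step=int(meta["step"]))
        if meta["best_val"] is not None:
            state.best_val = meta["best_val"]
    return state


def resume(state: TrainState, dataset: list[PairedStudy], extra_steps: int,
           callback=None) -> TrainState:
    """Continue a (possibly reloaded) run for ``extra_steps`` more steps."""
    arrays = [_normalised_arrays(s) for s in dataset]
    for _ in range(extra_steps):
        idx = int(state.rng.integers(0, len(arrays)))
        train_step(state, arrays[idx])
        if callback is not None:
            callback(state)
    return state
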