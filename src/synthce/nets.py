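"""Phase-conditioned translation networks.

The generator is an encoder--decoder CNN with skip connections (U-Net
style): each encoder block is a single stride-2 convolution (channels
double per level, capped), each decoder block a transpose convolution
followed by a standard convolution after concatenation with the skip
feature map.  Instance normalisation (no learnable affine) follows every
convolution except the output layer; 50% dropout is applied to the first
three decoder blocks at training *and* inference, acting as the noise
source z.  The output passes through a sigmoid so predictions live in the
window-normalised intensity range (0, 1).

Conditioning on the normalised phase t is either by concatenating a
constant-t channel to the decoder feature maps and discriminator input
("concat"), by HyperNetwork-generated kernels (see :mod:`synthce.hyper`,
mode "hyper"/"none"), or absent.

The discriminator is a PatchGAN: a short stack of stride-2 convolutions
ending in a stride-1 convolution that emits a spatial map of patch logits
rather than a single scalar.  Convolutions carry no bias (instance
normalisation would cancel it) except the two un-normalised output layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class ShapeError(ValueError):
    """Input spatial shape incompatible with the network's stride stack."""


@dataclass(frozen=True)
class LayerDef:
    name: str
    kind: str           # "conv" | "tconv"
    in_ch: int
    out_ch: int
    stride: int
    kernel: int
    dims: int

    @property
    def kernel_shape(self) -> tuple[int, ...]:
        k = (self.kernel,) * self.dims
        if self.kind == "tconv":
            return (self.in_ch, self.out_ch) + k
        return (self.out_ch, self.in_ch) + k

    @property
    def n_elements(self) -> int:
        return int(np.prod(self.kernel_shape))


@dataclass
class GeneratorSpec:
    n_layers: int = 7
    base_channels: int = 32
    dims: int = 3
    dropout_rate: float = 0.5
    n_dropout_blocks: int = 3
    conditioning: str = "concat"      # "concat" | "hyper" | "none"
    max_channels: int = 512
    kernel: int = 3
    up_kernel: int = 4                # stride-2 transpose convs: even overlap
    norm_final_block: bool = True     # instance norm in the full-res decoder block
    condition_output: bool = True     # concat mode: t channel at the output conv
    output_bias_init: float = -1.5    # sigmoid^-1 of a typical soft-tissue level

    def __post_init__(self):
        if self.n_layers < 2:
            raise ValueError("generator needs at least 2 layers")
        if self.conditioning not in ("concat", "hyper", "none"):
            raise ValueError(f"unknown conditioning {self.conditioning!r}")

    def channels(self) -> list[int]:
        return [min(self.base_channels * 2 ** i, self.max_channels)
                for i in range(self.n_layers)]

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_layers", "base_channels", "dims", "dropout_rate",
            "n_dropout_blocks", "conditioning", "max_channels", "kernel",
            "up_kernel", "norm_final_block", "condition_output",
            "output_bias_init")}


@dataclass
class DiscriminatorSpec:
    n_layers: int = 3
    base_channels: int = 16
    dims: int = 3
    kernel: int = 4
    max_channels: int = 512


def condition_concat(features: Tensor, t: float) -> Tensor:
    """Append one channel filled with the constant t at the spatial shape."""
    tile = np.full((1,) + features.shape[1:], float(t))
    return ad.concat([features, Tensor(tile)], axis=0)


def _as_channel_array(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x[None] if x.ndim in (2, 3) and x.shape[0] != 1 else x


class Generator:
    """f_theta with forward(x, t) -> y_hat_t.  See module docstring."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        self.spec = spec
        self.layers: list[LayerDef] = []
        ch = spec.channels()
        L, d, k = spec.n_layers, spec.dims, spec.kernel
        t_extra = 1 if spec.conditioning == "concat" else 0
        self.layers.append(LayerDef("enc0", "conv", 1, ch[0], 1, k, d))
        for i in range(1, L):
            self.layers.append(LayerDef(f"enc{i}", "conv", ch[i - 1], ch[i], 2, k, d))
        for i in range(L - 1, 0, -1):
            self.layers.append(
                LayerDef(f"dec{i}_tc", "tconv", ch[i] + t_extra, ch[i - 1], 2,
                         spec.up_kernel, d))
            self.layers.append(
                LayerDef(f"dec{i}_conv", "conv", 2 * ch[i - 1], ch[i - 1], 1, k, d))
        out_extra = t_extra if spec.condition_output else 0
        self.layers.append(LayerDef("out", "conv", ch[0] + out_extra, 1, 1, k, d))
        self._by_name = {l.name: l for l in self.layers}

        rng = np.random.default_rng(seed)
        interior = set(self.interior_names)
        self.params: dict[str, Tensor] = {}
        for l in self.layers:
            if spec.conditioning == "hyper" and l.name in interior:
                continue  # supplied by the HyperNetwork at forward time
            fan_in = l.in_ch * l.kernel ** d
            self.params[l.name] = ad.he_normal(l.kernel_shape, fan_in, rng)
        self.params["out.bias"] = ad.parameter(
            np.full((1,) + (1,) * d, spec.output_bias_init))

    # ------------------------------------------------------------------

    @property
    def interior_names(self) -> list[str]:
        """Every convolution except the first and last layer."""
        return [l.name for l in self.layers if l.name not in ("enc0", "out")]

    def layer_def(self, name: str) -> LayerDef:
        return self._by_name[name]

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def check_input(self, spatial: tuple[int, ...]) -> None:
        factor = 2 ** (self.spec.n_layers - 1)
        if any(s % factor or s < factor for s in spatial):
            raise ShapeError(
                f"spatial shape {spatial} not divisible by 2^(n_layers-1) = {factor}")

    def forward(self, x, t: float | None = None,
                rng: np.random.Generator | int | None = None,
                params: dict[str, Tensor] | None = None,
                dropout: bool = True) -> Tensor:
        """One generator pass.  ``params`` overrides stored kernels by layer
        name (used by the HyperNetwork variant); ``rng`` seeds the dropout
        noise z for reproducible inference."""
        spec = self.spec
        if spec.conditioning == "concat" and t is None:
            raise ValueError("concat conditioning requires a phase t")
        p = dict(self.params)
        if params:
            p.update(params)
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

        h = x if isinstance(x, Tensor) else Tensor(_as_channel_array(x))
        self.check_input(h.shape[1:])
        pad = spec.kernel // 2
        uk = spec.up_kernel
        up_pad = uk // 2 - 1 if uk % 2 == 0 else uk // 2
        skips = []
        for i in range(spec.n_layers):
            name = f"enc{i}" if i else "enc0"
            stride = 2 if i else 1
            h = ad.conv_nd(h, p[name], stride=stride, pad=pad)
            h = ad.leaky_relu(ad.instance_norm(h), 0.2)
            if i < spec.n_layers - 1:
                skips.append(h)
        n_drop = spec.n_dropout_blocks
        for j, i in enumerate(range(spec.n_layers - 1, 0, -1)):
            if spec.conditioning == "concat":
                h = condition_concat(h, t)
            h = ad.conv_transpose_nd(h, p[f"dec{i}_tc"], stride=2, pad=up_pad)
            # ReLU before the skip-concat convolution, with no normalisation in
            # between: a constant conditioning shift would otherwise be removed
            # exactly by the next instance norm, which has no learnable affine.
            h = ad.relu(h)
            h = ad.concat([h, skips[i - 1]], axis=0)
            h = ad.conv_nd(h, p[f"dec{i}_conv"], stride=1, pad=pad)
            if i > 1 or spec.norm_final_block:
                h = ad.instance_norm(h)
            h = ad.relu(h)
            if dropout and spec.dropout_rate > 0 and j < n_drop:
                h = ad.dropout(h, spec.dropout_rate, rng)
        if spec.conditioning == "concat" and spec.condition_output:
            h = condition_concat(h, t)
        h = ad.conv_nd(h, p["out"], stride=1, pad=pad) + p["out.bias"]
        return ad.sigmoid(h)

    __call__ = forward


class Discriminator:
    """PatchGAN g_phi with forward(y, t) -> spatial patch-logit map."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0,
                 condition_at_input: bool = True):
        self.spec = spec
        self.condition_at_input = condition_at_input
        d, k = spec.dims, spec.kernel
        ch = [min(spec.base_channels * 2 ** i, spec.max_channels)
              for i in range(spec.n_layers)]
        in0 = 1 + (1 if condition_at_input else 0)
        self.layers = [LayerDef("d0", "conv", in0, ch[0], 2, k, d)]
        for i in range(1, spec.n_layers):
            extra = 1 if (not condition_at_input and i == 1) else 0
            self.layers.append(
                LayerDef(f"d{i}", "conv", ch[i - 1] + extra, ch[i], 2, k, d))
        self.layers.append(LayerDef("final", "conv", ch[-1], 1, 1, k, d))

        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        for l in self.layers:
            fan_in = l.in_ch * l.kernel ** d
            self.params[l.name] = ad.he_normal(l.kernel_shape, fan_in, rng)
        self.params["final.bias"] = ad.parameter(np.zeros((1,) + (1,) * d))

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def forward(self, y, t: float) -> Tensor:
        spec = self.spec
        h = y if isinstance(y, Tensor) else Tensor(_as_channel_array(y))
        factor = 2 ** spec.n_layers
        if any(s % factor for s in h.shape[1:]):
            raise ShapeError(
                f"spatial shape {h.shape[1:]} not divisible by 2^n_layers = {factor}")
        if self.condition_at_input:
            h = condition_concat(h, t)
        pad = spec.kernel // 2 - 1 if spec.kernel % 2 == 0 else spec.kernel // 2
        for i in range(spec.n_layers):
            h = ad.conv_nd(h, self.params[f"d{i}" if i else "d0"], stride=2, pad=pad)
            if i > 0:
                h = ad.instance_norm(h)
            h = ad.leaky_relu(h, 0.2)
            if not self.condition_at_input and i == 0:
                h = condition_concat(h, t)  # intermediate-feature conditioning
        h = ad.conv_nd(h, self.params["final"], stride=1,
                       pad=(spec.kernel - 1) // 2)
        return h + self.params["final.bias"]

    __call__ = forward


def build_generator(spec: GeneratorSpec, seed: int = 0) -> Generator:
    return Generator(spec, seed=seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> Discriminator:
    return Discriminator(spec, seed=seed)
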