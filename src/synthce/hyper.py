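"""HyperNetwork conditioning: phase-dependent convolutional kernels.

Instead of concatenating the normalised phase t to feature maps, this
variant lets a small two-layer *linear* network emit the generator's
convolutional kernels as a function of t.  Learnt embedding vectors are
scaled elementwise by t and pushed through the shared dense layers

    K(t) = reshape( W2 (W1 (t h) + b1) + b2 ),

so every generated kernel -- and hence the whole parameter set theta(t) --
is exactly affine in t:

    theta(t) = (2 - t) * theta(1) + (t - 1) * theta(2).

Kernel interpolation between the two trained phases is therefore the
mechanism by which intermediate contrast phases are synthesised.

Kernels are generated for every interior layer of the generator; the first
and last layers (and the discriminator) are trained directly.  Each
interior kernel is flattened and split into fixed-size chunks with one
embedding per chunk and a single shared trunk/head, which keeps the
HyperNetwork's trainable parameter count well below the kernel count it
replaces.  Setting ``chunk_size=None`` instead gives one embedding and one
dedicated output head per layer (only sensible for small architectures,
since a dedicated head always carries more parameters than its kernel).
An optional ReLU between the two dense layers is available for sensitivity
analysis; it breaks the affine property and is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nets import Generator, GeneratorSpec


class PhaseRangeError(ValueError):
    """Normalised time outside the trained range [1, 2]."""


@dataclass
class HyperNetSpec:
    embed_dim: int = 64
    hidden_width: int = 128
    chunk_size: int | None = 3456
    nonlinearity: str | None = None   # None = linear (affine in t); "relu"

    def __post_init__(self):
        if self.nonlinearity not in (None, "relu"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")


@dataclass(frozen=True)
class _LayerEntry:
    name: str
    kernel_shape: tuple[int, ...]
    n_elements: int
    row_start: int   # first embedding row owned by this layer
    row_stop: int


@dataclass
class HyperEmbeddingBank:
    """Learnt embeddings plus the registry mapping layers to kernel shapes."""

    spec: HyperNetSpec
    registry: list[_LayerEntry]
    embeddings: Tensor      # (n_rows, embed_dim), one row per chunk (or layer)

    @property
    def n_rows(self) -> int:
        return self.embeddings.shape[0]

    def entry(self, name: str) -> _LayerEntry:
        for e in self.registry:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass
class ParamSet:
    """Materialised generator kernels, keyed by layer name."""

    kernels: dict[str, Tensor]
    t: float | None = None

    def as_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.kernels.items()}

    def save(self, path) -> None:
        np.savez(path, **{k: v.data for k, v in self.kernels.items()},
                 _t=np.asarray(self.t if self.t is not None else np.nan))

    @classmethod
    def load(cls, path) -> "ParamSet":
        with np.load(path) as z:
            t = float(z["_t"])
            kernels = {k: Tensor(z[k]) for k in z.files if k != "_t"}
        return cls(kernels=kernels, t=None if math.isnan(t) else t)


def init_bank(generator: Generator, spec: HyperNetSpec | None = None,
              seed: int = 0) -> HyperEmbeddingBank:
    """Create seeded embeddings for every interior layer of ``generator``.

    Embedding rows are scaled per layer so that generated kernels start out
    near He magnitude at the phase midpoint t = 1.5.
    """
    spec = spec or HyperNetSpec()
    rng = np.random.default_rng(seed)
    registry: list[_LayerEntry] = []
    rows = []
    row = 0
    for name in generator.interior_names:
        ldef = generator.layer_def(name)
        n_el = ldef.n_elements
        chunk = spec.chunk_size or n_el
        n_chunks = -(-n_el // chunk)
        fan_in = ldef.in_ch * ldef.kernel ** ldef.dims
        scale = math.sqrt(2.0 / fan_in) / 1.5
        rows.append(rng.normal(0.0, scale, size=(n_chunks, spec.embed_dim)))
        registry.append(_LayerEntry(name, ldef.kernel_shape, n_el, row, row + n_chunks))
        row += n_chunks
    return HyperEmbeddingBank(spec=spec, registry=registry,
                              embeddings=ad.parameter(np.concatenate(rows, axis=0)))


class HyperNetwork:
    """Two dense layers with bias and (by default) no intermediate
    non-linearity, shared across all generated chunks."""

    def __init__(self, bank: HyperEmbeddingBank, seed: int = 0):
        spec = bank.spec
        rng = np.random.default_rng(seed + 1)
        d, h = spec.embed_dim, spec.hidden_width
        self.spec = spec
        self.W1 = ad.parameter(rng.normal(0.0, 1.0 / math.sqrt(d), size=(d, h)))
        self.b1 = ad.parameter(np.zeros(h))
        if spec.chunk_size is None:
            self.W2 = {
                e.name: ad.parameter(
                    rng.normal(0.0, 1.0 / math.sqrt(h), size=(h, e.n_elements)))
                for e in bank.registry
            }
            self.b2 = {e.name: ad.parameter(np.zeros(e.n_elements))
                       for e in bank.registry}
        else:
            self.W2 = ad.parameter(
                rng.normal(0.0, 1.0 / math.sqrt(h), size=(h, spec.chunk_size)))
            self.b2 = ad.parameter(np.zeros(spec.chunk_size))

    def parameters(self) -> list[Tensor]:
        out = [self.W1, self.b1]
        if isinstance(self.W2, dict):
            out += list(self.W2.values()) + list(self.b2.values())
        else:
            out += [self.W2, self.b2]
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def generate_kernels(bank: HyperEmbeddingBank, hypernet: HyperNetwork,
                     t: float, warn_only: bool = False) -> ParamSet:
    """Materialise theta(t): K_i(t) = reshape(W2 (W1 (t h_i) + b1) + b2)."""
    if not 1.0 <= t <= 2.0:
        if not warn_only:
            raise PhaseRangeError(f"normalised time {t} outside [1, 2]")
        import warnings
        warnings.warn(f"extrapolating kernels at t = {t} outside [1, 2]")
    spec = bank.spec
    hidden = ad.matmul(ad.mul(bank.embeddings, float(t)), hypernet.W1) + hypernet.b1
    if spec.nonlinearity == "relu":
        hidden = ad.relu(hidden)
    kernels: dict[str, Tensor] = {}
    for e in bank.registry:
        rows = hidden[e.row_start:e.row_stop]
        if isinstance(hypernet.W2, dict):
            flat = ad.matmul(rows, hypernet.W2[e.name]) + hypernet.b2[e.name]
            flat = ad.reshape(flat, (-1,))
        else:
            flat = ad.matmul(rows, hypernet.W2) + hypernet.b2
            flat = ad.reshape(flat, (-1,))[: e.n_elements]
        kernels[e.name] = ad.reshape(flat, e.kernel_shape)
    return ParamSet(kernels=kernels, t=t)


class MaterializedGenerator:
    """A generator bound to a fixed parameter set theta(t)."""

    def __init__(self, base: Generator, paramset: ParamSet):
        for name, k in paramset.kernels.items():
            want = base.layer_def(name).kernel_shape
            if tuple(k.shape) != want:
                raise ValueError(
                    f"kernel shape mismatch for layer {name}: "
                    f"got {tuple(k.shape)}, expected {want}")
        self.base = base
        self.paramset = paramset

    def forward(self, x, rng=None, dropout: bool = True) -> Tensor:
        return self.base.forward(x, t=None, rng=rng,
                                 params=self.paramset.kernels, dropout=dropout)

    __call__ = forward


def materialize_generator(base: Generator, paramset: ParamSet) -> MaterializedGenerator:
    return MaterializedGenerator(base, paramset)


class HyperGenerator:
    """Bundles the base generator (first/last layers trained directly), the
    embedding bank and the HyperNetwork into one forward(x, t) model."""

    def __init__(self, gen_spec: GeneratorSpec | None = None,
                 hyper_spec: HyperNetSpec | None = None, seed: int = 0):
        gen_spec = gen_spec or GeneratorSpec(conditioning="hyper")
        if gen_spec.conditioning == "concat":
            raise ValueError("HyperGenerator requires conditioning 'hyper'")
        self.base = Generator(gen_spec, seed=seed)
        self.bank = init_bank(self.base, hyper_spec, seed=seed)
        self.hypernet = HyperNetwork(self.bank, seed=seed)
        self.spec = gen_spec

    def kernels_at(self, t: float, warn_only: bool = False) -> ParamSet:
        return generate_kernels(self.bank, self.hypernet, t, warn_only=warn_only)

    def forward(self, x, t: float, rng=None, dropout: bool = True,
                paramset: ParamSet | None = None) -> Tensor:
        ps = paramset or self.kernels_at(t)
        return self.base.forward(x, t=None, rng=rng, params=ps.kernels,
                                 dropout=dropout)

    __call__ = forward

    def parameters(self) -> list[Tensor]:
        direct = [self.base.params["enc0"], self.base.params["out"],
                  self.base.params["out.bias"]]
        return direct + [self.bank.embeddings] + self.hypernet.parameters()

    def n_trainable_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def interior_kernel_count(self) -> int:
        return sum(self.base.layer_def(n).n_elements
                   for n in self.base.interior_names)
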