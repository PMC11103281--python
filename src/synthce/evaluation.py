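"""Quantitative evaluation protocol.

Image quality is summarised by MSE, peak signal-to-noise ratio and SSIM,
globally and restricted to the foreground regions.  Intensities are
windowed HU re-quantised onto a 16-bit scale, so the pSNR peak defaults to
65535 -- the value that reconciles MSE/pSNR pairs under
pSNR = 10 log10(peak^2 / MSE).  Because that map is strictly decreasing,
the median pSNR over any record set equals the pSNR of the median MSE.

Agreement between predicted and reference ROI intensities uses
Bland-Altman analysis on per-subject means: the difference DI is plotted
against the pairwise mean I-bar; the bias is the mean difference with 95%
limits of agreement at +/- 1.96 SD(DI); regression of DI on I-bar
separates a constant bias (significant intercept, non-significant slope)
from a proportional one (significant slope).  Model biases are compared by
ANCOVA with interaction -- slope equality is tested first, then adjusted
mean biases with Bonferroni-corrected pairwise contrasts.  Non-normal
confidence intervals come from the non-parametric percentile bootstrap.

The downstream task is 2D tumour segmentation from synthesised images
across a sweep of contrast phases, scored by the Dice coefficient.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

from . import autodiff as ad
from .autodiff import Tensor
from .nets import Generator, GeneratorSpec
from .volio import WINDOW_HU, WINDOW_WIDTH, Volume

DEFAULT_PEAK = 65535.0


def hu_to_uint16_scale(data: np.ndarray) -> np.ndarray:
    """Map windowed HU onto the 16-bit dynamic range [0, 65535]."""
    lo, hi = WINDOW_HU
    return (np.clip(data, lo, hi) - lo) / WINDOW_WIDTH * DEFAULT_PEAK


def psnr_from_mse(mse: float, peak: float = DEFAULT_PEAK) -> float:
    """pSNR = 10 log10(peak^2 / MSE); +inf for identical images."""
    if mse < 0:
        raise ValueError("MSE must be non-negative")
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(peak ** 2 / mse)


@dataclass
class MetricRecord:
    subject: str
    model: str
    phase: float
    scope: str        # "global" | "foreground"
    mse: float
    psnr: float
    ssim: float


def image_metrics(pred: Volume, truth: Volume, mask: np.ndarray | None = None,
                  peak: float = DEFAULT_PEAK, subject: str = "",
                  model: str = "", phase: float = np.nan) -> MetricRecord:
    """MSE / pSNR / SSIM on the 16-bit intensity scale.

    With a mask, MSE is taken over masked voxels only and SSIM is the mean
    of the SSIM map over the mask (standard 11-wide Gaussian window).
    """
    if pred.data.shape != truth.data.shape:
        raise ValueError("prediction and truth shapes differ")
    p = hu_to_uint16_scale(pred.data if pred.units == "HU"
                           else pred.data * WINDOW_WIDTH + WINDOW_HU[0])
    q = hu_to_uint16_scale(truth.data if truth.units == "HU"
                           else truth.data * WINDOW_WIDTH + WINDOW_HU[0])
    err = (p - q) ** 2
    scope = "global" if mask is None else "foreground"
    mse = float(err.mean() if mask is None else err[mask].mean())
    mean_ssim, ssim_map = structural_similarity(
        q, p, data_range=peak, gaussian_weights=True, full=True)
    ssim = float(mean_ssim if mask is None else ssim_map[mask].mean())
    return MetricRecord(subject=subject, model=model, phase=phase, scope=scope,
                        mse=mse, psnr=psnr_from_mse(mse, peak), ssim=ssim)


def select_slices(mask: np.ndarray, n_slices: int = 5) -> np.ndarray:
    """Indices of ``n_slices`` equally spaced axial slices spanning the
    ROI's axial extent (all available slices, with a warning, if fewer)."""
    axial = mask.any(axis=tuple(range(mask.ndim - 1)))
    zs = np.flatnonzero(axial)
    if zs.size == 0:
        raise ValueError("empty ROI mask")
    if zs.size < n_slices:
        warnings.warn(f"ROI spans only {zs.size} slices; using all")
        return zs
    return np.unique(np.round(np.linspace(zs[0], zs[-1], n_slices)).astype(int))


def roi_intensity_table(pred: Volume, masks, n_slices: int = 5) -> dict[str, float | None]:
    """Per-ROI mean HU over ``n_slices`` equally spaced slices.

    ``masks`` is a mapping roi name -> boolean array (2D masks are averaged
    whole).  An empty ROI is recorded as absent (None).
    """
    rois = masks.rois() if hasattr(masks, "rois") else dict(masks)
    out: dict[str, float | None] = {}
    for name, mask in rois.items():
        if mask is None or not mask.any():
            out[name] = None
            continue
        if mask.ndim == 2:
            out[name] = float(pred.data[mask].mean())
            continue
        zs = select_slices(mask, n_slices)
        sub_mask = np.zeros_like(mask)
        sub_mask[..., zs] = mask[..., zs]
        out[name] = float(pred.data[sub_mask].mean())
    return out


# -- Bland-Altman / ANCOVA ---------------------------------------------------


@dataclass
class BlandAltmanFit:
    n: int
    bias: float                  # mean difference
    loa: tuple[float, float]     # bias +/- 1.96 SD(DI)
    intercept: float
    slope: float
    p_intercept: float
    p_slope: float
    bias_type: str               # "constant" | "proportional" | "none"
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


def bland_altman(pred_means, truth_means, alpha: float = 0.05) -> BlandAltmanFit:
    """Agreement between paired per-subject means (prediction vs reference)."""
    import statsmodels.api as sm

    pred = np.asarray(pred_means, dtype=float)
    truth = np.asarray(truth_means, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("paired 1D inputs required")
    if pred.size < 3:
        raise ValueError("at least 3 pairs required for bias regression")
    diffs = pred - truth
    means = (pred + truth) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    fit = sm.OLS(diffs, sm.add_constant(means)).fit()
    if np.isnan(fit.pvalues).all() and np.allclose(diffs, diffs[0]):
        # degenerate: exactly constant differences
        intercept, slope = float(diffs[0]), 0.0
        p_int, p_slope = (0.0 if diffs[0] != 0 else 1.0), 1.0
    else:
        intercept, slope = (float(v) for v in fit.params)
        p_int, p_slope = (float(v) for v in fit.pvalues)
    if p_slope < alpha:
        bias_type = "proportional"
    elif p_int < alpha:
        bias_type = "constant"
    else:
        bias_type = "none"
    return BlandAltmanFit(n=pred.size, bias=bias,
                          loa=(bias - 1.96 * sd, bias + 1.96 * sd),
                          intercept=intercept, slope=slope,
                          p_intercept=p_int, p_slope=p_slope,
                          bias_type=bias_type, means=means, diffs=diffs)


@dataclass
class AncovaResult:
    p_interaction: float
    p_group: float | None
    adjusted_means: dict[str, float] | None
    contrasts: dict[tuple[str, str], float] | None   # Bonferroni-adjusted
    alpha: float = 0.05


def ancova_compare(fits: dict[str, BlandAltmanFit],
                   alpha: float = 0.05) -> AncovaResult:
    """Compare model biases controlling for mean intensity as covariate.

    The model-by-covariate interaction (slope equality) is tested first;
    adjusted means and Bonferroni-corrected pairwise contrasts are only
    computed when it is non-significant.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    if len(fits) < 2:
        raise ValueError("need at least two models")
    frames = [pd.DataFrame({"diff": f.diffs, "mean": f.means, "model": name})
              for name, f in fits.items()]
    data = pd.concat(frames, ignore_index=True)
    full = smf.ols("diff ~ mean * C(model)", data=data).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise np.linalg.LinAlgError("singular ANCOVA design")
    tbl = anova_lm(full, typ=2)
    p_inter = float(tbl.loc["mean:C(model)", "PR(>F)"])
    if p_inter < alpha:
        return AncovaResult(p_interaction=p_inter, p_group=None,
                            adjusted_means=None, contrasts=None, alpha=alpha)
    add = smf.ols("diff ~ mean + C(model)", data=data).fit()
    tbl2 = anova_lm(add, typ=2)
    p_group = float(tbl2.loc["C(model)", "PR(>F)"])
    grand = float(data["mean"].mean())
    names = list(fits)
    adjusted = {
        name: float(add.predict(pd.DataFrame({"mean": [grand], "model": [name]})).iloc[0])
        for name in names
    }
    pairs = list(itertools.combinations(names, 2))
    contrasts: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        la = _design_row(add, grand, a)
        lb = _design_row(add, grand, b)
        p = float(add.t_test(la - lb).pvalue)
        contrasts[(a, b)] = min(1.0, p * len(pairs))
    return AncovaResult(p_interaction=p_inter, p_group=p_group,
                        adjusted_means=adjusted, contrasts=contrasts, alpha=alpha)


def _design_row(fit, covariate_value: float, model_name: str) -> np.ndarray:
    import patsy

    (row,) = np.asarray(patsy.dmatrix(
        fit.model.data.design_info,
        pd.DataFrame({"mean": [covariate_value], "model": [model_name]})))
    return row


# -- bootstrap and hypothesis tests ------------------------------------------


def bootstrap_ci(samples, statistic=np.median, runs: int = 100_000,
                 seed: int | None = None, alpha: float = 0.05,
                 block: int = 20_000) -> tuple[float, float]:
    """Seeded non-parametric percentile bootstrap interval."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    out = np.empty(runs)
    done = 0
    while done < runs:
        b = min(block, runs - done)
        idx = rng.integers(0, x.size, size=(b, x.size))
        out[done:done + b] = statistic(x[idx], axis=1)
        done += b
    # outer order statistics: conservative for the discrete bootstrap
    # distribution of rank-based statistics such as the median
    lo = np.percentile(out, 100 * alpha / 2, method="lower")
    hi = np.percentile(out, 100 * (1 - alpha / 2), method="higher")
    return float(lo), float(hi)


def bonferroni(p_values, m: int | None = None):
    """Multiply by the family size and cap at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if m is None else m
    return np.minimum(1.0, p * m)


def compare_models(groups: dict[str, np.ndarray], test: str = "u",
                   family_size: int | None = None) -> dict:
    """Pairwise (t / Mann-Whitney U) or omnibus (Kruskal-Wallis H) tests
    with Bonferroni adjustment over the reported family."""
    names = list(groups)
    for n in names:
        if len(groups[n]) < 2:
            raise ValueError(f"group {n!r} has fewer than 2 samples")
    if test == "h":
        stat, p = stats.kruskal(*[groups[n] for n in names])
        return {"omnibus": float(bonferroni([p], family_size or 1)[0])}
    pairs = list(itertools.combinations(names, 2))
    m = family_size or len(pairs)
    out = {}
    for a, b in pairs:
        if test == "u":
            p = stats.mannwhitneyu(groups[a], groups[b],
                                   alternative="two-sided").pvalue
        elif test == "t":
            p = stats.ttest_ind(groups[a], groups[b]).pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
        out[(a, b)] = float(bonferroni([p], m)[0])
    return out


def metrics_table(records: list[MetricRecord]) -> pd.DataFrame:
    """Tidy long-format table of metric records (one row per
    subject/model/phase/scope), ready for per-cell medians or CSV export."""
    from dataclasses import asdict

    return pd.DataFrame([asdict(r) for r in records])


def summarise_metrics(records: list[MetricRecord],
                      ci_runs: int = 100_000, seed: int | None = None
                      ) -> pd.DataFrame:
    """Median and bootstrap 95% CI per model/phase/scope/metric."""
    df = metrics_table(records)
    rows = []
    for (model, phase, scope), grp in df.groupby(["model", "phase", "scope"]):
        for metric in ("mse", "psnr", "ssim"):
            vals = grp[metric].to_numpy()
            med = float(np.median(vals))
            if np.isfinite(vals).all() and vals.size >= 2:
                lo, hi = bootstrap_ci(vals, runs=ci_runs, seed=seed)
            else:
                lo = hi = med
            rows.append({"model": model, "phase": phase, "scope": scope,
                         "metric": metric, "median": med,
                         "ci_low": lo, "ci_high": hi, "n": vals.size})
    return pd.DataFrame(rows)


def plot_bland_altman(fit: BlandAltmanFit, ax=None, title: str = ""):
    """Difference-vs-mean plot with bias and limits of agreement.

    Requires matplotlib (the ``plot`` extra); returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(fit.means, fit.diffs, s=18, alpha=0.8)
    ax.axhline(fit.bias, color="k", lw=1, label=f"bias {fit.bias:.1f}")
    for v in fit.loa:
        ax.axhline(v, color="k", lw=1, ls="--")
    xs = np.linspace(fit.means.min(), fit.means.max(), 2)
    ax.plot(xs, fit.intercept + fit.slope * xs, color="C1", lw=1,
            label=f"slope {fit.slope:.2f} ({fit.bias_type})")
    ax.set_xlabel("mean intensity (HU)")
    ax.set_ylabel("difference (HU)")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax


# -- downstream segmentation -------------------------------------------------


def dice(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """2|A n B| / (|A| + |B|); defined as 1 when both masks are empty."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(truth_mask, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


@dataclass
class DiceRecord:
    model: str
    phase_seconds: float
    median_dice: float

    def __post_init__(self):
        if not 0.0 <= self.median_dice <= 1.0:
            raise ValueError("Dice outside [0, 1]")


@dataclass
class SegmenterConfig:
    n_layers: int = 3
    base_channels: int = 8
    steps: int = 150
    batch: int = 8
    lr: float = 1e-3
    seed: int = 0


def train_downstream_seg(patches: list[tuple[np.ndarray, np.ndarray]],
                         config: SegmenterConfig | None = None) -> Generator:
    """Train a small 2D encoder--decoder segmenter on (image, mask) patches.

    Images are window-normalised 2D arrays; masks are binary.  Binary
    cross-entropy on the sigmoid output, Adam optimiser.
    """
    config = config or SegmenterConfig()
    spec = GeneratorSpec(n_layers=config.n_layers,
                         base_channels=config.base_channels, dims=2,
                         dropout_rate=0.0, conditioning="none")
    model = Generator(spec, seed=config.seed)
    opt = ad.Adam(model.parameters(), lr=config.lr, betas=(0.9, 0.999))
    rng = np.random.default_rng(config.seed)
    eps = 1e-7
    for _ in range(config.steps):
        idxs = rng.integers(0, len(patches), size=config.batch)
        total = None
        for i in idxs:
            img, msk = patches[i]
            p = model.forward(img, t=None, dropout=False)
            y = np.asarray(msk, dtype=float)[None]
            term = ad.log(p * (1 - 2 * eps) + eps) * Tensor(y) \
                + ad.log((1.0 - p) * (1 - 2 * eps) + eps) * Tensor(1.0 - y)
            bce = -1.0 / config.batch * term.mean()
            total = bce if total is None else total + bce
        total.backward()
        opt.step()
        opt.zero_grad()
    return model


def predict_mask(model: Generator, image: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    with ad.no_grad():
        p = model.forward(image, t=None, dropout=False)
    return p.data[0] > threshold
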