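"""Grayscale preprocessing and segmentation for brain-style images.

The chain sharpens the image with a frequency-domain high-pass filter,
brightens and denoises it (additive enhancement + median filter),
segments candidate lesion tissue with two complementary rules — a fixed
intensity band grown into connected regions, and thresholds derived
from a Gaussian-mixture fit of the histogram — cleans the mask by
morphological opening, and finally subtracts the non-lesion content
from the source so that only the segmented structure remains.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage, optimize

__all__ = [
    "HighPassSpec",
    "GaussianMixture1D",
    "RegionGrowSpec",
    "StructuringElement",
    "PipelineConfig",
    "PipelineResult",
    "highpass_transfer",
    "filter_frequency",
    "median_filter",
    "enhance",
    "region_grow",
    "fit_gmm",
    "fit_gaussian_mixture",
    "optimal_thresholds",
    "opening",
    "subtract",
    "preprocess_pipeline",
    "read_gray",
    "write_gray",
    "dice",
]


@dataclass(frozen=True)
class HighPassSpec:
    """Frequency-domain high-pass transfer function.

    ``kind`` is one of ideal, butterworth, exponential; ``cutoff`` is in
    (centered) frequency-grid units.  ``scale_c`` defaults to 1 with
    sqrt(2)-1 as the standard half-power alternative; ``scale_a``
    defaults to 1 with ln 2 as the alternative.
    """

    kind: str = "butterworth"
    cutoff: float = 30.0
    order: int = 2
    scale_c: float = 1.0
    scale_a: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("ideal", "butterworth", "exponential"):
            raise ValueError(f"unknown high-pass kind {self.kind!r}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass(frozen=True)
class GaussianMixture1D:
    """A d-mode Gaussian mixture over gray levels, means sorted ascending."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        var = np.asarray(self.variances, dtype=float)
        if not (len(w) == len(mu) == len(var)):
            raise ValueError("component count mismatch")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")
        if np.any(var <= 0):
            raise ValueError("variances must be positive")
        if np.any(np.diff(mu) < 0):
            raise ValueError("means must be sorted ascending")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "variances", var)

    @property
    def d(self) -> int:
        return len(self.weights)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        comp = np.exp(-((x - self.means) ** 2) / (2 * self.variances)) / np.sqrt(
            2 * np.pi * self.variances
        )
        return (self.weights * comp).sum(axis=-1)


@dataclass(frozen=True)
class RegionGrowSpec:
    """Strict intensity band (seed_value, threshold) grown into regions."""

    seed_value: float = 80.0
    threshold: float = 90.0
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.seed_value >= self.threshold:
            raise ValueError("seed_value must be below threshold")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class StructuringElement:
    """Binary mask for morphological operations (default 6x6 square)."""

    mask: np.ndarray = field(default_factory=lambda: np.ones((6, 6), dtype=bool))

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.size == 0 or not m.any():
            raise ValueError("structuring element must be nonempty")
        object.__setattr__(self, "mask", m)


# ---------------------------------------------------------------------------
# frequency-domain filtering


def highpass_transfer(spec: HighPassSpec, height: int, width: int) -> np.ndarray:
    """Centered transfer-function grid in [0, 1].

    The ideal filter is 0 at radii <= cutoff and 1 beyond; Butterworth
    and exponential filters are 0 exactly at the DC bin and approach 1
    at high radii.
    """
    u = np.arange(height) - height // 2
    v = np.arange(width) - width // 2
    radius = np.sqrt(u[:, None] ** 2 + v[None, :] ** 2)
    if spec.kind == "ideal":
        return (radius > spec.cutoff).astype(float)
    out = np.zeros((height, width))
    nonzero = radius > 0
    r = radius[nonzero]
    if spec.kind == "butterworth":
        out[nonzero] = 1.0 / (1.0 + (spec.scale_c * spec.cutoff / r) ** (2 * spec.order))
    else:  # exponential
        out[nonzero] = np.exp(-spec.scale_a * (spec.cutoff / r) ** spec.order)
    return out


def filter_frequency(img: np.ndarray, spec: HighPassSpec) -> np.ndarray:
    """High-pass filter via the 2-D Fourier transform.

    Returns the real part of the inverse transform of the product;
    values are left unclamped because downstream stages consume signed
    detail.
    """
    img = np.asarray(img, dtype=float)
    transfer = highpass_transfer(spec, *img.shape)
    spectrum = np.fft.fft2(img) * np.fft.ifftshift(transfer)
    return np.real(np.fft.ifft2(spectrum))


def median_filter(img: np.ndarray, k: int = 3) -> np.ndarray:
    """k x k median with edge-replicated borders."""
    if k < 1 or k % 2 == 0:
        raise ValueError("median window must be odd and positive")
    return ndimage.median_filter(np.asarray(img, dtype=float), size=k, mode="nearest")


def enhance(src: np.ndarray, hp: np.ndarray, c: float = 25.0) -> np.ndarray:
    """Additive brightness enhancement: src + high-pass detail + c, clamped."""
    src = np.asarray(src, dtype=float)
    hp = np.asarray(hp, dtype=float)
    if src.shape != hp.shape:
        raise ValueError("shape mismatch")
    return np.clip(src + hp + c, 0.0, 255.0)


# ---------------------------------------------------------------------------
# segmentation


def _connectivity_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def region_grow(img: np.ndarray, spec: RegionGrowSpec) -> np.ndarray:
    """Union of connected components of the strict intensity band.

    Growing a region from every unclaimed in-band seed until no seeds
    remain is equivalent to connected-component labeling of the band,
    which is how the loop is realized here.
    """
    img = np.asarray(img, dtype=float)
    band = (img > spec.seed_value) & (img < spec.threshold)
    labels, n = ndimage.label(band, structure=_connectivity_structure(spec.connectivity))
    return labels > 0


def _em_run(
    x: np.ndarray,
    w: np.ndarray,
    means0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    d = len(means0)
    total = w.sum()
    means = means0.astype(float).copy()
    overall_var = max(
        float(np.average((x - np.average(x, weights=w)) ** 2, weights=w)), 1e-6
    )
    variances = np.full(d, overall_var / max(d, 1))
    mix = np.full(d, 1.0 / d)
    prev_ll = -np.inf
    ll = -np.inf
    floored = False
    for _ in range(max_iter):
        comp = mix * np.exp(
            -((x[:, None] - means) ** 2) / (2 * variances)
        ) / np.sqrt(2 * np.pi * variances)
        dens = np.maximum(comp.sum(axis=1), 1e-300)
        ll = float(np.sum(w * np.log(dens)) / total)
        resp = comp / dens[:, None]
        wk = (w[:, None] * resp).sum(axis=0)
        mix = wk / total
        means = (w[:, None] * resp * x[:, None]).sum(axis=0) / np.maximum(wk, 1e-300)
        variances = (w[:, None] * resp * (x[:, None] - means) ** 2).sum(
            axis=0
        ) / np.maximum(wk, 1e-300)
        if np.any(variances < 1e-6):
            floored = True
            variances = np.maximum(variances, 1e-6)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return mix, means, variances, ll, floored


def fit_gmm(
    samples: np.ndarray,
    d: int = 2,
    weights: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> GaussianMixture1D:
    """Expectation-maximization fit of a 1-D Gaussian mixture.

    ``samples`` may carry ``weights`` (e.g. histogram counts), in which
    case the fit is over the weighted empirical distribution.  EM is
    run from two deterministic starts — means at the d mass quantiles,
    and means spread evenly over the value range (which can find
    low-weight modes, such as a small bright lesion, that quantile
    initialization misses) — and the higher-likelihood fit is kept.
    Iteration stops when the mean log-likelihood changes by < ``tol``.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        keep = w > 0
        x, w = x[keep], w[keep]
    if len(np.unique(x)) < d:
        raise ValueError("need at least d distinct sample values")
    total = w.sum()
    q = (np.arange(d) + 0.5) / d
    order = np.argsort(x)
    cdf = np.cumsum(w[order]) / total
    quantile_means = x[order][np.searchsorted(cdf, q).clip(0, len(x) - 1)]
    range_means = np.linspace(x.min(), x.max(), d + 2)[1:-1]
    best = None
    floored_any = False
    for means0 in (quantile_means, range_means):
        mix, means, variances, ll, floored = _em_run(x, w, means0, max_iter, tol)
        floored_any = floored_any or floored
        if best is None or ll > best[3]:
            best = (mix, means, variances, ll)
    mix, means, variances, _ = best
    if floored_any:
        warnings.warn("degenerate mixture variance floored at 1e-6", stacklevel=2)
    order = np.argsort(means)
    mix = mix[order] / mix.sum()
    return GaussianMixture1D(mix, means[order], variances[order])


def _fit_gmm_mse(img: np.ndarray, d: int) -> GaussianMixture1D:
    """Least-squares fit of the mixture density to the 256-bin histogram."""
    hist, edges = np.histogram(np.asarray(img).ravel(), bins=256, range=(0, 256))
    centers = (edges[:-1] + edges[1:]) / 2
    density = hist / hist.sum()  # probability mass per unit-width bin
    start = fit_gmm(centers, d=d, weights=np.maximum(hist, 0) + 1e-9, max_iter=50)

    def unpack(theta):
        logits = np.concatenate([theta[:d - 1], [0.0]])
        wts = np.exp(logits - logits.max())
        wts /= wts.sum()
        mu = theta[d - 1: 2 * d - 1]
        sig = np.exp(theta[2 * d - 1:])
        return wts, mu, sig

    def residual(theta):
        wts, mu, sig = unpack(theta)
        comp = wts * np.exp(
            -((centers[:, None] - mu) ** 2) / (2 * sig**2)
        ) / np.sqrt(2 * np.pi * sig**2)
        return comp.sum(axis=1) - density

    theta0 = np.concatenate(
        [
            np.log(start.weights[:-1] / start.weights[-1]),
            start.means,
            0.5 * np.log(start.variances),
        ]
    )
    sol = optimize.least_squares(residual, theta0, max_nfev=2000)
    wts, mu, sig = unpack(sol.x)
    order = np.argsort(mu)
    return GaussianMixture1D(wts[order], mu[order], np.maximum(sig[order] ** 2, 1e-6))


def fit_gaussian_mixture(
    img: np.ndarray, d: int = 2, fit_mode: str = "em"
) -> GaussianMixture1D:
    """Fit a d-mode mixture to an image's gray-level distribution.

    ``em`` runs weighted EM over the 256-bin histogram (equivalent to EM
    on the binned intensities); ``mse`` minimizes the squared error
    between the mixture density and the normalized histogram.
    """
    if d < 2:
        raise ValueError("need at least two modes")
    if fit_mode == "mse":
        return _fit_gmm_mse(img, d)
    if fit_mode != "em":
        raise ValueError(f"unknown fit_mode {fit_mode!r}")
    hist, edges = np.histogram(np.asarray(img).ravel(), bins=256, range=(0, 256))
    centers = (edges[:-1] + edges[1:]) / 2
    return fit_gmm(centers, d=d, weights=hist)


def optimal_thresholds(gmm: GaussianMixture1D) -> np.ndarray:
    """Minimum-error boundaries between adjacent mixture modes.

    The threshold between modes i and i+1 is the gray level in
    (mu_i, mu_{i+1}) where the weighted densities cross, found by
    bisection; if they never cross there the midpoint is used.
    """
    thresholds = []
    for i in range(gmm.d - 1):
        w1, w2 = gmm.weights[i], gmm.weights[i + 1]
        m1, m2 = gmm.means[i], gmm.means[i + 1]
        v1, v2 = gmm.variances[i], gmm.variances[i + 1]

        def gap(x):
            a = w1 * np.exp(-((x - m1) ** 2) / (2 * v1)) / np.sqrt(2 * np.pi * v1)
            b = w2 * np.exp(-((x - m2) ** 2) / (2 * v2)) / np.sqrt(2 * np.pi * v2)
            return a - b

        lo, hi = float(m1), float(m2)
        if hi - lo < 1e-12:
            thresholds.append((lo + hi) / 2)
            continue
        eps = 1e-9 * (hi - lo)
        if gap(lo + eps) * gap(hi - eps) > 0:
            warnings.warn("no density crossing between modes; using midpoint", stacklevel=2)
            thresholds.append((lo + hi) / 2)
            continue
        a, b = lo + eps, hi - eps
        for _ in range(100):
            mid = (a + b) / 2
            if b - a < 1e-6:
                break
            if gap(a) * gap(mid) <= 0:
                b = mid
            else:
                a = mid
        thresholds.append((a + b) / 2)
    return np.array(thresholds)


def opening(mask: np.ndarray, se: StructuringElement | None = None) -> np.ndarray:
    """Morphological opening (erosion then dilation with the same element)."""
    if se is None:
        se = StructuringElement()
    mask = np.asarray(mask).astype(bool)
    return ndimage.binary_opening(mask, structure=se.mask)


def subtract(
    src: np.ndarray, opened: np.ndarray, direction: str = "src_minus_opened"
) -> np.ndarray:
    """Pixelwise image subtraction with negatives clamped to zero."""
    src = np.asarray(src, dtype=float)
    opened = np.asarray(opened, dtype=float)
    if src.shape != opened.shape:
        raise ValueError("shape mismatch")
    if direction == "src_minus_opened":
        diff = src - opened
    elif direction == "opened_minus_src":
        diff = opened - src
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return np.clip(diff, 0.0, 255.0)


# ---------------------------------------------------------------------------
# the full chain


@dataclass(frozen=True)
class PipelineConfig:
    """Stage parameters for the full preprocessing/segmentation chain.

    The mixture is fitted with three modes by default (background,
    tissue, bright lesion) and the mask keeps pixels above the top
    threshold; the fixed-band region-growing mask is combined with it
    by union (``mask_combine='intersection'`` for the strict reading).
    """

    highpass: HighPassSpec = field(default_factory=HighPassSpec)
    enhance_c: float = 25.0
    median_k: int = 3
    region: RegionGrowSpec = field(default_factory=RegionGrowSpec)
    gmm_modes: int = 3
    gmm_fit_mode: str = "em"
    mask_combine: str = "union"
    se: StructuringElement = field(default_factory=StructuringElement)
    subtract_direction: str = "src_minus_opened"


@dataclass
class PipelineResult:
    """Every intermediate stage of one pipeline run, for inspection."""

    source: np.ndarray
    highpassed: np.ndarray
    enhanced: np.ndarray
    median: np.ndarray
    region_mask: np.ndarray
    threshold_mask: np.ndarray
    segmentation_mask: np.ndarray
    opened_mask: np.ndarray
    opened_image: np.ndarray
    final: np.ndarray


def preprocess_pipeline(
    img: np.ndarray, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full chain on one 8-bit grayscale image.

    Stage order: high-pass filter -> additive enhancement -> median
    filter -> band region growing + mixture thresholding (masks
    combined) -> opening -> subtraction.  The "opened image" handed to
    the subtraction stage is the source with the opened segmentation
    removed, so subtracting it from the source isolates the segmented
    structure as a bright remnant on black.
    """
    if config is None:
        config = PipelineConfig()
    src = np.asarray(img, dtype=float)
    hp = filter_frequency(src, config.highpass)
    enhanced = enhance(src, hp, config.enhance_c)
    med = median_filter(enhanced, config.median_k)
    region_mask = region_grow(med, config.region)
    try:
        gmm = fit_gaussian_mixture(med, d=config.gmm_modes, fit_mode=config.gmm_fit_mode)
        thresholds = optimal_thresholds(gmm)
        threshold_mask = med > thresholds[-1]
    except ValueError:  # nearly constant image: no mixture structure
        threshold_mask = np.zeros_like(region_mask)
    if config.mask_combine == "union":
        seg = region_mask | threshold_mask
    elif config.mask_combine == "intersection":
        seg = region_mask & threshold_mask
    else:
        raise ValueError(f"unknown mask_combine {config.mask_combine!r}")
    opened_mask = opening(seg, config.se)
    opened_image = np.where(opened_mask, 0.0, src)
    final = subtract(src, opened_image, config.subtract_direction)
    return PipelineResult(
        source=src,
        highpassed=hp,
        enhanced=enhanced,
        median=med,
        region_mask=region_mask,
        threshold_mask=threshold_mask,
        segmentation_mask=seg,
        opened_mask=opened_mask,
        opened_image=opened_image,
        final=final,
    )


# ---------------------------------------------------------------------------
# I/O helpers and mask scoring


def read_gray(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/TIFF as a float array in [0, 255]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float)


def write_gray(img: np.ndarray, path: str | Path) -> None:
    """Write a [0, 255] array (or boolean mask as 0/255) as 8-bit PNG/TIFF."""
    arr = np.asarray(img)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    else:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
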