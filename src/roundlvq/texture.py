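"""Co-occurrence texture descriptors and PCA reduction.

A gray-level co-occurrence matrix (GLCM) counts how often pairs of
quantized intensities occur at a fixed pixel offset.  Computing it at
0/45/90/135 degrees and averaging the descriptors over the four angles
gives a degree of rotational invariance.  The 13 classical Haralick
statistics are extracted per matrix, and PCA reduces the pooled feature
table to a handful of components for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import LabeledDataset

__all__ = [
    "GLCMSpec",
    "ANGLES",
    "HARALICK_NAMES",
    "quantize",
    "compute_glcm",
    "glcm_set",
    "haralick_features",
    "image_feature_vector",
    "first_order_stats",
    "PCAModel",
    "pca_fit",
    "pca_project",
    "pca_reconstruct",
]

# offsets as (row, col) steps with rows increasing downward, origin top-left
ANGLES = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_correlation_1",
    "info_correlation_2",
)


@dataclass(frozen=True)
class GLCMSpec:
    """Quantization levels, offset distance, angles, and counting mode."""

    levels: int = 8
    distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least two gray levels")
        if self.distance < 1:
            raise ValueError("offset distance must be >= 1")
        for a in self.angles:
            if a not in ANGLES:
                raise ValueError(f"unsupported angle {a}")


def quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantize a [0, 255] image to ``levels`` integer bins."""
    img = np.asarray(img, dtype=float)
    q = np.floor(img * levels / 256.0).astype(int)
    return np.clip(q, 0, levels - 1)


def compute_glcm(img: np.ndarray, spec: GLCMSpec, angle: int) -> np.ndarray:
    """Co-occurrence counts of quantized intensity pairs at one angle.

    Symmetric mode also counts the reversed offset, so a horizontally
    adjacent equal pair contributes twice at 0 degrees.  Pairs whose
    neighbor falls outside the image are skipped.  With ``normalize``
    the matrix is divided by its total count.
    """
    if angle not in ANGLES:
        raise ValueError(f"unsupported angle {angle}")
    q = quantize(img, spec.levels)
    if q.max() >= spec.levels:
        raise ValueError("quantized level exceeds matrix size")
    dr, dc = ANGLES[angle]
    dr, dc = dr * spec.distance, dc * spec.distance
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    src = q[r0:r1, c0:c1].ravel()
    dst = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    mat = np.zeros((spec.levels, spec.levels))
    np.add.at(mat, (src, dst), 1.0)
    if spec.symmetric:
        mat = mat + mat.T
    if spec.normalize and mat.sum() > 0:
        mat = mat / mat.sum()
    return mat


def glcm_set(img: np.ndarray, spec: GLCMSpec) -> dict[int, np.ndarray]:
    """One co-occurrence matrix per configured angle."""
    return {a: compute_glcm(img, spec, a) for a in spec.angles}


def haralick_features(glcm: np.ndarray) -> np.ndarray:
    """The 13 classical co-occurrence descriptors of a normalized GLCM.

    Entropies use log base 2 with the 0*log0 = 0 convention; the sum
    variance is taken about the sum average.  Correlation and the
    information measures fall back to 0 on degenerate (zero-variance or
    zero-entropy) matrices.
    """
    p = np.asarray(glcm, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be square")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("GLCM must be normalized to sum 1")
    g = p.shape[0]
    idx = np.arange(g, dtype=float)
    i = idx[:, None]
    j = idx[None, :]

    def xlog2(v):
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        pos = v > 0
        out[pos] = v[pos] * np.log2(v[pos])
        return out

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(idx * px))
    mu_y = float(np.sum(idx * py))
    sd_x = float(np.sqrt(np.sum((idx - mu_x) ** 2 * px)))
    sd_y = float(np.sqrt(np.sum((idx - mu_y) ** 2 * py)))

    p_sum = np.zeros(2 * g - 1)  # p_{x+y}(k), k = i+j in 0..2g-2
    p_diff = np.zeros(g)  # p_{|x-y|}(k), k in 0..g-1
    for a in range(g):
        for b in range(g):
            p_sum[a + b] += p[a, b]
            p_diff[abs(a - b)] += p[a, b]
    k_sum = np.arange(2 * g - 1, dtype=float)
    k_diff = np.arange(g, dtype=float)

    asm = float(np.sum(p * p))
    contrast = float(np.sum(k_diff**2 * p_diff))
    if sd_x > 1e-12 and sd_y > 1e-12:
        correlation = float((np.sum(i * j * p) - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float(np.sum((i - mu_x) ** 2 * p))
    idm = float(np.sum(p / (1.0 + (i - j) ** 2)))
    sum_average = float(np.sum(k_sum * p_sum))
    sum_variance = float(np.sum((k_sum - sum_average) ** 2 * p_sum))
    sum_entropy = float(-np.sum(xlog2(p_sum)))
    entropy = float(-np.sum(xlog2(p)))
    diff_mean = float(np.sum(k_diff * p_diff))
    difference_variance = float(np.sum((k_diff - diff_mean) ** 2 * p_diff))
    difference_entropy = float(-np.sum(xlog2(p_diff)))

    hx = float(-np.sum(xlog2(px)))
    hy = float(-np.sum(xlog2(py)))
    outer = px[:, None] * py[None, :]
    pos = outer > 0
    hxy1 = float(-np.sum(p[pos] * np.log2(outer[pos])))
    hxy2 = float(-np.sum(xlog2(outer)))
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 1e-12 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
        ]
    )


def _angle_averaged(img: np.ndarray, spec: GLCMSpec) -> np.ndarray:
    mats = glcm_set(img, spec)
    feats = [haralick_features(m) for m in mats.values()]
    return np.mean(feats, axis=0)


def first_order_stats(img: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Eight first-order statistics of an image (or a masked region)."""
    vals = np.asarray(img, dtype=float).ravel()
    if mask is not None:
        sel = np.asarray(mask).astype(bool).ravel()
        vals = vals[sel] if sel.any() else np.zeros(1)
    hist, _ = np.histogram(vals, bins=256, range=(0, 256))
    prob = hist / hist.sum()
    pos = prob > 0
    entropy = float(-np.sum(prob[pos] * np.log2(prob[pos])))
    var = float(np.var(vals))
    skew = float(stats.skew(vals)) if var > 1e-12 else 0.0
    kurt = float(stats.kurtosis(vals)) if var > 1e-12 else 0.0
    return np.array(
        [
            float(np.mean(vals)),
            var,
            skew,
            kurt,
            float(np.sum(prob**2)),
            entropy,
            float(np.min(vals)),
            float(np.max(vals)),
        ]
    )


def image_feature_vector(
    source: np.ndarray,
    segmented: np.ndarray,
    spec: GLCMSpec | None = None,
    include_first_order: bool = False,
) -> np.ndarray:
    """Angle-averaged descriptors of the source and segmented images.

    The 13 descriptors are computed on both the source image and the
    pipeline's final (segmented) image and concatenated (26 features);
    with ``include_first_order`` eight first-order statistics of the
    segmented image are appended (34).
    """
    if spec is None:
        spec = GLCMSpec()
    parts = [_angle_averaged(source, spec), _angle_averaged(segmented, spec)]
    if include_first_order:
        parts.append(first_order_stats(segmented))
    return np.concatenate(parts)


def feature_names(include_first_order: bool = False) -> tuple[str, ...]:
    names = [f"src_{n}" for n in HARALICK_NAMES]
    names += [f"seg_{n}" for n in HARALICK_NAMES]
    if include_first_order:
        names += [
            "seg_mean",
            "seg_var",
            "seg_skew",
            "seg_kurtosis",
            "seg_energy",
            "seg_fo_entropy",
            "seg_min",
            "seg_max",
        ]
    return tuple(names)


# ---------------------------------------------------------------------------
# PCA


@dataclass(frozen=True)
class PCAModel:
    """Mean vector, column-orthonormal loadings, explained variances."""

    mean: np.ndarray
    loadings: np.ndarray  # p x q, columns sorted by descending variance
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca_fit(X: np.ndarray, q: int = 4) -> PCAModel:
    """Top-q eigenvectors of the sample covariance matrix.

    Sign convention: the largest-magnitude loading of each component is
    made positive so fits are reproducible across eigensolvers.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two samples")
    if q > min(n - 1, p):
        raise ValueError("too many components for this data")
    mean = X.mean(axis=0)
    cov = np.cov(X - mean, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:q]
    loadings = eigvec[:, order]
    eigval = eigval[order]
    for c in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, c]))
        if loadings[pivot, c] < 0:
            loadings[:, c] = -loadings[:, c]
    return PCAModel(mean=mean, loadings=loadings, explained_variance=eigval)


def pca_project(model: PCAModel, x: np.ndarray) -> np.ndarray:
    """Component scores n_s = F_s^T (x - mean); accepts a vector or matrix."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.mean.shape[0]:
        raise ValueError("dimension mismatch")
    return (x - model.mean) @ model.loadings


def pca_reconstruct(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Back-projection mean + F_s n_s."""
    return model.mean + np.asarray(scores, dtype=float) @ model.loadings.T


def pca_reduce_dataset(
    train_set: LabeledDataset, test_set: LabeledDataset, q: int = 4
) -> tuple[LabeledDataset, LabeledDataset, PCAModel]:
    """Fit PCA on the training split only and project both splits."""
    import dataclasses as _dc

    model = pca_fit(train_set.features, q=q)
    names = tuple(f"pc{i+1}" for i in range(q))
    tr = _dc.replace(
        train_set, features=pca_project(model, train_set.features), feature_names=names
    )
    te = _dc.replace(
        test_set, features=pca_project(model, test_set.features), feature_names=names
    )
    return tr, te, model
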