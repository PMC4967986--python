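"""Synthetic test beds: head phantoms with plantable lesions, and
Gaussian-blob feature tables.

The phantom generator draws an elliptical "head" on a dark background
and optionally plants a bright circular lesion whose mean intensity
(default 85) sits inside the fixed (80, 90) region-growing band used by
the segmentation stage, so planted lesions are detectable by
construction.  Real MR images would need the band re-tuned; the
phantoms emulate geometry and contrast, not MRI physics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import LabeledDataset

__all__ = [
    "PhantomSpec",
    "BlobSpec",
    "make_phantom",
    "make_blobs",
    "make_image_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensities of one synthetic head image."""

    size: int = 128
    lesion: bool = True
    lesion_center: tuple[float, float] | None = None  # (row, col); None -> offset default
    lesion_radius: float = 10.0
    lesion_mean: float = 85.0
    head_mean: float = 45.0
    background_mean: float = 8.0
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 16:
            raise ValueError("phantom too small")
        # keep ~95% of lesion pixels inside the (80, 90) region-growing band
        if self.lesion and not (
            80.0 < self.lesion_mean - 2 * self.noise_sigma
            and self.lesion_mean + 2 * self.noise_sigma < 90.0
        ):
            raise ValueError(
                "lesion_mean +/- 2 sigma must stay inside the (80, 90) band"
            )


@dataclass(frozen=True)
class BlobSpec:
    """K isotropic Gaussian classes in p dimensions."""

    classes: int = 2
    n_per_class: tuple[int, ...] | int = 100
    dimension: int = 2
    centers: np.ndarray | None = None
    spread: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes < 2:
            raise ValueError("need at least two classes")
        counts = self.counts()
        if any(c < 1 for c in counts):
            raise ValueError("every class needs at least one sample")

    def counts(self) -> tuple[int, ...]:
        if isinstance(self.n_per_class, int):
            return (self.n_per_class,) * self.classes
        if len(self.n_per_class) != self.classes:
            raise ValueError("one count per class required")
        return tuple(self.n_per_class)


def _head_axes(size: int) -> tuple[float, float]:
    # semi-axes of the head ellipse (rows, cols)
    return 0.42 * size, 0.34 * size


def _inside_head(size: int, center: tuple[float, float], radius: float) -> bool:
    a, b = _head_axes(size)
    c = size / 2
    r, q = center
    # the whole disk must stay inside the ellipse: shrink the ellipse by radius
    return ((r - c) / max(a - radius, 1e-9)) ** 2 + (
        (q - c) / max(b - radius, 1e-9)
    ) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """One phantom image and its ground-truth lesion mask."""
    size = spec.size
    c = size / 2
    a, b = _head_axes(size)
    rows, cols = np.mgrid[0:size, 0:size]
    head = ((rows - c) / a) ** 2 + ((cols - c) / b) ** 2 <= 1.0
    img = np.full((size, size), spec.background_mean)
    img[head] = spec.head_mean
    mask = np.zeros((size, size), dtype=bool)
    if spec.lesion:
        center = spec.lesion_center
        if center is None:
            center = (c - 0.4 * a, c)  # upper part of the head
        if not _inside_head(size, center, spec.lesion_radius):
            raise ValueError("lesion disk must lie inside the head ellipse")
        mask = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= spec.lesion_radius**2
        img[mask] = spec.lesion_mean
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 255.0), mask


def make_blobs(spec: BlobSpec) -> LabeledDataset:
    """Labeled rows drawn from isotropic Gaussians at the class centers."""
    rng = np.random.default_rng(spec.seed)
    counts = spec.counts()
    if spec.centers is None:
        # spread class centers along the diagonal, 6 sigma apart
        step = 6.0 * spec.spread if spec.spread > 0 else 6.0
        centers = np.array(
            [np.full(spec.dimension, k * step) for k in range(spec.classes)]
        )
    else:
        centers = np.asarray(spec.centers, dtype=float)
        if centers.shape != (spec.classes, spec.dimension):
            raise ValueError("centers must be a K x p matrix")
    rows = []
    labels = []
    for k, (center, n_k) in enumerate(zip(centers, counts)):
        rows.append(center + spec.spread * rng.standard_normal((n_k, spec.dimension)))
        labels.extend([f"c{k}"] * n_k)
    features = np.vstack(rows)
    return LabeledDataset.from_arrays(features, labels)


def make_image_dataset(
    n_normal: int,
    n_abnormal: int,
    seed: int = 0,
    base: PhantomSpec | None = None,
) -> tuple[list[np.ndarray], list[str], list[np.ndarray]]:
    """A set of phantoms with per-image randomized lesion geometry.

    Normal images carry no lesion; abnormal images get a lesion disk of
    randomized radius and position (kept inside the head).  Returns
    (images, labels, ground-truth masks), deterministic per seed.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("counts must be non-negative")
    if base is None:
        base = PhantomSpec()
    rng = np.random.default_rng(seed)
    images: list[np.ndarray] = []
    labels: list[str] = []
    masks: list[np.ndarray] = []
    size = base.size
    c = size / 2
    a, b = _head_axes(size)
    for i in range(n_normal + n_abnormal):
        abnormal = i >= n_normal
        sub_seed = int(rng.integers(0, 2**31))
        if abnormal:
            radius = float(rng.uniform(0.06 * size, 0.11 * size))
            while True:
                r = c + rng.uniform(-0.7, 0.7) * a
                q = c + rng.uniform(-0.7, 0.7) * b
                if _inside_head(size, (r, q), radius):
                    break
            spec = dataclasses.replace(
                base,
                lesion=True,
                lesion_center=(r, q),
                lesion_radius=radius,
                seed=sub_seed,
            )
        else:
            spec = dataclasses.replace(base, lesion=False, seed=sub_seed)
        img, mask = make_phantom(spec)
        images.append(img)
        labels.append("abnormal" if abnormal else "normal")
        masks.append(mask)
    return images, labels, masks
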