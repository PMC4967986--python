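"""Tabular labeled datasets: shuffling, percentage splitting, metrics.

The classifiers in this package are evaluated by repeated random
subsampling: shuffle the whole dataset, cut off the first
``train_fraction`` block as the training set, and score on the rest.
Keeping the split positional makes the shuffle the single source of
randomness, so a run is fully reproducible from its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "SplitSpec",
    "EvalReport",
    "MinMaxRecord",
    "shuffle_instances",
    "percentage_split",
    "evaluate",
    "minmax_normalize",
    "apply_minmax",
    "invert_minmax",
    "read_csv",
    "write_csv",
]


@dataclass(frozen=True)
class LabeledDataset:
    """An n x p feature matrix with one class label per row.

    ``class_names`` fixes the ordering of classes used by confusion
    matrices; every label must appear in it.
    """

    features: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels, dtype=object)
        if features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, p = features.shape
        if n < 1 or p < 1:
            raise ValueError("dataset needs at least one row and one feature")
        if labels.shape != (n,):
            raise ValueError("label count must equal the number of rows")
        if not np.all(np.isfinite(features)):
            raise ValueError("features must be finite")
        known = set(self.class_names)
        for lab in labels:
            if lab not in known:
                raise ValueError(f"label {lab!r} not in class_names")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must equal feature count")
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "class_names", tuple(self.class_names))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @classmethod
    def from_arrays(
        cls,
        features: np.ndarray,
        labels: Sequence,
        class_names: Sequence[str] | None = None,
        feature_names: Sequence[str] | None = None,
    ) -> "LabeledDataset":
        features = np.asarray(features, dtype=float)
        labels = np.asarray(labels, dtype=object)
        if class_names is None:
            class_names = tuple(sorted({str(l) for l in labels}))
            labels = np.array([str(l) for l in labels], dtype=object)
        if feature_names is None:
            feature_names = tuple(f"f{i}" for i in range(features.shape[1]))
        return cls(features, labels, tuple(class_names), tuple(feature_names))

    def take(self, index: np.ndarray) -> "LabeledDataset":
        return dataclasses.replace(
            self, features=self.features[index], labels=self.labels[index]
        )

    def label_indices(self) -> np.ndarray:
        """Labels encoded as integer positions in ``class_names``."""
        lookup = {c: i for i, c in enumerate(self.class_names)}
        return np.array([lookup[l] for l in self.labels], dtype=int)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split fractions for percentage-split evaluation."""

    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass(frozen=True)
class EvalReport:
    """Test-set accuracy, its root-mean-square 0/1 error, and confusion counts.

    ``rmse_indicator`` is sqrt(mean squared 0/1 misclassification
    indicator) = sqrt(1 - accuracy); accuracy 0.903 pairs with 0.3113.
    """

    accuracy: float
    rmse_indicator: float
    confusion: np.ndarray
    n_test: int
    class_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_test < 1:
            raise ValueError("empty evaluation")


def shuffle_instances(ds: LabeledDataset, seed: int) -> LabeledDataset:
    """Permute rows (feature row and label move together), seeded."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n)
    return ds.take(perm)


def percentage_split(
    ds: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Positional split: first floor(n * train_fraction) rows train, rest test.

    The dataset is expected to have been shuffled beforehand; the split
    itself introduces no randomness.
    """
    if ds.n < 2:
        raise ValueError("need at least two rows to split")
    n_train = int(np.floor(ds.n * spec.train_fraction))
    if n_train == 0 or n_train == ds.n:
        raise ValueError("split leaves an empty partition")
    idx = np.arange(ds.n)
    return ds.take(idx[:n_train]), ds.take(idx[n_train:])


def evaluate(
    predicted: Sequence, truth: Sequence, class_names: Sequence[str]
) -> EvalReport:
    """Accuracy, rmse of the 0/1 error indicator, and the confusion matrix."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted/truth length mismatch")
    if len(truth) == 0:
        raise ValueError("empty evaluation")
    lookup = {c: i for i, c in enumerate(class_names)}
    k = len(class_names)
    confusion = np.zeros((k, k), dtype=int)
    for p_lab, t_lab in zip(predicted, truth):
        if p_lab not in lookup or t_lab not in lookup:
            raise ValueError(f"label outside class_names: {p_lab!r}/{t_lab!r}")
        confusion[lookup[t_lab], lookup[p_lab]] += 1
    n_test = len(truth)
    accuracy = float(np.trace(confusion)) / n_test
    return EvalReport(
        accuracy=accuracy,
        rmse_indicator=float(np.sqrt(1.0 - accuracy)),
        confusion=confusion,
        n_test=n_test,
        class_names=tuple(class_names),
    )


@dataclass(frozen=True)
class MinMaxRecord:
    """Per-feature minima/maxima recorded by :func:`minmax_normalize`."""

    minima: np.ndarray
    maxima: np.ndarray


def minmax_normalize(ds: LabeledDataset) -> tuple[LabeledDataset, MinMaxRecord]:
    """Map each feature to [0, 1]; constant features map to 0."""
    minima = ds.features.min(axis=0)
    maxima = ds.features.max(axis=0)
    record = MinMaxRecord(minima=minima, maxima=maxima)
    return apply_minmax(ds, record), record


def apply_minmax(ds: LabeledDataset, record: MinMaxRecord) -> LabeledDataset:
    """Apply a stored min/max transform, e.g. to held-out data."""
    span = record.maxima - record.minima
    safe = np.where(span > 0, span, 1.0)
    scaled = (ds.features - record.minima) / safe
    scaled = np.where(span > 0, scaled, 0.0)
    return dataclasses.replace(ds, features=scaled)


def invert_minmax(ds: LabeledDataset, record: MinMaxRecord) -> LabeledDataset:
    span = record.maxima - record.minima
    restored = np.where(span > 0, ds.features * span + record.minima, record.minima)
    return dataclasses.replace(ds, features=restored)


def read_csv(path: str | Path, label_column: str = "class") -> LabeledDataset:
    """Read a feature table with a header row and one label column."""
    frame = pd.read_csv(path)
    if label_column not in frame.columns:
        raise ValueError(f"label column {label_column!r} missing")
    labels = frame[label_column].astype(str).to_numpy(dtype=object)
    feats = frame.drop(columns=[label_column])
    return LabeledDataset.from_arrays(
        feats.to_numpy(dtype=float), labels, feature_names=tuple(feats.columns)
    )


def write_csv(
    ds: LabeledDataset, path: str | Path, label_column: str = "class"
) -> None:
    frame = pd.DataFrame(ds.features, columns=list(ds.feature_names))
    frame[label_column] = ds.labels
    frame.to_csv(path, index=False)
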