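"""Multirandomized training: shuffle, split, train, evaluate, keep the best.

Competitive classifiers are sensitive to the order and composition of
the training split.  Repeating the shuffle-split-train-evaluate cycle R
times (50 by default) and retaining the best-scoring model trades a
constant factor of compute for a markedly more stable selected model.

Note that model selection here scores on the same held-out split that
is reported, with no inner validation split; the selected accuracy is
therefore an optimistic estimate.  This mirrors the protocol the
package implements rather than a recommendation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np

from .data import (
    EvalReport,
    LabeledDataset,
    SplitSpec,
    evaluate,
    percentage_split,
    shuffle_instances,
)

__all__ = [
    "MultiRandomConfig",
    "MultiRandomReport",
    "Trainer",
    "classifier_contract_adapter",
    "derive_run_seed",
    "multirandom_train",
    "write_report_csv",
]


class Trainer(Protocol):
    """Anything that fits on a labeled dataset and returns a predictor."""

    def fit(self, train_set: LabeledDataset, seed: int): ...


@dataclass(frozen=True)
class MultiRandomConfig:
    repetitions: int = 50
    split: SplitSpec = field(default_factory=SplitSpec)
    meta_seed: int = 0
    selection_metric: str = "accuracy"

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("need at least one repetition")
        if self.selection_metric != "accuracy":
            raise ValueError("only accuracy selection is supported")


@dataclass
class MultiRandomReport:
    """Per-run evaluations plus the summary the protocol reports."""

    per_run: list[tuple[int, EvalReport]]
    mean_accuracy: float
    std_accuracy: float
    best_run: int

    @property
    def best_accuracy(self) -> float:
        return self.per_run[self.best_run][1].accuracy

    def accuracies(self) -> np.ndarray:
        return np.array([rep.accuracy for _, rep in self.per_run])


def derive_run_seed(meta_seed: int, run: int) -> int:
    """Per-run seed from (meta_seed, run) via a splitmix64-style mixer."""
    z = (int(meta_seed) * 0x9E3779B97F4A7C15 + (run + 1) * 0xBF58476D1CE4E5B9) % 2**64
    z ^= z >> 30
    z = (z * 0xBF58476D1CE4E5B9) % 2**64
    z ^= z >> 27
    z = (z * 0x94D049BB133111EB) % 2**64
    z ^= z >> 31
    return int(z % 2**31)


class _FunctionTrainer:
    def __init__(self, fit_fn: Callable, predict_fn: Callable):
        self._fit = fit_fn
        self._predict = predict_fn

    def fit(self, train_set: LabeledDataset, seed: int):
        model = self._fit(train_set, seed)
        predict_fn = self._predict
        class _Predictor:
            def predict(self, X):
                return predict_fn(model, X)
        predictor = _Predictor()
        predictor.model = model
        return predictor


def classifier_contract_adapter(fit_fn: Callable, predict_fn: Callable) -> Trainer:
    """Wrap (fit, predict) callables into the trainer contract.

    ``fit_fn(train_set, seed) -> model`` and ``predict_fn(model, X) ->
    labels``.  This lets any external classifier take part in the
    multirandomization protocol.
    """
    return _FunctionTrainer(fit_fn, predict_fn)


def multirandom_train(
    ds: LabeledDataset, trainer: Trainer, cfg: MultiRandomConfig
) -> tuple[object, MultiRandomReport]:
    """Run R shuffle/split/train/evaluate cycles; return the best model.

    Ties on accuracy go to the lowest run index.  Raises with the run
    index attached if the trainer fails mid-protocol.
    """
    per_run: list[tuple[int, EvalReport]] = []
    models: list[object] = []
    for r in range(cfg.repetitions):
        run_seed = derive_run_seed(cfg.meta_seed, r)
        try:
            shuffled = shuffle_instances(ds, run_seed)
            train_set, test_set = percentage_split(
                shuffled, SplitSpec(cfg.split.train_fraction, run_seed)
            )
            predictor = trainer.fit(train_set, run_seed)
            predicted = predictor.predict(test_set.features)
            report = evaluate(predicted, test_set.labels, ds.class_names)
        except Exception as exc:
            raise RuntimeError(f"trainer failed on randomization run {r}") from exc
        per_run.append((run_seed, report))
        models.append(predictor)
    accs = np.array([rep.accuracy for _, rep in per_run])
    best = int(np.argmax(accs))  # argmax takes the first (lowest) index on ties
    mean = float(accs.mean())
    std = float(accs.std(ddof=1)) if len(accs) > 1 else 0.0
    report = MultiRandomReport(
        per_run=per_run, mean_accuracy=mean, std_accuracy=std, best_run=best
    )
    return models[best], report


def write_report_csv(report: MultiRandomReport, path: str | Path) -> None:
    """Per-run rows (run, seed, accuracy, rmse) plus a summary row."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["run", "seed", "accuracy", "rmse_indicator"])
        for r, (seed, rep) in enumerate(report.per_run):
            writer.writerow([r, seed, f"{rep.accuracy:.6f}", f"{rep.rmse_indicator:.6f}"])
        writer.writerow(
            [
                "summary",
                f"best_run={report.best_run}",
                f"mean={report.mean_accuracy:.6f}",
                f"std={report.std_accuracy:.6f}",
            ]
        )
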