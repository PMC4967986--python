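"""End-to-end orchestration: images -> segmentation -> features -> classifier.

These helpers wire the imaging pipeline, the texture descriptors, PCA
and the multirandomized LVQ trainer into the complete classification
workflow, so the CLI, tests and reproduction script all share one path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import lvq
from .data import LabeledDataset, apply_minmax, minmax_normalize
from .imaging import PipelineConfig, preprocess_pipeline
from .randomize import MultiRandomConfig, MultiRandomReport, classifier_contract_adapter, multirandom_train
from .texture import GLCMSpec, feature_names, image_feature_vector, pca_fit, pca_project

__all__ = [
    "extract_feature_table",
    "LVQTrainer",
    "lvq_trainer",
    "run_image_experiment",
]


def extract_feature_table(
    images: Sequence[np.ndarray],
    labels: Sequence[str],
    pipeline_config: PipelineConfig | None = None,
    glcm_spec: GLCMSpec | None = None,
    include_first_order: bool = False,
) -> LabeledDataset:
    """Segment every image and compute its texture feature vector."""
    if len(images) != len(labels):
        raise ValueError("one label per image required")
    rows = []
    for img in images:
        result = preprocess_pipeline(img, pipeline_config)
        rows.append(
            image_feature_vector(
                result.source, result.final, glcm_spec, include_first_order
            )
        )
    return LabeledDataset.from_arrays(
        np.array(rows), list(labels), feature_names=feature_names(include_first_order)
    )


@dataclass
class LVQTrainer:
    """Trainer-contract wrapper around :func:`roundlvq.lvq.train`.

    Optionally min-max normalizes features and reduces them with PCA,
    both fitted on the training split only.
    """

    variant: str = "lvq1"
    config: lvq.LVQConfig = field(default_factory=lvq.LVQConfig)
    normalize: bool = False
    pca_components: int | None = None

    def fit(self, train_set: LabeledDataset, seed: int):
        norm_record = None
        if self.normalize:
            train_set, norm_record = minmax_normalize(train_set)
        pca_model = None
        if self.pca_components is not None:
            q = min(self.pca_components, train_set.p, train_set.n - 1)
            pca_model = pca_fit(train_set.features, q=q)
            train_set = dataclasses.replace(
                train_set,
                features=pca_project(pca_model, train_set.features),
                feature_names=tuple(f"pc{i+1}" for i in range(q)),
            )
        config = dataclasses.replace(self.config, seed=seed)
        model = lvq.train(self.variant, train_set, config)
        return _LVQPredictor(model, norm_record, pca_model)


class _LVQPredictor:
    def __init__(self, model, norm_record, pca_model):
        self.model = model
        self.norm_record = norm_record
        self.pca_model = pca_model

    @property
    def input_dim(self) -> int:
        if self.norm_record is not None:
            return len(self.norm_record.minima)
        if self.pca_model is not None:
            return len(self.pca_model.mean)
        return self.model.p

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.norm_record is not None:
            span = self.norm_record.maxima - self.norm_record.minima
            safe = np.where(span > 0, span, 1.0)
            X = np.where(span > 0, (X - self.norm_record.minima) / safe, 0.0)
        if self.pca_model is not None:
            X = pca_project(self.pca_model, X)
        return lvq.predict(self.model, X)


def save_predictor(predictor: "_LVQPredictor", path) -> None:
    """Serialize a fitted predictor (preprocessing + LVQ model) to JSON."""
    import json
    from pathlib import Path

    payload = {
        "format": "roundlvq-predictor",
        "version": 1,
        "norm": None,
        "pca": None,
        "model": lvq._model_to_dict(predictor.model),
    }
    if predictor.norm_record is not None:
        payload["norm"] = {
            "minima": predictor.norm_record.minima.tolist(),
            "maxima": predictor.norm_record.maxima.tolist(),
        }
    if predictor.pca_model is not None:
        payload["pca"] = {
            "mean": predictor.pca_model.mean.tolist(),
            "loadings": predictor.pca_model.loadings.tolist(),
            "explained_variance": predictor.pca_model.explained_variance.tolist(),
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_predictor(path) -> "_LVQPredictor":
    """Load a predictor saved by :func:`save_predictor` (or a bare model)."""
    import json
    from pathlib import Path

    from .data import MinMaxRecord
    from .texture import PCAModel

    d = json.loads(Path(path).read_text())
    if d.get("format") == "roundlvq-model":
        return _LVQPredictor(lvq._model_from_dict(d), None, None)
    if d.get("format") != "roundlvq-predictor":
        raise ValueError("not a roundlvq predictor file")
    norm = None
    if d["norm"] is not None:
        norm = MinMaxRecord(
            minima=np.array(d["norm"]["minima"]), maxima=np.array(d["norm"]["maxima"])
        )
    pca = None
    if d["pca"] is not None:
        pca = PCAModel(
            mean=np.array(d["pca"]["mean"]),
            loadings=np.array(d["pca"]["loadings"]),
            explained_variance=np.array(d["pca"]["explained_variance"]),
        )
    return _LVQPredictor(lvq._model_from_dict(d["model"]), norm, pca)


def lvq_trainer(
    variant: str = "lvq1",
    config: lvq.LVQConfig | None = None,
    normalize: bool = False,
    pca_components: int | None = None,
) -> LVQTrainer:
    return LVQTrainer(
        variant=variant,
        config=config or lvq.LVQConfig(),
        normalize=normalize,
        pca_components=pca_components,
    )


def run_image_experiment(
    images: Sequence[np.ndarray],
    labels: Sequence[str],
    variant: str = "lvq1",
    config: lvq.LVQConfig | None = None,
    multirandom: MultiRandomConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    glcm_spec: GLCMSpec | None = None,
    pca_components: int | None = 4,
) -> tuple[object, MultiRandomReport, LabeledDataset]:
    """Full rehearsal: segment, extract features, multirandom-train an LVQ."""
    table = extract_feature_table(images, labels, pipeline_config, glcm_spec)
    trainer = lvq_trainer(
        variant=variant,
        config=config,
        normalize=True,
        pca_components=pca_components,
    )
    cfg = multirandom or MultiRandomConfig()
    best, report = multirandom_train(table, trainer, cfg)
    return best, report, table
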