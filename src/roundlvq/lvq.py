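"""Learning Vector Quantization with classical and rounded winner selection.

The family implemented here covers LVQ1, LVQ3, their optimized variants
(OLVQ1/OLVQ3, one adaptive learning rate per codebook vector), Multipass
LVQ (a coarse OLVQ1 pass followed by slow LVQ3 fine-tuning), and a
two-level hierarchical LVQ.

The non-classical ingredient is the *rounded* distance: the Euclidean
distance between input and prototype is passed through a round-off
function before the winner is chosen.  Rounding deliberately creates
ties among prototypes at nearly equal distance; resolving those ties at
random keeps marginal prototypes in the competition instead of letting
a single narrowly-closest vector absorb every update.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import LabeledDataset

__all__ = [
    "Codebook",
    "LVQConfig",
    "LVQModel",
    "VARIANTS",
    "euclidean_distance",
    "round_distance",
    "round_half_away",
    "mode_distances",
    "find_bmu",
    "decay_alpha",
    "init_codebook",
    "lvq1_step",
    "lvq3_step",
    "olvq_step",
    "train",
    "train_multipass",
    "train_hlvq",
    "predict",
    "save_model",
    "load_model",
]

VARIANTS = ("lvq1", "lvq3", "olvq1", "olvq3", "multipass", "hlvq")


@dataclass
class Codebook:
    """Labeled prototype vectors; OLVQ variants carry per-vector rates."""

    vectors: np.ndarray
    labels: np.ndarray
    per_vector_alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != self.labels.shape[0]:
            raise ValueError("vectors and labels must agree on prototype count")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("prototype vectors must be finite")
        if self.per_vector_alpha is not None:
            self.per_vector_alpha = np.asarray(self.per_vector_alpha, dtype=float)
            if self.per_vector_alpha.shape != self.labels.shape:
                raise ValueError("one learning rate per prototype required")

    @property
    def m(self) -> int:
        return self.vectors.shape[0]

    def copy(self) -> "Codebook":
        return Codebook(
            self.vectors.copy(),
            self.labels.copy(),
            None if self.per_vector_alpha is None else self.per_vector_alpha.copy(),
        )


@dataclass(frozen=True)
class LVQConfig:
    """Training hyper-parameters.

    Defaults follow the configuration found to work best for the
    brain-image application: learning rate 0.3, 40 codebook vectors,
    2000 presentations, linear learning-rate decay.
    """

    alpha0: float = 0.3
    iterations: int = 2000
    num_codebooks: int = 40
    decay: str = "linear"
    distance_mode: str = "euclidean"  # euclidean | rounded | rounded_squared
    round_decimals: int = 0
    tie_break: str = "random"  # random | lowest_index (training-time ties)
    window: float = 0.3
    epsilon: float = 0.3
    seed: int = 0
    # multipass knobs
    multipass_alpha1: float = 0.3
    multipass_alpha2: float = 0.05
    multipass_length_factor: int = 40
    # hierarchical knobs
    hlvq_overlap: float = 0.1
    hlvq_level1_codebooks: int = 0  # 0 -> 2 * number of classes

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha0 < 1.0):
            raise ValueError("alpha0 must lie in (0, 1)")
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")
        if not (0.0 < self.window < 1.0):
            raise ValueError("window must lie in (0, 1)")
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in (0, 1]")
        if self.distance_mode not in ("euclidean", "rounded", "rounded_squared"):
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")
        if self.tie_break not in ("random", "lowest_index"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")


@dataclass
class LVQModel:
    """A fitted model: codebook + config; hierarchical models route to children."""

    codebook: Codebook
    config: LVQConfig
    variant: str
    children: dict | None = None  # hlvq: partition index -> sub-model or label
    meta: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.codebook.vectors.shape[1]


# ---------------------------------------------------------------------------
# distances and winner selection


def euclidean_distance(w: np.ndarray, x: np.ndarray) -> float:
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    if w.shape != x.shape:
        raise ValueError("vector length mismatch")
    return float(np.sqrt(np.sum((w - x) ** 2)))


def round_half_away(values: np.ndarray, decimals: int = 0) -> np.ndarray:
    """Round half away from zero (so 0.5 -> 1), unlike banker's rounding."""
    scale = 10.0 ** decimals
    v = np.asarray(values, dtype=float) * scale
    return np.sign(v) * np.floor(np.abs(v) + 0.5) / scale


def round_distance(w: np.ndarray, x: np.ndarray, round_decimals: int = 0) -> float:
    """Euclidean distance passed through the round-off function."""
    return float(round_half_away(euclidean_distance(w, x), round_decimals))


def mode_distances(
    vectors: np.ndarray, x: np.ndarray, distance_mode: str, round_decimals: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """(selection distances, raw Euclidean distances) to every prototype."""
    diff = vectors - x
    raw = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    if distance_mode == "euclidean":
        return raw, raw
    if distance_mode == "rounded":
        return round_half_away(raw, round_decimals), raw
    if distance_mode == "rounded_squared":
        return round_half_away(raw * raw, round_decimals), raw
    raise ValueError(f"unknown distance_mode {distance_mode!r}")


def _pick(
    dist: np.ndarray,
    raw: np.ndarray,
    candidates: np.ndarray,
    tie_break: str,
    rng: np.random.Generator | None,
) -> int:
    sub = dist[candidates]
    tied = candidates[sub == sub.min()]
    if len(tied) == 1 or tie_break == "lowest_index":
        return int(tied[0])
    if tie_break == "random":
        if rng is None:
            raise ValueError("random tie-break requires an rng")
        return int(rng.choice(tied))
    # deterministic inference: lowest raw distance, then lowest index
    sub_raw = raw[tied]
    return int(tied[sub_raw == sub_raw.min()][0])


def find_bmu(
    cb: Codebook,
    x: np.ndarray,
    config: LVQConfig,
    rng: np.random.Generator | None = None,
    tie_break: str | None = None,
) -> tuple[int, int]:
    """Winner and runner-up prototype indices for input ``x``.

    With rounded distances several prototypes may tie on the selection
    value; training resolves ties per ``config.tie_break`` (random among
    tied, seeded), while inference passes ``tie_break='raw'`` for a
    deterministic lowest-raw-distance rule.
    """
    if cb.m == 0:
        raise ValueError("empty codebook")
    tb = config.tie_break if tie_break is None else tie_break
    dist, raw = mode_distances(cb.vectors, x, config.distance_mode, config.round_decimals)
    all_idx = np.arange(cb.m)
    winner = _pick(dist, raw, all_idx, tb, rng)
    if cb.m == 1:
        return winner, winner
    rest = all_idx[all_idx != winner]
    runner = _pick(dist, raw, rest, tb, rng)
    return winner, runner


def decay_alpha(alpha0: float, t: int, T: int) -> float:
    """Linear decay alpha0 * (1 - t/T) over the training run."""
    if T <= 0:
        raise ValueError("total presentations T must be positive")
    if not (0 <= t < T):
        raise ValueError("presentation index out of range")
    return alpha0 * (1.0 - t / T)


# ---------------------------------------------------------------------------
# codebook initialization and update steps


def _allocate_per_class(counts: np.ndarray, m: int) -> np.ndarray:
    """Largest-remainder allocation of m prototypes, each class >= 1."""
    k = len(counts)
    if m < k:
        raise ValueError("need at least one prototype per class")
    frac = counts / counts.sum() * m
    alloc = np.maximum(np.floor(frac).astype(int), 1)
    # distribute the remainder by largest fractional part; steal from the
    # most over-allocated classes if the floor+min-1 step overshot m
    while alloc.sum() < m:
        rem = frac - alloc
        alloc[int(np.argmax(rem))] += 1
    while alloc.sum() > m:
        surplus = alloc - np.maximum(frac, 1)
        cand = np.where(alloc > 1)[0]
        alloc[cand[int(np.argmax(surplus[cand]))]] -= 1
    return alloc


def init_codebook(
    train_set: LabeledDataset, m: int, seed: int, with_alpha: float | None = None
) -> Codebook:
    """Sample prototypes (without replacement) from the training rows.

    Per-class prototype counts are proportional to class frequencies,
    with at least one prototype per class.
    """
    classes = list(train_set.class_names)
    counts = np.array([np.sum(train_set.labels == c) for c in classes])
    if np.any(counts == 0):
        raise ValueError("every class needs at least one training row")
    alloc = _allocate_per_class(counts, m)
    rng = np.random.default_rng(seed)
    vec_rows: list[np.ndarray] = []
    labels: list = []
    for cls, take in zip(classes, alloc):
        rows = np.where(train_set.labels == cls)[0]
        take = min(int(take), len(rows))
        chosen = rng.choice(rows, size=take, replace=False)
        for r in chosen:
            vec_rows.append(train_set.features[r].copy())
            labels.append(cls)
    vectors = np.array(vec_rows)
    alpha = None
    if with_alpha is not None:
        alpha = np.full(len(labels), float(with_alpha))
    return Codebook(vectors, np.array(labels, dtype=object), alpha)


def lvq1_step(
    cb: Codebook,
    x: np.ndarray,
    y,
    alpha: float,
    config: LVQConfig,
    rng: np.random.Generator | None = None,
) -> Codebook:
    """Move the winner toward x if its class matches, else away (in place)."""
    winner, _ = find_bmu(cb, x, config, rng)
    sign = 1.0 if cb.labels[winner] == y else -1.0
    cb.vectors[winner] += sign * alpha * (x - cb.vectors[winner])
    return cb

def lvq3_step(
    cb: Codebook,
    x: np.ndarray,
    y,
    alpha: float,
    config: LVQConfig,
    rng: np.random.Generator | None = None,
    alpha_override: float | None = None,
) -> Codebook:
    """Window-based update of winner and runner-up (in place).

    If exactly one of the two nearest prototypes has the correct class
    and x falls inside the window around their mid-plane, the correct
    one attracts and the wrong one repels.  If both are correct, both
    attract with the damped rate epsilon * alpha.
    """
    winner, runner = find_bmu(cb, x, config, rng)
    a = alpha if alpha_override is None else alpha_override
    dist, _raw = mode_distances(cb.vectors, x, config.distance_mode, config.round_decimals)
    d_i, d_j = dist[winner], dist[runner]
    hi = max(d_i, d_j)
    ratio = 1.0 if hi == 0 else min(d_i, d_j) / hi
    inside = ratio > (1.0 - config.window) / (1.0 + config.window)
    match_i = cb.labels[winner] == y
    match_j = cb.labels[runner] == y
    if match_i and match_j:
        rate = config.epsilon * a
        cb.vectors[winner] += rate * (x - cb.vectors[winner])
        cb.vectors[runner] += rate * (x - cb.vectors[runner])
    elif inside and (match_i ^ match_j):
        good, bad = (winner, runner) if match_i else (runner, winner)
        cb.vectors[good] += a * (x - cb.vectors[good])
        cb.vectors[bad] -= a * (x - cb.vectors[bad])
    return cb


def olvq_step(
    cb: Codebook,
    x: np.ndarray,
    y,
    config: LVQConfig,
    rng: np.random.Generator | None = None,
    rule: str = "olvq1",
) -> Codebook:
    """LVQ1/LVQ3 update driven by the winner's private learning rate.

    Afterwards the winner's rate follows the optimized-LVQ recursion
    alpha <- alpha / (1 + s*alpha), shrinking after a correct win
    (s=+1) and growing (capped at alpha0) after a wrong one (s=-1).
    """
    if cb.per_vector_alpha is None:
        raise ValueError("OLVQ update requires per-vector learning rates")
    winner, _ = find_bmu(cb, x, config, rng)
    a_c = float(cb.per_vector_alpha[winner])
    if rule == "olvq1":
        sign = 1.0 if cb.labels[winner] == y else -1.0
        cb.vectors[winner] += sign * a_c * (x - cb.vectors[winner])
    elif rule == "olvq3":
        lvq3_step(cb, x, y, a_c, config, rng, alpha_override=a_c)
    else:
        raise ValueError(f"unknown OLVQ rule {rule!r}")
    s = 1.0 if cb.labels[winner] == y else -1.0
    new_alpha = a_c / (1.0 + s * a_c)
    cb.per_vector_alpha[winner] = min(new_alpha, config.alpha0)
    return cb


# ---------------------------------------------------------------------------
# training drivers


def _presentation_order(n: int, total: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded shuffle of the row indices, cycled to ``total`` presentations."""
    order = rng.permutation(n)
    reps = int(np.ceil(total / n)) if total else 0
    return np.tile(order, max(reps, 1))[:total]


def _run_presentations(
    cb: Codebook,
    train_set: LabeledDataset,
    config: LVQConfig,
    variant: str,
    iterations: int,
    alpha0: float,
    rng: np.random.Generator,
    history: list | None = None,
) -> Codebook:
    order = _presentation_order(train_set.n, iterations, rng)
    X = train_set.features
    y = train_set.labels
    for t in range(iterations):
        idx = order[t]
        alpha = decay_alpha(alpha0, t, iterations)
        if variant == "lvq1":
            lvq1_step(cb, X[idx], y[idx], alpha, config, rng)
        elif variant == "lvq3":
            lvq3_step(cb, X[idx], y[idx], alpha, config, rng)
        elif variant in ("olvq1", "olvq3"):
            olvq_step(cb, X[idx], y[idx], config, rng, rule=variant)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        if history is not None:
            history.append(cb.vectors.copy())
    return cb


def train(
    variant: str,
    train_set: LabeledDataset,
    config: LVQConfig,
    record_history: bool = False,
) -> LVQModel:
    """Fit one LVQ variant on a labeled dataset.

    One iteration is one single-sample presentation; the presentation
    schedule is a seeded shuffle of the training rows, cycled.  The
    whole run is deterministic given (data, config, seed).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "multipass":
        return train_multipass(train_set, config)
    if variant == "hlvq":
        return train_hlvq(train_set, config)
    rng = np.random.default_rng(config.seed)
    with_alpha = config.alpha0 if variant in ("olvq1", "olvq3") else None
    cb = init_codebook(train_set, config.num_codebooks, config.seed, with_alpha)
    history: list | None = [] if record_history else None
    _run_presentations(
        cb, train_set, config, variant, config.iterations, config.alpha0, rng, history
    )
    meta = {"presentations": config.iterations}
    if record_history:
        meta["history"] = history
    return LVQModel(codebook=cb, config=config, variant=variant, meta=meta)


def train_multipass(train_set: LabeledDataset, config: LVQConfig) -> LVQModel:
    """Coarse OLVQ1 pass, then slow LVQ3 fine-tuning from the same codebook.

    Pass 1 runs for ``multipass_length_factor`` x m presentations at a
    large rate; pass 2 runs ten times as long at a small rate
    (default 0.05) so the class boundaries are only nudged.
    """
    if config.multipass_alpha2 >= 0.1:
        warnings.warn(
            "multipass fine-tuning rate >= 0.1; the second pass is meant "
            "to fine-tune slowly",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    m = config.num_codebooks
    pass1 = config.multipass_length_factor * m
    pass2 = 10 * pass1
    cb = init_codebook(train_set, m, config.seed, with_alpha=config.multipass_alpha1)
    cfg1 = dataclasses.replace(config, alpha0=config.multipass_alpha1)
    _run_presentations(cb, train_set, cfg1, "olvq1", pass1, cfg1.alpha0, rng)
    cb.per_vector_alpha = None  # pass 2 is plain LVQ3
    if config.multipass_alpha2 > 0:
        cfg2 = dataclasses.replace(config, alpha0=config.multipass_alpha2)
        _run_presentations(cb, train_set, cfg2, "lvq3", pass2, cfg2.alpha0, rng)
    meta = {"pass1_presentations": pass1, "pass2_presentations": pass2}
    return LVQModel(codebook=cb, config=config, variant="multipass", meta=meta)


def train_hlvq(
    train_set: LabeledDataset, config: LVQConfig, overlap: float | None = None
) -> LVQModel:
    """Two-level hierarchical LVQ with overlapping partition borders.

    A small level-1 LVQ1 codebook partitions the training set by BMU;
    points whose runner-up distance is within (1+overlap) of the winner
    distance join both partitions, so neighbouring sub-models share
    their border region.  Each partition trains its own LVQ1 sub-model
    over the classes it contains; single-class partitions become leaves.
    """
    overlap = config.hlvq_overlap if overlap is None else overlap
    k = len(train_set.class_names)
    m1 = config.hlvq_level1_codebooks or 2 * k
    cfg1 = dataclasses.replace(config, num_codebooks=m1)
    top = train(
        "lvq1", train_set, cfg1
    )
    cb = top.codebook
    # assign every training row to its winner partition (+ border overlap)
    members: dict[int, list[int]] = {i: [] for i in range(cb.m)}
    for r in range(train_set.n):
        dist, raw = mode_distances(
            cb.vectors, train_set.features[r], config.distance_mode, config.round_decimals
        )
        order = np.lexsort((np.arange(cb.m), raw, dist))
        w = int(order[0])
        members[w].append(r)
        if cb.m > 1:
            ru = int(order[1])
            if raw[ru] <= (1.0 + overlap) * raw[w]:
                members[ru].append(r)
    children: dict[int, object] = {}
    kept: list[int] = []
    for i in range(cb.m):
        rows = members[i]
        if not rows:
            continue  # empty partition: dropped; routing falls back to the rest
        kept.append(i)
        part = train_set.take(np.array(rows))
        part_classes = sorted(set(part.labels))
        if len(part_classes) == 1:
            children[i] = ("leaf", part_classes[0])
        else:
            m_sub = max(len(part_classes), config.num_codebooks // max(cb.m, 1))
            m_sub = min(m_sub, part.n)
            m_sub = max(m_sub, len(part_classes))
            sub_cfg = dataclasses.replace(
                config, num_codebooks=m_sub, seed=config.seed + 1 + i
            )
            sub_ds = dataclasses.replace(part, class_names=tuple(part_classes))
            children[i] = ("model", train("lvq1", sub_ds, sub_cfg))
    keep = np.array(kept, dtype=int)
    routed = Codebook(cb.vectors[keep], cb.labels[keep])
    children = {new: children[old] for new, old in enumerate(kept)}
    meta = {"level1_codebooks": m1, "overlap": overlap}
    return LVQModel(
        codebook=routed, config=config, variant="hlvq", children=children, meta=meta
    )


# ---------------------------------------------------------------------------
# inference


def _predict_row(model: LVQModel, x: np.ndarray):
    cb = model.codebook
    dist, raw = mode_distances(
        cb.vectors, x, model.config.distance_mode, model.config.round_decimals
    )
    # deterministic inference tie-break: rounded value, then raw, then index
    order = np.lexsort((np.arange(cb.m), raw, dist))
    w = int(order[0])
    if model.children is None:
        return cb.labels[w]
    kind, payload = model.children[w]
    if kind == "leaf":
        return payload
    return _predict_row(payload, x)


def predict(model: LVQModel, X: np.ndarray) -> np.ndarray:
    """Label of the best-matching prototype for every row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        return np.array([], dtype=object)
    if X.shape[1] != model.p:
        raise ValueError("feature dimension mismatch with the fitted model")
    return np.array([_predict_row(model, x) for x in X], dtype=object)


# ---------------------------------------------------------------------------
# serialization: one self-describing text file per model


_FORMAT = "roundlvq-model"
_VERSION = 1


def _model_to_dict(model: LVQModel) -> dict:
    d = {
        "format": _FORMAT,
        "version": _VERSION,
        "variant": model.variant,
        "config": dataclasses.asdict(model.config),
        "codebook": {
            "vectors": model.codebook.vectors.tolist(),
            "labels": [str(l) for l in model.codebook.labels],
            "per_vector_alpha": (
                None
                if model.codebook.per_vector_alpha is None
                else model.codebook.per_vector_alpha.tolist()
            ),
        },
        "meta": {k: v for k, v in model.meta.items() if k != "history"},
    }
    if model.children is not None:
        d["children"] = {
            str(i): (
                {"kind": "leaf", "label": str(payload)}
                if kind == "leaf"
                else {"kind": "model", "model": _model_to_dict(payload)}
            )
            for i, (kind, payload) in model.children.items()
        }
    return d


def _model_from_dict(d: dict) -> LVQModel:
    if d.get("format") != _FORMAT:
        raise ValueError("not a roundlvq model file")
    cb = d["codebook"]
    codebook = Codebook(
        np.array(cb["vectors"], dtype=float),
        np.array(cb["labels"], dtype=object),
        None if cb["per_vector_alpha"] is None else np.array(cb["per_vector_alpha"]),
    )
    config = LVQConfig(**d["config"])
    children = None
    if "children" in d:
        children = {}
        for key, val in d["children"].items():
            if val["kind"] == "leaf":
                children[int(key)] = ("leaf", val["label"])
            else:
                children[int(key)] = ("model", _model_from_dict(val["model"]))
    return LVQModel(
        codebook=codebook,
        config=config,
        variant=d["variant"],
        children=children,
        meta=d.get("meta", {}),
    )


def save_model(model: LVQModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_model_to_dict(model), indent=1))


def load_model(path: str | Path) -> LVQModel:
    return _model_from_dict(json.loads(Path(path).read_text()))
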