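"""Paired one-vs-all classifiers per VAD dimension, decision-table fusion,
and evaluation metrics.

Each emotion dimension (valence, arousal, dominance) gets two binary
recurrent-network classifiers: an upper-level one (targets: positive
valence, active arousal, *low* dominance — the inverted dominance semantics
of the source scheme are preserved deliberately) and a lower-level one
(negative valence, passive arousal, high dominance).  A fragment is labelled
``target`` when the network's raw tanh output strictly exceeds the decision
threshold (default 0; ties fall to ``outlier``).

The two binary labels fuse into a four-way dimension outcome::

    upper=target,  lower=target   ->  error
    upper=target,  lower=outlier  ->  upper
    upper=outlier, lower=target   ->  lower
    upper=outlier, lower=outlier  ->  neutral

Evaluation reports one-vs-rest binary metrics per (dimension, level) —
computed both on the fused final decision and on the stage-1 classifier
labels — a per-dimension decision accuracy, and 3x3 confusion matrices over
{upper, neutral, lower} with error outcomes tallied in a separate column
(rows normalized to percentages).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import PreconditionError, RangeError, SchemaError
from .io import DIMENSIONS, EmotionalState
from .rnn import LMConfig, LMState, RNNParams, as_static_sequences, predict_last, train

__all__ = [
    "OneVsAllClassifier",
    "DimensionDecision",
    "VADDecision",
    "VADModel",
    "classify_level",
    "final_decision",
    "classify_vad",
    "train_vad_model",
    "MetricsReport",
    "evaluate",
]

_TARGET_SEMANTICS = {
    ("valence", "upper"): "positive valence",
    ("valence", "lower"): "negative valence",
    ("arousal", "upper"): "active arousal",
    ("arousal", "lower"): "passive arousal",
    # inverted on purpose: the upper-level classifier targets LOW dominance
    ("dominance", "upper"): "low dominance",
    ("dominance", "lower"): "high dominance",
}


@dataclass
class OneVsAllClassifier:
    dimension: str
    level: str  # upper | lower
    rnn: RNNParams
    threshold: float = 0.0

    def __post_init__(self):
        if self.dimension not in DIMENSIONS:
            raise SchemaError(f"unknown dimension {self.dimension!r}")
        if self.level not in ("upper", "lower"):
            raise SchemaError("classifier level must be upper or lower")
        if not (-1.0 < self.threshold < 1.0):
            raise RangeError("threshold must lie in (-1, 1)")

    @property
    def target_semantics(self) -> str:
        return _TARGET_SEMANTICS[(self.dimension, self.level)]

    def score(self, features: np.ndarray) -> np.ndarray:
        """Raw tanh output(s) for one or more feature vectors."""
        return predict_last(self.rnn, as_static_sequences(features))


def classify_level(clf: OneVsAllClassifier, features: np.ndarray):
    """Binary label(s) of feature vector(s): 'target' iff raw > threshold.

    Returns ``(label, raw)`` for one vector, ``(labels, raws)`` arrays for a
    matrix of vectors.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    if F.shape[1] != clf.rnn.n_input:
        raise SchemaError(
            f"feature length {F.shape[1]} != classifier input {clf.rnn.n_input}"
        )
    raw = clf.score(F)
    labels = np.where(raw > clf.threshold, "target", "outlier")
    if np.asarray(features).ndim == 1:
        return str(labels[0]), float(raw[0])
    return labels, raw


def final_decision(upper_label: str, lower_label: str) -> str:
    """Fuse the two one-vs-all labels into the dimension outcome."""
    for lab in (upper_label, lower_label):
        if lab not in ("target", "outlier"):
            raise SchemaError(f"label must be target/outlier, got {lab!r}")
    if upper_label == "target":
        return "error" if lower_label == "target" else "upper"
    return "lower" if lower_label == "target" else "neutral"


@dataclass(frozen=True)
class DimensionDecision:
    outcome: str  # upper | lower | neutral | error
    upper_raw: float
    lower_raw: float


@dataclass(frozen=True)
class VADDecision:
    valence: DimensionDecision
    arousal: DimensionDecision
    dominance: DimensionDecision

    def outcome(self, dimension: str) -> str:
        return getattr(self, dimension).outcome


@dataclass
class VADModel:
    """Six one-vs-all classifiers: (upper, lower) per dimension."""

    classifiers: dict[tuple[str, str], OneVsAllClassifier]

    def __post_init__(self):
        for dim in DIMENSIONS:
            for level in ("upper", "lower"):
                if (dim, level) not in self.classifiers:
                    raise SchemaError(f"missing classifier for ({dim}, {level})")

    def pair(self, dimension: str):
        return self.classifiers[(dimension, "upper")], self.classifiers[(dimension, "lower")]


def classify_vad(features: np.ndarray, model: VADModel) -> VADDecision | list[VADDecision]:
    """Classify feature vector(s) along all three dimensions."""
    single = np.asarray(features).ndim == 1
    F = np.atleast_2d(np.asarray(features, dtype=float))
    per_dim = {}
    for dim in DIMENSIONS:
        up, lo = model.pair(dim)
        up_labels, up_raw = classify_level(up, F)
        lo_labels, lo_raw = classify_level(lo, F)
        per_dim[dim] = [
            DimensionDecision(final_decision(u, l), float(ur), float(lr))
            for u, l, ur, lr in zip(np.atleast_1d(up_labels), np.atleast_1d(lo_labels),
                                    np.atleast_1d(up_raw), np.atleast_1d(lo_raw))
        ]
    decisions = [
        VADDecision(per_dim["valence"][i], per_dim["arousal"][i], per_dim["dominance"][i])
        for i in range(F.shape[0])
    ]
    return decisions[0] if single else decisions


def train_vad_model(
    features: np.ndarray,
    states: Sequence[EmotionalState],
    n_hidden: int = 80,
    config: LMConfig = LMConfig(),
    seed: int = 0,
    threshold: float = 0.0,
) -> tuple[VADModel, dict[tuple[str, str], LMState]]:
    """Train the six one-vs-all networks on labelled fragment features.

    For each (dimension, level) classifier the target class consists of the
    fragments whose true level equals the classifier's level; everything
    else — including neutral fragments — is the outlier class.  Targets are
    coded +1 (target) / -1 (outlier) to match the tanh output range.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    if F.shape[0] != len(states):
        raise SchemaError("features/states length mismatch")
    X = as_static_sequences(F)
    classifiers = {}
    histories = {}
    for k, dim in enumerate(DIMENSIONS):
        for j, level in enumerate(("upper", "lower")):
            y = np.array(
                [1.0 if s.level(dim) == level else -1.0 for s in states]
            )
            params = RNNParams.init(
                F.shape[1], n_hidden=n_hidden, seed=seed * 100 + k * 10 + j
            )
            trained, state = train(params, X, y, config=config)
            classifiers[(dim, level)] = OneVsAllClassifier(dim, level, trained, threshold)
            histories[(dim, level)] = state
    return VADModel(classifiers), histories


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-level binary metrics, per-dimension decision accuracy, and
    Table-style confusion matrices (percent, rows = actual level)."""

    per_level: pd.DataFrame  # dimension, level, basis, accuracy..f1 (%)
    decision_accuracy: dict[str, float]  # dimension -> %
    confusion: dict[str, pd.DataFrame]  # dimension -> rows {upper,neutral,lower} x cols {...,error}
    n: int = 0


def _binary_metrics(pred_pos: np.ndarray, true_pos: np.ndarray) -> dict[str, float]:
    tp = int(np.sum(pred_pos & true_pos))
    tn = int(np.sum(~pred_pos & ~true_pos))
    fp = int(np.sum(pred_pos & ~true_pos))
    fn = int(np.sum(~pred_pos & true_pos))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {
        "accuracy": 100 * acc, "precision": 100 * prec, "recall": 100 * rec,
        "specificity": 100 * spec, "f1": 100 * f1,
    }


def evaluate(
    predictions: Sequence[VADDecision],
    truth: Sequence[EmotionalState],
    threshold: float = 0.0,
) -> MetricsReport:
    """Score predicted decisions against true states.

    Binary per-level metrics are computed one-vs-rest on two bases: the
    fused final decision (``basis='decision'``) and the raw stage-1
    classifier labels (``basis='stage1'``, raw output > threshold).
    Decision accuracy per dimension is the fraction of fragments whose fused
    outcome equals the true level; ``error`` outcomes never match and are
    reported in the confusion matrices' separate error column.
    """
    if len(predictions) != len(truth):
        raise SchemaError("predictions/truth length mismatch")
    if len(predictions) == 0:
        raise RangeError("empty evaluation set")

    rows = []
    decision_acc = {}
    confusion = {}
    for dim in DIMENSIONS:
        outcomes = np.array([p.outcome(dim) for p in predictions])
        true_lv = np.array([t.level(dim) for t in truth])
        decision_acc[dim] = 100 * float(np.mean(outcomes == true_lv))
        for level in ("upper", "lower"):
            rows.append(
                {"dimension": dim, "level": level, "basis": "decision",
                 **_binary_metrics(outcomes == level, true_lv == level)}
            )
            raws = np.array(
                [getattr(p, dim).upper_raw if level == "upper" else getattr(p, dim).lower_raw
                 for p in predictions]
            )
            rows.append(
                {"dimension": dim, "level": level, "basis": "stage1",
                 **_binary_metrics(raws > threshold, true_lv == level)}
            )
        cm = pd.DataFrame(
            0.0, index=["upper", "neutral", "lower"],
            columns=["upper", "neutral", "lower", "error"],
        )
        for actual in cm.index:
            mask = true_lv == actual
            if not mask.any():
                cm.loc[actual] = np.nan
                continue
            for pred_col in cm.columns:
                cm.loc[actual, pred_col] = 100 * float(
                    np.mean(outcomes[mask] == pred_col)
                )
        confusion[dim] = cm
    return MetricsReport(
        per_level=pd.DataFrame(rows),
        decision_accuracy=decision_acc,
        confusion=confusion,
        n=len(predictions),
    )
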