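"""Max-margin classification and the performance measures reported per run.

Hand imagery is the positive class and foot imagery the negative class
throughout: sensitivity = TP / (TP + FN) is the hand recognition rate and
specificity = TN / (TN + FP) the foot recognition rate; accuracy is the
percentage of correct predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import FOOT, HAND, LABELS

__all__ = ["ConfusionCounts", "EvalResult", "UndefinedMetricError",
           "train_classifier", "predict", "confusion",
           "accuracy", "sensitivity", "specificity"]


class UndefinedMetricError(ZeroDivisionError):
    """A performance measure's denominator is zero for these counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int
    positive_class: str = HAND
    negative_class: str = FOOT

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def swapped(self) -> "ConfusionCounts":
        """Counts with the positive/negative role of the classes exchanged."""
        return ConfusionCounts(tp=self.tn, fn=self.fp, tn=self.tp, fp=self.fn,
                               positive_class=self.negative_class,
                               negative_class=self.positive_class)


@dataclass
class EvalResult:
    """One evaluated configuration: metrics plus the settings that produced it."""

    accuracy: float
    sensitivity: float
    specificity: float
    confusion: ConfusionCounts
    subset: tuple[str, ...] | str = "sensor"
    m_pairs: int = 1
    band: str = "broadband"
    extra: dict = field(default_factory=dict)

    def row(self) -> dict:
        subset = self.subset if isinstance(self.subset, str) else "+".join(self.subset)
        return {"band": self.band, "subset": subset, "n_rois": 0 if isinstance(self.subset, str)
                else len(self.subset), "m_pairs": self.m_pairs,
                "accuracy": round(self.accuracy, 2), "sensitivity": round(self.sensitivity, 2),
                "specificity": round(self.specificity, 2),
                "tp": self.confusion.tp, "fn": self.confusion.fn,
                "tn": self.confusion.tn, "fp": self.confusion.fp}


def train_classifier(features: np.ndarray, labels: np.ndarray, c: float = 1.0,
                     kernel: str = "linear") -> Pipeline:
    """Fit a standardized max-margin (SVM) classifier on training features."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    if len(set(labels)) < 2:
        raise ValueError("training data must contain both classes")
    model = Pipeline([("scale", StandardScaler()),
                      ("svm", SVC(kernel=kernel, C=c))])
    model.fit(features, labels.astype(str))
    return model


def predict(model: Pipeline, features: np.ndarray) -> np.ndarray:
    """Predicted labels, one per feature row."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != model.named_steps["scale"].n_features_in_:
        raise ValueError(
            f"features must be (n, {model.named_steps['scale'].n_features_in_}), "
            f"got {features.shape}")
    return model.predict(features).astype(object)


def confusion(true_labels: np.ndarray, predicted_labels: np.ndarray) -> ConfusionCounts:
    """Count TP/FN/TN/FP with hand as the positive class."""
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    unknown = (set(true_labels) | set(predicted_labels)) - set(LABELS)
    if unknown:
        raise ValueError(f"unknown label values: {sorted(map(str, unknown))}")
    tp = int(np.sum((true_labels == HAND) & (predicted_labels == HAND)))
    fn = int(np.sum((true_labels == HAND) & (predicted_labels == FOOT)))
    tn = int(np.sum((true_labels == FOOT) & (predicted_labels == FOOT)))
    fp = int(np.sum((true_labels == FOOT) & (predicted_labels == HAND)))
    return ConfusionCounts(tp, fn, tn, fp)


def accuracy(conf: ConfusionCounts) -> float:
    """Percent correct: 100 * (TP + TN) / total."""
    if conf.total == 0:
        raise UndefinedMetricError("accuracy undefined with zero evaluated trials")
    return 100.0 * (conf.tp + conf.tn) / conf.total


def sensitivity(conf: ConfusionCounts) -> float:
    """Hand (positive-class) recognition rate: 100 * TP / (TP + FN)."""
    if conf.tp + conf.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive-class trials")
    return 100.0 * conf.tp / (conf.tp + conf.fn)


def specificity(conf: ConfusionCounts) -> float:
    """Foot (negative-class) recognition rate: 100 * TN / (TN + FP)."""
    if conf.tn + conf.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative-class trials")
    return 100.0 * conf.tn / (conf.tn + conf.fp)
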