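"""Thresholding of per-plan anomaly scores and the evaluation metric suite.

Convention: a plan is flagged abnormal when its score is **>= threshold**,
so the recall-1 threshold can sit exactly at the minimum abnormal score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "ScoreSet",
    "ConfusionTable",
    "Metrics",
    "select_threshold_tpr1",
    "select_threshold_quantile",
    "classify",
    "compute_metrics",
    "roc_and_auc",
]


def _as_binary_labels(labels) -> np.ndarray:
    """Normalize labels to a 0/1 int array (1 = abnormal)."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return np.array([1 if str(v) == "abnormal" else 0 for v in arr])
    return arr.astype(int)


@dataclass
class ScoreSet:
    """Per-plan scores with optional labels, threshold and calls."""

    scores: np.ndarray
    labels: np.ndarray | None = None
    threshold: float | None = None
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.labels is not None:
            self.labels = _as_binary_labels(self.labels)
        if self.flags is not None and self.threshold is None:
            raise ValueError("flags require a threshold")

    def with_threshold(self, threshold: float) -> "ScoreSet":
        return ScoreSet(
            scores=self.scores,
            labels=self.labels,
            threshold=float(threshold),
            flags=classify(self.scores, threshold),
        )


@dataclass(frozen=True)
class ConfusionTable:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class Metrics:
    """The evaluation metric suite; ``anomalies`` counts flagged plans (TP+FP)."""

    accuracy: float
    precision: float
    recall: float
    fpr: float
    f1: float
    anomalies: int
    confusion: ConfusionTable
    auc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "fpr": self.fpr,
            "f1": self.f1,
            "anomalies": self.anomalies,
            "TP": self.confusion.TP,
            "FP": self.confusion.FP,
            "TN": self.confusion.TN,
            "FN": self.confusion.FN,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_text(self) -> str:
        return "\n".join(f"{k}\t{v}" for k, v in self.to_dict().items())


def select_threshold_tpr1(scores, labels) -> float:
    """Largest threshold with recall 1: the minimum abnormal score.

    Under the >= flagging convention this guarantees every abnormal plan is
    called and, among all recall-1 thresholds, minimizes the false-positive
    rate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _as_binary_labels(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    abn = scores[labels == 1]
    if abn.size == 0:
        raise ValueError("TPR==1 policy undefined without abnormal labels")
    return float(abn.min())


def select_threshold_quantile(scores, q: float) -> float:
    """Empirical q-quantile of the scores (linear interpolation)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty scores")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    return float(np.quantile(scores, q))


def classify(scores, threshold: float) -> np.ndarray:
    """Boolean calls: score >= threshold means abnormal."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(scores, dtype=float) >= threshold


def compute_metrics(flags, labels) -> Metrics:
    """Confusion-table statistics (AUC left unset; see :func:`roc_and_auc`)."""
    flags = np.asarray(flags, dtype=bool)
    labels = _as_binary_labels(labels)
    if flags.shape != labels.shape:
        raise ValueError("flags and labels must have equal length")
    tp = int(np.sum(flags & (labels == 1)))
    fp = int(np.sum(flags & (labels == 0)))
    tn = int(np.sum(~flags & (labels == 0)))
    fn = int(np.sum(~flags & (labels == 1)))
    conf = ConfusionTable(TP=tp, FP=fp, TN=tn, FN=fn)

    n = conf.n
    accuracy = (tp + tn) / n if n else 0.0
    if tp + fp == 0:
        warnings.warn("no plans flagged; precision defined as 0", UserWarning)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    fpr = fp / (fp + tn) if (fp + tn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return Metrics(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        fpr=fpr,
        f1=f1,
        anomalies=tp + fp,
        confusion=conf,
    )


def metrics_from_confusion(conf: ConfusionTable) -> Metrics:
    """Same statistics computed directly from counts."""
    flags = np.array([True] * (conf.TP + conf.FP) + [False] * (conf.TN + conf.FN))
    labels = np.array(
        [1] * conf.TP + [0] * conf.FP + [0] * conf.TN + [1] * conf.FN
    )
    return compute_metrics(flags, labels)


def roc_and_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC point list over all distinct thresholds and the trapezoid AUC.

    With half-credit for ties the trapezoid area equals the Mann-Whitney
    statistic P(score_abn > score_norm) + 0.5 * P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _as_binary_labels(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def roc_to_csv(points: list[tuple[float, float]], path: str | Path) -> None:
    lines = ["fpr,tpr"] + [f"{f},{t}" for f, t in points]
    Path(path).write_text("\n".join(lines) + "\n")
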