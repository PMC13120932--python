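"""Evaluation metrics for the binary Normal-vs-OSCC task.

The positive class is OSCC throughout.  Metrics are reported as percentages
to two decimal places, matching the convention of published benchmark tables
for this task.  Degenerate denominators (e.g. precision with no positive
predictions) return ``None`` — an explicit undefined marker — rather than 0,
so evaluation bugs surface instead of hiding in averages.

AUC is computed with the tie-aware Mann-Whitney rank statistic, which equals
the trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "accuracy",
    "precision",
    "recall",
    "f1",
    "auc",
    "evaluate",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Counts for binary classification; positive class = OSCC."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn}


@dataclass
class MetricReport:
    """Percentages in [0, 100]; undefined values are None."""

    acc: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    auc: float | None
    confusion: ConfusionMatrix | None = None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        out = {}
        for key in ("acc", "precision", "recall", "f1", "auc"):
            v = getattr(self, key)
            out[key] = None if v is None else round(v, ndigits)
        return out

    def to_json(self) -> str:
        d = dict(self.rounded())
        d["confusion"] = self.confusion.as_dict() if self.confusion else None
        return json.dumps(d, indent=2)


def _validate_binary(labels: np.ndarray, name: str) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return labels.astype(int)


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Confusion counts; label 1 = OSCC (positive), 0 = Normal."""
    y = _validate_binary(true_labels, "true_labels")
    p = _validate_binary(predicted_labels, "predicted_labels")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def accuracy(cm: ConfusionMatrix) -> float | None:
    if cm.total == 0:
        logger.warning("accuracy undefined: empty sample set")
        return None
    return 100.0 * (cm.tp + cm.tn) / cm.total


def precision(cm: ConfusionMatrix) -> float | None:
    denom = cm.tp + cm.fp
    if denom == 0:
        logger.warning("precision undefined: no positive predictions")
        return None
    return 100.0 * cm.tp / denom


def recall(cm: ConfusionMatrix) -> float | None:
    denom = cm.tp + cm.fn
    if denom == 0:
        logger.warning("recall undefined: no positive samples")
        return None
    return 100.0 * cm.tp / denom


def f1(precision_pct: float | None, recall_pct: float | None) -> float | None:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if precision_pct is None or recall_pct is None:
        return None
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def auc(true_labels, scores) -> float | None:
    """Area under the empirical ROC curve, in percent.

    Tie-aware rank (Mann-Whitney) formulation: with midranks R_i of the
    positive scores among all scores,
    AUC = (sum(R_pos) - n_pos(n_pos+1)/2) / (n_pos * n_neg).
    """
    y = _validate_binary(true_labels, "true_labels")
    scores = np.asarray(scores, dtype=np.float64)
    if y.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        logger.warning("AUC undefined: only one class present")
        return None
    ranks = rankdata(scores)  # midranks for ties
    stat = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return 100.0 * stat / (n_pos * n_neg)


def evaluate(true_labels, scores, threshold: float = 0.5) -> MetricReport:
    """Full metric report from OSCC probabilities; predict OSCC if score >= threshold."""
    y = _validate_binary(true_labels, "true_labels")
    scores = np.asarray(scores, dtype=np.float64)
    preds = (scores >= threshold).astype(int)
    cm = confusion(y, preds)
    p = precision(cm)
    r = recall(cm)
    return MetricReport(
        acc=accuracy(cm), precision=p, recall=r, f1=f1(p, r),
        auc=auc(y, scores), confusion=cm,
    )
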