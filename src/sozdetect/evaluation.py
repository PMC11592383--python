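"""Confusion counts and the three headline metrics.

Accuracy = (TP+TN)/(TP+FN+TN+FP) x 100 %
Sensitivity = TP/(TP+FN) x 100 %   (true-positive rate on seizure windows)
Specificity = TN/(TN+FP) x 100 %   (true-negative rate on non-seizure windows)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Percent metrics, full precision internally; format to 2 dp for display."""

    accuracy: float
    sensitivity: float
    specificity: float

    def __str__(self) -> str:
        return (
            f"accuracy {self.accuracy:.2f}%  sensitivity {self.sensitivity:.2f}%  "
            f"specificity {self.specificity:.2f}%"
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def confusion(predictions, truths) -> ConfusionCounts:
    """Count TP/TN/FP/FN for binary verdicts against binary labels."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.size == 0:
        raise ValueError("empty prediction set")
    if predictions.shape != truths.shape:
        raise ValueError(
            f"length mismatch: {predictions.shape} predictions vs "
            f"{truths.shape} truths"
        )
    for name, arr in (("predictions", predictions), ("truths", truths)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contain non-binary values")
    tp = int(np.sum((predictions == 1) & (truths == 1)))
    tn = int(np.sum((predictions == 0) & (truths == 0)))
    fp = int(np.sum((predictions == 1) & (truths == 0)))
    fn = int(np.sum((predictions == 0) & (truths == 1)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy/sensitivity/specificity in percent from confusion counts."""
    if counts.tp + counts.fn == 0:
        raise ValueError("sensitivity undefined: no positive windows (TP+FN=0)")
    if counts.tn + counts.fp == 0:
        raise ValueError("specificity undefined: no negative windows (TN+FP=0)")
    return MetricsReport(
        accuracy=100.0 * (counts.tp + counts.tn) / counts.total,
        sensitivity=100.0 * counts.tp / (counts.tp + counts.fn),
        specificity=100.0 * counts.tn / (counts.tn + counts.fp),
    )
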