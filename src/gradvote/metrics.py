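"""Classification metrics: accuracy, precision, recall, F1, ROC and AUC.

Probabilities are cut at a threshold (0.5 by default, with >= mapping to
class 1) for the confusion-count metrics; the ROC curve is built from
thresholds at every distinct score and its area computed by the
trapezoidal rule, which equals the probability that a random positive
outscores a random negative (ties counted half).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve

__all__ = ["MetricsReport", "classification_metrics", "roc_auc", "compute_report"]


@dataclass
class MetricsReport:
    """All evaluation metrics for one fitted ensemble on one split."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    roc_points: list[tuple[float, float]]
    threshold: float = 0.5
    degenerate: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["roc_points"] = [list(p) for p in self.roc_points]
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def roc_to_csv(self, path: str | Path) -> None:
        lines = ["fpr,tpr"] + [f"{fpr:.10g},{tpr:.10g}" for fpr, tpr in self.roc_points]
        Path(path).write_text("\n".join(lines) + "\n")


def classification_metrics(
    y_true, y_prob, threshold: float = 0.5
) -> tuple[float, float, float, float, dict]:
    """Confusion-count metrics at a probability threshold.

    Returns (accuracy, precision, recall, f1, degenerate_flags). Precision
    is defined as 0 when nothing is predicted positive, and recall as 0
    when there are no positives; each case is flagged rather than raised.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(y_prob, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    pred = (p >= threshold).astype(int)

    tp = int(np.sum((y == 1) & (pred == 1)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    tn = int(np.sum((y == 0) & (pred == 0)))

    degenerate: dict = {}
    accuracy = (tp + tn) / y.size
    if tp + fp == 0:
        precision = 0.0
        degenerate["no_predicted_positives"] = True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        degenerate["no_positives"] = True
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f1, degenerate


def roc_auc(y_true, y_prob) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) and trapezoidal AUC.

    Thresholds at every distinct score in descending order; the curve is
    anchored at (0, 0) and (1, 1) and tied scores share one step. Raises
    on single-class input, where the curve is undefined.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(y_prob, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC/AUC undefined: only one class present")
    fpr, tpr, _ = roc_curve(y, p, drop_intermediate=False)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    fpr_arr = np.array([q[0] for q in points])
    tpr_arr = np.array([q[1] for q in points])
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return points, auc


def compute_report(y_true, y_prob, threshold: float = 0.5) -> MetricsReport:
    """Full MetricsReport for one label/probability pair."""
    accuracy, precision, recall, f1, degenerate = classification_metrics(
        y_true, y_prob, threshold
    )
    points, auc = roc_auc(y_true, y_prob)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        auc=auc,
        roc_points=points,
        threshold=threshold,
        degenerate=degenerate,
    )
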