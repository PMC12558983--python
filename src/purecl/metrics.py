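"""Classification metrics derived from a confusion matrix.

Macro (unweighted) averaging is used for precision/recall/F1 so that rare
classes weigh as much as common ones.  Per-class "accuracy" in the
per-class table is the class-conditional recall (diagonal over row sum),
the convention used in per-class disease-classification tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClassificationMetrics", "confusion_matrix", "metrics_from_confusion"]


@dataclass
class ClassificationMetrics:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray
    per_class: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Counts C[i, j] = #{true i predicted j}."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def metrics_from_confusion(cm: np.ndarray,
                           class_names: list[str] | None = None) -> ClassificationMetrics:
    cm = np.asarray(cm)
    k = cm.shape[0]
    if class_names is None:
        class_names = [f"class_{i}" for i in range(k)]
    diag = np.diag(cm).astype(float)
    row = cm.sum(axis=1).astype(float)   # true counts
    col = cm.sum(axis=0).astype(float)   # predicted counts
    total = cm.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(row > 0, diag / row, 0.0)
        precision = np.where(col > 0, diag / col, 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    per_class = pd.DataFrame({
        "class": class_names,
        "accuracy": recall,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    })
    return ClassificationMetrics(
        accuracy=float(diag.sum() / total) if total else 0.0,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        confusion=cm,
        per_class=per_class,
    )
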