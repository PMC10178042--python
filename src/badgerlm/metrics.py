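"""Multiclass confusion matrix and macro-averaged evaluation metrics.

Per-class metrics use the one-vs-rest convention: for class k, TP is the
diagonal entry, FP the rest of column k, FN the rest of row k, TN everything
else. Precision = TP/(TP+FP), sensitivity = TP/(TP+FN), F1 their harmonic
mean. The per-class "accuracy" column reported by evaluation tables in this
domain equals the per-class sensitivity (recall); the strict one-vs-rest
(TP+TN)/total variant is exposed separately as ``ovr_accuracy``. The overall
("All") row macro-averages the per-class values, with overall accuracy the
global fraction of correct predictions.

Display convention: percentages to 2 decimals, F1 to 4; internal values are
kept at full precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.class_names) != counts.shape[0]:
            raise ValueError("class_names length must match matrix size")
        object.__setattr__(self, "counts", counts)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_names),
                            columns=list(self.class_names))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="true\\pred")


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and macro-averaged metrics; fractions internally (not %)."""

    class_names: tuple[str, ...]
    accuracy: np.ndarray  # per-class, equals sensitivity by table convention
    precision: np.ndarray
    sensitivity: np.ndarray
    f1: np.ndarray
    ovr_accuracy: np.ndarray  # strict one-vs-rest (TP+TN)/total
    overall_accuracy: float  # macro = mean per-class accuracy
    overall_precision: float
    overall_sensitivity: float
    overall_f1: float
    overall_accuracy_global: float  # correct / total

    def to_frame(self, model: str = "") -> pd.DataFrame:
        """Table-shaped frame: All row then per-class rows, % to 2 dp, F1 to 4 dp."""
        rows = [
            {
                "Model": model,
                "Class": "All",
                "Accuracy": round(100 * self.overall_accuracy, 2),
                "Precision": round(100 * self.overall_precision, 2),
                "Sensitivity": round(100 * self.overall_sensitivity, 2),
                "F1": round(self.overall_f1, 4),
            }
        ]
        for i, name in enumerate(self.class_names):
            rows.append(
                {
                    "Model": model,
                    "Class": name,
                    "Accuracy": round(100 * self.accuracy[i], 2),
                    "Precision": round(100 * self.precision[i], 2),
                    "Sensitivity": round(100 * self.sensitivity[i], 2),
                    "F1": round(self.f1[i], 4),
                }
            )
        return pd.DataFrame(rows)

    def write_csv(self, path, model: str = "") -> None:
        self.to_frame(model).to_csv(path, index=False)


def confusion(y_true, y_pred, n_classes: int, class_names=None) -> ConfusionMatrix:
    """Tally counts[i, j] = #{true = i, predicted = j}."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    if class_names is None:
        class_names = tuple(str(k) for k in range(n_classes))
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; reporting 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest precision/sensitivity/F1 per class plus macro overall row."""
    C = cm.counts
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    K = cm.n_classes
    total = cm.total
    precision = np.empty(K)
    sensitivity = np.empty(K)
    f1 = np.empty(K)
    ovr_acc = np.empty(K)
    for k in range(K):
        tp = float(C[k, k])
        fp = float(C[:, k].sum() - C[k, k])
        fn = float(C[k, :].sum() - C[k, k])
        tn = float(total - tp - fp - fn)
        precision[k] = _safe_div(tp, tp + fp, f"precision of class {cm.class_names[k]}")
        sensitivity[k] = _safe_div(tp, tp + fn, f"sensitivity of class {cm.class_names[k]}")
        f1[k] = _safe_div(
            2 * precision[k] * sensitivity[k], precision[k] + sensitivity[k],
            f"F1 of class {cm.class_names[k]}",
        )
        ovr_acc[k] = (tp + tn) / total
    overall = macro_overall(precision, sensitivity, f1)
    return MetricsReport(
        class_names=cm.class_names,
        accuracy=sensitivity.copy(),
        precision=precision,
        sensitivity=sensitivity,
        f1=f1,
        ovr_accuracy=ovr_acc,
        overall_accuracy=float(sensitivity.mean()),
        overall_precision=overall["precision"],
        overall_sensitivity=overall["sensitivity"],
        overall_f1=overall["f1"],
        overall_accuracy_global=float(np.trace(C)) / total,
    )


def macro_overall(precision, sensitivity, f1) -> dict[str, float]:
    """Unweighted means of per-class precision/sensitivity/F1 (the "All" row)."""
    return {
        "precision": float(np.mean(precision)),
        "sensitivity": float(np.mean(sensitivity)),
        "f1": float(np.mean(f1)),
    }


def evaluate(y_true, y_pred, n_classes: int, class_names=None) -> MetricsReport:
    """Convenience: confusion matrix + per-class metrics in one call."""
    return per_class_metrics(confusion(y_true, y_pred, n_classes, class_names))
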