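"""Classification metrics: confusion matrices, per-taxon precision/recall.

Precision for class x is TP_x / (TP_x + FP_x): of everything classified as
x, the fraction that truly is x. Recall for class x is TP_x / (TP_x + FN_x):
of everything truly x, the fraction recovered. Accuracy is the proportion of
correct classifications over all evaluated units (images or specimens).
Macro precision/recall are unweighted means over classes, reported with 95%
t-intervals across the per-class values. A class that never receives a
prediction has undefined precision; it is reported as 0 with an explicit
flag so macro means stay conservative and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "precision_recall",
    "size_precision_table",
]


@dataclass
class ConfusionMatrix:
    """counts[i, j] = units of true class i predicted as class j."""

    counts: np.ndarray
    class_labels: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        C = len(self.class_labels)
        if self.counts.shape != (C, C):
            raise ValueError("counts must be C x C for C class labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_labels,
                            columns=self.class_labels)


@dataclass
class MetricsReport:
    accuracy: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    macro_precision: float
    macro_recall: float
    ci95_precision: tuple[float, float]
    ci95_recall: tuple[float, float]
    undefined_precision_flags: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "per_class_precision": [float(v) for v in self.per_class_precision],
            "per_class_recall": [float(v) for v in self.per_class_recall],
            "ci95_precision": list(self.ci95_precision),
            "ci95_recall": list(self.ci95_recall),
            "undefined_precision": [bool(v) for v in self.undefined_precision_flags],
        }


def confusion(true_labels, predicted_labels, class_labels) -> ConfusionMatrix:
    """Tally a confusion matrix over an explicit, ordered class list."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    index = {lab: i for i, lab in enumerate(class_labels)}
    C = len(class_labels)
    counts = np.zeros((C, C), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside class list: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(class_labels))


def _t_interval(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    m = float(values.mean())
    if len(values) < 2 or np.allclose(values.std(ddof=1), 0):
        return (m, m)
    half = stats.t.ppf(0.975, len(values) - 1) * stats.sem(values)
    return (m - float(half), m + float(half))


def precision_recall(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class precision/recall, accuracy and macro means from a matrix."""
    counts = cm.counts
    if counts.sum() == 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(counts).astype(float)
    predicted = counts.sum(axis=0).astype(float)  # TP + FP per class
    actual = counts.sum(axis=1).astype(float)  # TP + FN per class
    undefined = predicted == 0
    precision = np.where(undefined, 0.0, tp / np.where(predicted == 0, 1, predicted))
    recall = np.where(actual == 0, 0.0, tp / np.where(actual == 0, 1, actual))
    accuracy = float(tp.sum() / counts.sum())
    return MetricsReport(
        accuracy=accuracy,
        per_class_precision=precision,
        per_class_recall=recall,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        ci95_precision=_t_interval(precision),
        ci95_recall=_t_interval(recall),
        undefined_precision_flags=undefined,
    )


def size_precision_table(
    taxa: list,
    per_taxon_precision,
    per_taxon_mean_size_mm2,
    training_size: int | None = None,
    orders: list | None = None,
) -> pd.DataFrame:
    """Join per-taxon precision with mean body size for size-effect analysis."""
    precision = list(per_taxon_precision)
    sizes = list(per_taxon_mean_size_mm2)
    if not (len(taxa) == len(precision) == len(sizes)):
        raise ValueError("taxa, precision and size lists must align")
    if orders is not None and len(orders) != len(taxa):
        raise ValueError("orders list must align with taxa")
    table = pd.DataFrame(
        {
            "taxon": list(taxa),
            "order": orders if orders is not None else [""] * len(taxa),
            "mean_size_mm2": sizes,
            "precision": precision,
        }
    )
    table["training_size"] = training_size
    return table
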