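"""Confusion matrices and the reported classification metrics.

Conventions used throughout:

* rows are ground truth, columns are predictions, in the fixed class order
  NSR, LBBB, RBBB, APC, PVC (or any explicit ``class_order``);
* the per-predicted-class *misclassification error* is column-wise:
  ``100 * (column total - diagonal) / column total`` — equivalently
  ``100 - PPV`` of that predicted class;
* binary normal/abnormal metrics follow the usual definitions
  Acc=(TP+TN)/total, Se=TP/(TP+FN), Sp=TN/(TN+FP), Pp=TP/(TP+FP),
  reported on the 0–100 percent scale;
* display rounding is half-up to two decimals; internal values keep full
  precision.  A ratio with a zero denominator is reported as ``None``
  ("not applicable"), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Hashable, Iterable, Sequence

import numpy as np

from .io import ClassLabel

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "misclassification_error",
    "overall_accuracy",
    "binary_metrics",
    "patient_specific_relabel",
    "round_half_up",
    "BUNDLE_BRANCH_NORMAL_RECORDS",
]

#: MIT-BIH records with no sinus rhythm — only bundle-branch beats — whose
#: LBBB/RBBB beats count as that patient's normal rhythm.
BUNDLE_BRANCH_NORMAL_RECORDS: frozenset[str] = frozenset(
    {"109", "111", "118", "124", "207", "214", "232"}
)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention the reported tables use)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows = ground truth, columns = predicted."""

    class_order: tuple[Hashable, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_order", tuple(self.class_order))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index_of(self, label: Hashable) -> int:
        try:
            return self.class_order.index(label)
        except ValueError as exc:
            raise ValueError(f"unknown class {label!r}") from exc

    # ------------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        labels = [getattr(c, "value", c) for c in self.class_order]
        lines = ["truth\\pred," + ",".join(str(l) for l in labels)]
        for lab, row in zip(labels, self.counts):
            lines.append(str(lab) + "," + ",".join(str(int(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        rows = [
            ln.split(",")
            for ln in Path(path).read_text().splitlines()
            if ln.strip()
        ]
        header = [h.strip() for h in rows[0][1:]]
        counts = np.array([[int(v) for v in r[1:]] for r in rows[1:]], dtype=int)
        order = tuple(
            ClassLabel(h) if h in ClassLabel._value2member_map_ else h
            for h in header
        )
        return cls(class_order=order, counts=counts)


@dataclass(frozen=True)
class MetricsReport:
    """Percent-scale metrics; ``None`` marks an undefined (0/0) ratio."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    misclassification_error: dict = field(default_factory=dict)

    def rounded(self, ndigits: int = 2) -> dict:
        def r(v):
            return None if v is None else round_half_up(v, ndigits)

        return {
            "accuracy": r(self.accuracy),
            "sensitivity": r(self.sensitivity),
            "specificity": r(self.specificity),
            "ppv": r(self.ppv),
            "misclassification_error": {
                str(getattr(k, "value", k)): r(v)
                for k, v in self.misclassification_error.items()
            },
        }


def confusion(
    true_labels: Sequence[Hashable],
    predicted_labels: Sequence[Hashable],
    class_order: Iterable[Hashable],
) -> ConfusionMatrix:
    """Tally counts[i][j] = #(truth == class i and prediction == class j)."""
    order = tuple(class_order)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    lookup = {c: i for i, c in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in lookup or p not in lookup:
            raise ValueError(f"label outside class_order: {t!r} / {p!r}")
        counts[lookup[t], lookup[p]] += 1
    return ConfusionMatrix(class_order=order, counts=counts)


def misclassification_error(
    matrix: ConfusionMatrix, predicted_class: Hashable
) -> float | None:
    """Percent of beats *assigned to* a class whose truth differs.

    Column-wise: ``100 * (column total - diagonal) / column total``, i.e.
    ``100 - PPV`` of the predicted class.  ``None`` when nothing was
    assigned to the class.
    """
    j = matrix.index_of(predicted_class)
    col_total = int(matrix.counts[:, j].sum())
    if col_total == 0:
        return None
    return 100.0 * (col_total - int(matrix.counts[j, j])) / col_total


def overall_accuracy(matrix: ConfusionMatrix) -> float:
    """100 * trace / total."""
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(matrix.counts)) / matrix.total


def binary_metrics(
    matrix: ConfusionMatrix, positive_classes: Iterable[Hashable]
) -> MetricsReport:
    """Collapse to positive (abnormal) vs negative and report Acc/Se/Sp/Pp.

    TP counts positives predicted as any positive class; FN positives
    predicted negative; TN/FP likewise for negatives.
    """
    positives = set(positive_classes)
    if not positives or not positives < set(matrix.class_order):
        raise ValueError("positive_classes must be a non-empty proper subset")
    pos_idx = [i for i, c in enumerate(matrix.class_order) if c in positives]
    neg_idx = [i for i, c in enumerate(matrix.class_order) if c not in positives]
    c = matrix.counts
    tp = int(c[np.ix_(pos_idx, pos_idx)].sum())
    fn = int(c[np.ix_(pos_idx, neg_idx)].sum())
    fp = int(c[np.ix_(neg_idx, pos_idx)].sum())
    tn = int(c[np.ix_(neg_idx, neg_idx)].sum())

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return MetricsReport(
        accuracy=ratio(tp + tn, tp + tn + fp + fn),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
    )


def multiclass_report(matrix: ConfusionMatrix) -> dict:
    """Overall accuracy/error plus per-predicted-class error, full precision."""
    errors = {
        c: misclassification_error(matrix, c) for c in matrix.class_order
    }
    acc = overall_accuracy(matrix)
    return {
        "overall_accuracy": acc,
        "overall_error": 100.0 - acc,
        "misclassification_error": errors,
    }


def patient_specific_relabel(
    record_id: str,
    label: ClassLabel,
    bundle_normal_records: Iterable[str] = BUNDLE_BRANCH_NORMAL_RECORDS,
) -> str:
    """Collapse a beat to ``"normal"`` / ``"abnormal"`` per patient context.

    NSR is always normal; APC/PVC always abnormal; LBBB/RBBB count as
    normal only for records whose baseline rhythm is bundle-branch block
    (no sinus beats exist for those patients).
    """
    if label is ClassLabel.NSR:
        return "normal"
    if label in (ClassLabel.LBBB, ClassLabel.RBBB):
        return "normal" if str(record_id) in set(map(str, bundle_normal_records)) else "abnormal"
    return "abnormal"
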