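"""Classification evaluation: confusion counts, macro metrics, one-vs-rest ROC/AUC.

All quantities derive from one-vs-rest confusion counts. For class i, with
TP/TN/FP/FN the one-vs-rest counts:

    accuracy (macro form) = (1/C) Σ_i (TP_i + TN_i) / n
    recall_i    = TP_i / (TP_i + FN_i)
    precision_i = TP_i / (TP_i + FP_i)
    macro F1    = (1/C) Σ_i 2·precision_i·recall_i / (precision_i + recall_i)

The macro one-vs-rest accuracy equals plain fraction-correct for binary
problems but not in general, so both are reported. Precision/recall with an
empty denominator are set to 0 and flagged. ROC curves sweep every unique
score plus the ±∞ endpoints; AUC is trapezoidal, equal to the
concordant-pair (Mann–Whitney) statistic with ties counted half.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, LabelError, UndefinedMetricError


@dataclass
class ConfusionMatrix:
    """C×C count matrix; rows are true classes, columns predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise InvalidParameterError(
                f"confusion matrix must be square, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise InvalidParameterError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def ovr_counts(self, i: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for class i treated one-vs-rest."""
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn


def confusion(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise InvalidParameterError("y_true and y_pred must have the same length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise LabelError(f"{name} contains labels outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


@dataclass
class EvalReport:
    """Full evaluation: confusion matrix, per-class and macro metrics, AUCs."""

    confusion: ConfusionMatrix
    accuracy: float                      # plain fraction-correct
    macro_ovr_accuracy: float            # mean one-vs-rest accuracy
    precision: list[float]
    recall: list[float]
    f1: list[float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class_auc: list[float] | None = None
    macro_auc: float | None = None
    zero_division_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "confusion": self.confusion.counts.tolist(),
            "accuracy": self.accuracy,
            "macro_ovr_accuracy": self.macro_ovr_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "zero_division_flags": self.zero_division_flags,
        }
        if self.per_class_auc is not None:
            d["per_class_auc"] = self.per_class_auc
            d["macro_auc"] = self.macro_auc
        return d

    def write(self, path: str | Path) -> None:
        """Flat key/value text report plus a CSV confusion matrix."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            for key, value in self.to_dict().items():
                if key == "confusion":
                    continue
                fh.write(f"{key}\t{value}\n")
        with open(path.with_suffix(".confusion.csv"), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["true\\pred"] + list(range(self.confusion.n_classes)))
            for i, row in enumerate(self.confusion.counts):
                writer.writerow([i] + row.tolist())


def _safe_div(num: float, den: float, flags: list[str], what: str) -> float:
    if den == 0:
        flags.append(what)
        return 0.0
    return num / den


def classification_metrics(cm: ConfusionMatrix) -> EvalReport:
    """Accuracy, per-class/macro precision, recall and F1 from a confusion matrix."""
    if cm.total == 0:
        raise InvalidParameterError("cannot score an empty confusion matrix")
    C = cm.n_classes
    flags: list[str] = []
    precision, recall, f1, ovr_acc = [], [], [], []
    for i in range(C):
        tp, tn, fp, fn = cm.ovr_counts(i)
        p = _safe_div(tp, tp + fp, flags, f"precision[{i}]")
        r = _safe_div(tp, tp + fn, flags, f"recall[{i}]")
        precision.append(p)
        recall.append(r)
        f1.append(_safe_div(2 * p * r, p + r, flags, f"f1[{i}]"))
        ovr_acc.append((tp + tn) / cm.total)
    return EvalReport(
        confusion=cm,
        accuracy=float(np.trace(cm.counts) / cm.total),
        macro_ovr_accuracy=float(np.mean(ovr_acc)),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(np.mean(precision)),
        macro_recall=float(np.mean(recall)),
        macro_f1=float(np.mean(f1)),
        zero_division_flags=flags,
    )


def roc_curve(y_true_binary: np.ndarray, scores: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) sweeping unique scores plus ±∞ endpoints."""
    y = np.asarray(y_true_binary, dtype=bool)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            "ROC needs at least one positive and one negative sample"
        )
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1], [-np.inf]))
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for j, t in enumerate(thresholds):
        pred_pos = s >= t
        tpr[j] = np.sum(pred_pos & y) / n_pos
        fpr[j] = np.sum(pred_pos & ~y) / n_neg
    return fpr, tpr, thresholds


def auc_from_curve(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def roc_auc_ovr(y_true, probabilities) -> tuple[list[float], float]:
    """One-vs-rest AUC per class and the unweighted macro average.

    ``probabilities`` has one row per sample and one column per class; rows
    must sum to 1 (softmax output).
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    P = np.asarray(probabilities, dtype=np.float64)
    if P.ndim != 2 or len(P) != len(y_true):
        raise InvalidParameterError("probabilities must be (n_samples, n_classes)")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise InvalidParameterError("probability rows must sum to 1")
    aucs = []
    for c in range(P.shape[1]):
        fpr, tpr, _ = roc_curve(y_true == c, P[:, c])
        aucs.append(auc_from_curve(fpr, tpr))
    return aucs, float(np.mean(aucs))


def evaluate_predictions(y_true, probabilities, n_classes: int) -> EvalReport:
    """Full report from ground truth and softmax probabilities."""
    P = np.asarray(probabilities, dtype=np.float64)
    y_pred = P.argmax(axis=1)
    report = classification_metrics(confusion(y_true, y_pred, n_classes))
    try:
        per_class, macro = roc_auc_ovr(y_true, P)
        report.per_class_auc = per_class
        report.macro_auc = macro
    except UndefinedMetricError:
        report.zero_division_flags.append("auc")
    return report
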