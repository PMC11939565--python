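"""Evaluation: confusion matrix, per-class one-vs-rest precision /
recall / F1 with support, macro averages, accuracy, per-class ROC/AUC
and PR/AP curves, and stratified k-fold reporting.

Orientation convention: confusion-matrix rows are true classes, columns
predicted classes. Macro averages are unweighted arithmetic means over
classes; undefined 0/0 metrics are reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import (
    auc,
    average_precision_score,
    confusion_matrix,
    precision_recall_curve,
    roc_curve,
)

from cytomil.data import SplitSpec, stratified_kfold


@dataclass
class MetricsReport:
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float

    def to_frame(self, class_names: list[str] | None = None) -> pd.DataFrame:
        """Classification-report table (one row per class plus Average)."""
        c = len(self.precision)
        names = class_names or [f"class {j}" for j in range(c)]
        rows = [
            {
                "class": names[j],
                "precision": self.precision[j],
                "recall": self.recall[j],
                "f1-score": self.f1[j],
                "support": int(self.support[j]),
            }
            for j in range(c)
        ]
        rows.append(
            {
                "class": "Average",
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1-score": self.macro_f1,
                "support": int(self.support.sum()),
            }
        )
        return pd.DataFrame(rows)


def confusion(y_true, y_pred, num_classes: int = 4) -> np.ndarray:
    """C x C counts; rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    for arr in (y_true, y_pred):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError("labels out of range")
    return confusion_matrix(y_true, y_pred, labels=np.arange(num_classes))


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def per_class_metrics(cm: np.ndarray) -> MetricsReport:
    """One-vs-rest precision/recall/F1 per class from a confusion
    matrix, plus macro averages and overall accuracy."""
    cm = np.asarray(cm)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    support = cm.sum(axis=1)
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        accuracy=accuracy(cm),
    )


def macro_average(values: np.ndarray) -> float:
    """Unweighted arithmetic mean of a per-class metric."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("macro average over zero classes")
    return float(values.mean())


def accuracy(cm: np.ndarray) -> float:
    cm = np.asarray(cm)
    total = cm.sum()
    return float(np.trace(cm) / total) if total else 0.0


def roc_ovr(y_true, scores) -> dict[int, dict]:
    """Per-class one-vs-rest ROC curves and trapezoidal AUC.

    ``scores`` is an (M, C) matrix of class probabilities/scores."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    out = {}
    for j in range(scores.shape[1]):
        fpr, tpr, thr = roc_curve(y_true == j, scores[:, j])
        out[j] = {"fpr": fpr, "tpr": tpr, "thresholds": thr, "auc": float(auc(fpr, tpr))}
    return out


def pr_ovr(y_true, scores) -> dict[int, dict]:
    """Per-class one-vs-rest precision-recall curves and AP (step-wise
    precision-weighted recall increments)."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    out = {}
    for j in range(scores.shape[1]):
        prec, rec, thr = precision_recall_curve(y_true == j, scores[:, j])
        ap = float(average_precision_score(y_true == j, scores[:, j]))
        out[j] = {"precision": prec, "recall": rec, "thresholds": thr, "ap": ap}
    return out


def cross_validate(
    pipeline,
    data: tuple[np.ndarray, np.ndarray],
    k: int = 5,
    seed: int = 0,
    num_classes: int = 4,
) -> list[MetricsReport]:
    """Stratified k-fold evaluation of an estimator with sklearn-style
    ``fit``/``predict``; returns one MetricsReport per fold. Every
    sample is validated exactly once."""
    X, y = data
    y = np.asarray(y, dtype=int)
    folds = stratified_kfold(y, SplitSpec(k=k, seed=seed))
    reports = []
    for val_idx in folds:
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[val_idx] = False
        try:
            est = clone(pipeline)
        except TypeError:
            import copy as _copy

            est = _copy.deepcopy(pipeline)
        est.fit(X[train_mask], y[train_mask])
        pred = est.predict(X[val_idx])
        reports.append(per_class_metrics(confusion(y[val_idx], pred, num_classes)))
    return reports
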