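"""Binary-classification metrics, ROC/AUROC and stratified k-fold CV.

Metrics follow the standard confusion-matrix definitions:
Acc = (TP+TN)/(TP+TN+FP+FN), Sn (recall) = TP/(TP+FN), Sp = TN/(TN+FP),
precision = TP/(TP+FP) and the Matthews correlation coefficient; an MCC with
a zero denominator is defined as 0. AUROC equals the Mann-Whitney statistic
(ties counted half); ROC points use the "score >= threshold is positive"
convention with trapezoidal integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .sequence_io import DataError, SequenceDataset


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    acc: float
    sn: float
    sp: float
    mcc: float
    precision: float
    recall: float
    auroc: float | None = None
    folds: list["MetricsReport"] | None = None

    def as_dict(self) -> dict:
        d = {
            "acc": self.acc, "sn": self.sn, "sp": self.sp, "mcc": self.mcc,
            "precision": self.precision, "recall": self.recall,
        }
        if self.auroc is not None:
            d["auroc"] = self.auroc
        return d


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Count a confusion matrix from 0/1 truth and prediction vectors."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise DataError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Acc/Sn/Sp/MCC/precision/recall from confusion counts (no AUROC)."""
    if c.total == 0:
        raise DataError("cannot compute metrics from all-zero counts")
    acc = (c.TP + c.TN) / c.total
    sn = _safe_div(c.TP, c.TP + c.FN)
    sp = _safe_div(c.TN, c.TN + c.FP)
    precision = _safe_div(c.TP, c.TP + c.FP)
    mcc_den = math.sqrt(
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = (c.TP * c.TN - c.FP * c.FN) / mcc_den if mcc_den > 0 else 0.0
    return MetricsReport(
        acc=acc, sn=sn, sp=sp, mcc=mcc, precision=precision, recall=sn
    )


def roc_auroc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC curve points (FPR, TPR) and the area under it.

    Requires both classes to be present. The returned AUROC equals the
    probability that a random positive outscores a random negative, counting
    ties as one half.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(y_true).size < 2:
        raise DataError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y_true, scores)
    points = np.column_stack([fpr, tpr])
    return points, float(roc_auc_score(y_true, scores))


def kfold_cv(
    trainer: Callable[[SequenceDataset], Callable[[SequenceDataset], np.ndarray]],
    ds: SequenceDataset,
    k: int = 5,
    seed: int = 0,
    positive_label: str = "promoter",
    threshold: float = 0.5,
) -> MetricsReport:
    """Stratified k-fold cross-validation of a training procedure.

    ``trainer`` maps a training dataset to a scoring function (dataset ->
    positive-class probabilities). Folds are stratified with sizes differing
    by at most one; the summary report is the unweighted mean over folds and
    per-fold reports are retained in ``.folds``.
    """
    if k < 2:
        raise DataError(f"k must be >= 2, got {k}")
    labels = ds.labels()
    if any(l is None for l in labels):
        raise DataError("kfold_cv requires a fully labeled dataset")
    y = np.array([1 if l == positive_label else 0 for l in labels])
    for cls, count in zip(*np.unique(y, return_counts=True)):
        if count < k:
            raise DataError(
                f"class {cls} has {count} members, fewer than k={k} folds"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        scorer = trainer(ds.subset(train_idx.tolist()))
        scores = np.asarray(scorer(ds.subset(test_idx.tolist())))
        y_test = y[test_idx]
        rep = compute_metrics(
            confusion_from_predictions(y_test, (scores >= threshold).astype(int))
        )
        _, rep.auroc = roc_auroc(y_test, scores)
        fold_reports.append(rep)
    summary = MetricsReport(
        acc=float(np.mean([r.acc for r in fold_reports])),
        sn=float(np.mean([r.sn for r in fold_reports])),
        sp=float(np.mean([r.sp for r in fold_reports])),
        mcc=float(np.mean([r.mcc for r in fold_reports])),
        precision=float(np.mean([r.precision for r in fold_reports])),
        recall=float(np.mean([r.recall for r in fold_reports])),
        auroc=float(np.mean([r.auroc for r in fold_reports])),
        folds=fold_reports,
    )
    return summary
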