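"""Cross-validated performance evaluation.

Metrics follow the conventions of protein-classifier benchmarking:
sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Acc = (TP+TN)/total, the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 whenever a denominator factor vanishes, plus the ROC
curve and its area. Cross-validation is stratified and seeded; metrics are
pooled (micro-averaged) over the held-out predictions of all folds, so the
confusion counts that feed the formulas sum to the dataset size. Feature
selection runs inside each training fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.metrics import auc as _auc
from sklearn.metrics import confusion_matrix as _confusion_matrix
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

from .sequence_io import LabeledDataset


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def binary_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Sn, Sp, Acc, MCC) from binary confusion counts."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise EvaluationError("all confusion counts are zero")
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return sn, sp, acc, mcc


def roc_auc(scores, truth) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) over all distinct score thresholds, and the AUC.

    ``truth`` is boolean/0-1 with True = positive; ties in score contribute a
    single ROC vertex. AUC is the trapezoidal area, equal to the normalised
    Mann-Whitney U statistic.
    """
    truth = np.asarray(truth).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if truth.all() or not truth.any():
        raise EvaluationError("ROC requires both classes present")
    fpr, tpr, _ = _roc_curve(truth, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_auc(fpr, tpr))


@dataclass
class EvaluationReport:
    """Pooled cross-validation metrics for one tier."""

    acc: float
    sn: float | None = None
    sp: float | None = None
    mcc: float | None = None
    auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None
    per_class_sensitivity: dict[str, float] | None = None
    confusion: ConfusionCounts | None = None
    confusion_matrix: list[list[int]] | None = None
    class_labels: list[str] | None = None
    cv_folds: int = 0
    seed: int = 0
    pooled: bool = True
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "acc": self.acc, "sn": self.sn, "sp": self.sp, "mcc": self.mcc,
            "auc": self.auc,
            "roc_points": self.roc_points,
            "per_class_sensitivity": self.per_class_sensitivity,
            "confusion": None if self.confusion is None else vars(self.confusion),
            "confusion_matrix": self.confusion_matrix,
            "class_labels": self.class_labels,
            "cv_folds": self.cv_folds, "seed": self.seed, "pooled": self.pooled,
        }
        d.update(self.extra)
        return d


def _report_from_predictions(y_true, y_pred, scores, pos_label,
                             cv_folds, seed) -> EvaluationReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = sorted(set(map(str, y_true)))
    binary = pos_label is not None and len(labels) == 2

    if binary:
        t = y_true == pos_label
        p = y_pred == pos_label
        counts = ConfusionCounts(
            tp=int(np.sum(t & p)), tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)), fn=int(np.sum(t & ~p)))
        sn, sp, acc, mcc = binary_metrics(counts)
        roc_pts = auc_value = None
        if scores is not None:
            roc_pts, auc_value = roc_auc(scores, t)
        return EvaluationReport(acc=acc, sn=sn, sp=sp, mcc=mcc, auc=auc_value,
                                roc_points=roc_pts, confusion=counts,
                                class_labels=labels, cv_folds=cv_folds, seed=seed)

    cm = _confusion_matrix(y_true, y_pred, labels=labels)
    row_sums = cm.sum(axis=1)
    per_class = {lab: (cm[i, i] / row_sums[i] if row_sums[i] else 0.0)
                 for i, lab in enumerate(labels)}
    acc = float(np.trace(cm) / cm.sum())
    return EvaluationReport(acc=acc, per_class_sensitivity=per_class,
                            confusion_matrix=cm.tolist(), class_labels=labels,
                            cv_folds=cv_folds, seed=seed)


def kfold_cv(
    dataset: LabeledDataset,
    pipeline,
    folds: int = 10,
    seed: int = 0,
    pos_label: str | None = "apo",
) -> EvaluationReport:
    """Stratified k-fold cross-validation of an encode->select->train pipeline.

    ``pipeline`` is any sklearn-style estimator over raw sequences (see
    :func:`apopred.classify.make_tier_pipeline`); it is cloned and refit on
    each training split, so feature ranking/selection never sees held-out
    data. Predictions are pooled over all held-out splits before computing
    metrics. Binary problems additionally report ROC/AUC from the decision
    scores for ``pos_label``.
    """
    if dataset.labels is None:
        raise EvaluationError("kfold_cv requires a labelled dataset")
    if folds < 2:
        raise EvaluationError("folds must be >= 2")
    y = np.asarray(dataset.labels)
    class_counts = np.bincount(np.unique(y, return_inverse=True)[1])
    if class_counts.min() < folds:
        raise EvaluationError(
            f"smallest class has {class_counts.min()} samples < {folds} folds")

    X = np.asarray(dataset.sequences, dtype=object)
    labels = sorted(set(map(str, y)))
    binary = pos_label is not None and len(labels) == 2

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_true = np.empty(len(y), dtype=object)
    y_pred = np.empty(len(y), dtype=object)
    scores = np.full(len(y), np.nan) if binary else None
    for train, test in skf.split(X, y):
        model = clone(pipeline)
        model.fit(list(X[train]), y[train])
        pred = model.predict(list(X[test]))
        y_true[test] = y[test]
        y_pred[test] = pred
        if binary and hasattr(model, "decision_function"):
            s = np.asarray(model.decision_function(list(X[test]))).ravel()
            # orient scores so larger = more positive-class
            classes = [str(c) for c in getattr(model, "classes_", labels)]
            if pos_label in classes and classes.index(pos_label) == 0:
                s = -s
            scores[test] = s

    if scores is not None and np.isnan(scores).any():
        scores = None
    return _report_from_predictions(y_true, y_pred, scores, pos_label, folds, seed)
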