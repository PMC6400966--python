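"""Classification metrics, the model-selection fitness score, and the
cross-validation harness.

Model selection throughout the pipeline uses a single scalar computed over
cross-validation folds::

    fitness = mean(MCC) + mean(AUC) - sd(MCC)/4 - sd(AUC)/4

which rewards both thresholded performance (Matthews correlation
coefficient at probability threshold 0.5) and threshold-free ranking
quality (area under the ROC curve), while penalising models whose
performance varies strongly across folds.  The standard deviations are
population SDs over the fold values.  The global maximum is 2.0: a perfect
classifier on every fold with zero variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import models as _models
from .models import Hyperparameters

__all__ = [
    "ConfusionCounts",
    "CVResult",
    "mcc",
    "auc",
    "roc_points",
    "fitness",
    "accuracy",
    "confusion_from_scores",
    "cross_validate",
    "stratified_folds",
    "write_report_json",
    "write_roc_tsv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; the positive class is "phage"."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_scores(
    y_true: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> ConfusionCounts:
    """Binarize P(positive) at ``threshold`` and tabulate the confusion counts."""
    y = np.asarray(y_true, dtype=int)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    Defined as (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); 0 when
    any factor of the denominator vanishes (the conventional limit).
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    num = c.tp * c.tn - c.fp * c.fn
    factors = [(c.tp + c.fp), (c.tp + c.fn), (c.tn + c.fp), (c.tn + c.fn)]
    if 0 in factors:
        return 0.0
    return float(num / np.sqrt(np.prod([float(f) for f in factors])))


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("empty confusion table")
    return (c.tp + c.tn) / c.total


def roc_points(
    y_true: Sequence[int], scores: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC curve as (FPR, TPR, thresholds), from (0,0) to (1,1)."""
    y = np.asarray(y_true, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, np.asarray(scores, dtype=float))
    return fpr, tpr, thr


def auc(scores: Sequence[float], y_true: Sequence[int]) -> float:
    """Area under the ROC curve (trapezoidal rule over all thresholds).

    Equals the Mann-Whitney pairwise concordance probability with ties
    counted one half.
    """
    fpr, tpr, _ = roc_points(y_true, scores)
    return float(np.trapezoid(tpr, fpr))


@dataclass
class CVResult:
    """Per-fold MCC/AUC/accuracy with their aggregates and the fitness scalar."""

    fold_mcc: np.ndarray
    fold_auc: np.ndarray
    fold_accuracy: np.ndarray

    def __post_init__(self) -> None:
        self.fold_mcc = np.asarray(self.fold_mcc, dtype=float)
        self.fold_auc = np.asarray(self.fold_auc, dtype=float)
        self.fold_accuracy = np.asarray(self.fold_accuracy, dtype=float)
        n = len(self.fold_mcc)
        if n < 2 or len(self.fold_auc) != n or len(self.fold_accuracy) != n:
            raise ValueError("need >=2 folds with matching metric lengths")

    @property
    def mean_mcc(self) -> float:
        return float(self.fold_mcc.mean())

    @property
    def mean_auc(self) -> float:
        return float(self.fold_auc.mean())

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracy.mean())

    @property
    def sd_mcc(self) -> float:
        return float(self.fold_mcc.std())  # population SD over folds

    @property
    def sd_auc(self) -> float:
        return float(self.fold_auc.std())

    @property
    def fitness(self) -> float:
        return fitness(self)

    def to_dict(self) -> dict:
        return {
            "fold_mcc": self.fold_mcc.tolist(),
            "fold_auc": self.fold_auc.tolist(),
            "fold_accuracy": self.fold_accuracy.tolist(),
            "mean_mcc": self.mean_mcc,
            "mean_auc": self.mean_auc,
            "mean_accuracy": self.mean_accuracy,
            "sd_mcc": self.sd_mcc,
            "sd_auc": self.sd_auc,
            "fitness": self.fitness,
        }


def fitness(cv: CVResult) -> float:
    """Model-selection scalar: MCC + AUC means minus a quarter of each SD."""
    return cv.mean_mcc + cv.mean_auc - cv.sd_mcc / 4 - cv.sd_auc / 4


def stratified_folds(y: Sequence[int], n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Random stratified fold assignment (values 0..n_folds-1), seeded."""
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for f, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[chunk] = f
    return folds


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    hp: Hyperparameters,
    folds: np.ndarray | None = None,
    seed: int = 0,
    n_folds: int = 5,
    threshold: float = 0.5,
) -> CVResult:
    """K-fold cross-validation of one hyperparameter/feature-subset choice.

    Each fold's model is trained only on the out-of-fold rows (including the
    standardization fit), then scored on the held-out fold: MCC and accuracy
    at the 0.5 probability threshold, AUC threshold-free.  ``folds`` may
    carry a precomputed assignment (e.g. the lineage-sorted folds from
    :mod:`hostsieve.partition`); by default stratified random folds are
    drawn from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if folds is None:
        folds = stratified_folds(y, n_folds=n_folds, seed=seed)
    folds = np.asarray(folds, dtype=int)
    if folds.shape != y.shape:
        raise ValueError("fold assignment must align with y")
    fold_ids = np.unique(folds)
    if len(fold_ids) < 2:
        raise ValueError("need at least 2 folds")

    mccs, aucs, accs = [], [], []
    for f in fold_ids:
        test = folds == f
        train_idx = ~test
        if len(np.unique(y[test])) < 2 or len(np.unique(y[train_idx])) < 2:
            raise ValueError(f"fold {f} lacks one of the classes")
        model = _models.train(X[train_idx], y[train_idx], hp, seed=seed)
        scores = model.decision_scores(X[test])
        conf = confusion_from_scores(y[test], scores, threshold=threshold)
        mccs.append(mcc(conf))
        accs.append(accuracy(conf))
        aucs.append(auc(scores, y[test]))
    return CVResult(fold_mcc=mccs, fold_auc=aucs, fold_accuracy=accs)


def write_report_json(path: str | Path, cv: CVResult, extra: dict | None = None) -> None:
    report = cv.to_dict()
    if extra:
        report.update(extra)
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def write_roc_tsv(path: str | Path, y_true, scores) -> None:
    fpr, tpr, thr = roc_points(y_true, scores)
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\tthreshold\n")
        for a, b, t in zip(fpr, tpr, thr):
            fh.write(f"{a:.10g}\t{b:.10g}\t{t:.10g}\n")
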