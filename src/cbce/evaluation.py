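"""Evaluation protocol: cross-validation, confusion-matrix metrics,
Davies-Bouldin cluster validity and the ensemble-size stability experiment.

Conventions
-----------
Confusion matrices are oriented **rows = predicted class, columns = actual
class**, so per-class precision is the diagonal over the *row* sum and recall
the diagonal over the *column* sum.  Precision/recall/F are macro-averaged
(unweighted over classes): activity datasets are strongly imbalanced and a
frequency-weighted mean would hide failures on rare activities.

Accuracy is reported two ways — mean over folds and pooled trace/total —
which differ only through unequal fold sizes; both appear in the report.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .encoding import DataMatrix
from .ensemble import CBCEConfig, predict_matrix, train_ensemble

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "metrics_from_confusion",
    "cross_validate",
    "davies_bouldin",
    "stability_experiment",
    "plot_confusion",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """M×M count grid, rows = predicted, columns = actual."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if c.shape[0] != len(self.classes):
            raise ValueError("class list must match matrix dimension")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            c = c.astype(float)
            if (c < 0).any() or not (c == np.round(c)).all():
                raise ValueError("confusion counts must be non-negative integers")
        object.__setattr__(self, "counts", c.astype(int))
        object.__setattr__(self, "classes", tuple(self.classes))

    @classmethod
    def from_labels(cls, predicted: Sequence[str], actual: Sequence[str],
                    classes: Sequence[str]) -> "ConfusionMatrix":
        classes = tuple(classes)
        lookup = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for p, a in zip(predicted, actual, strict=True):
            counts[lookup[p], lookup[a]] += 1
        return cls(counts, classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        if self.total == 0:
            raise ValueError("empty confusion matrix")
        return float(np.trace(self.counts)) / self.total

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


@dataclass
class MetricsReport:
    """Accuracy plus per-class and macro precision/recall/F-measure."""

    accuracy: float
    per_class: pd.DataFrame  # columns: precision, recall, f_measure
    macro_precision: float
    macro_recall: float
    macro_f_measure: float
    confusion: ConfusionMatrix
    fold_accuracies: tuple[float, ...] = ()
    mean_fold_accuracy: float | None = None
    seed: int | None = None
    undefined_precision_classes: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f_measure": self.macro_f_measure,
            "per_class": self.per_class.to_dict(orient="index"),
            "seed": self.seed,
        }
        if self.fold_accuracies:
            out["fold_accuracies"] = list(self.fold_accuracies)
            out["mean_fold_accuracy"] = self.mean_fold_accuracy
        return out

    def summary(self) -> str:
        lines = [
            f"accuracy          {self.accuracy:8.4f}",
            f"macro precision   {self.macro_precision:8.4f}",
            f"macro recall      {self.macro_recall:8.4f}",
            f"macro F-measure   {self.macro_f_measure:8.4f}",
        ]
        if self.mean_fold_accuracy is not None:
            lines.append(f"mean fold accuracy{self.mean_fold_accuracy:8.4f}")
        lines.append("")
        lines.append(self.per_class.round(4).to_string())
        return "\n".join(lines)


def metrics_from_confusion(cm: ConfusionMatrix,
                           fold_accuracies: Sequence[float] = (),
                           seed: int | None = None) -> MetricsReport:
    """Per-class one-vs-rest precision/recall/F and macro averages.

    A class never predicted has an empty row; its precision is defined as 0
    and reported in ``undefined_precision_classes`` with a warning.  F is the
    harmonic mean, 0 whenever precision or recall is 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    row_sums = counts.sum(axis=1)   # predicted totals
    col_sums = counts.sum(axis=0)   # actual totals
    undefined = tuple(c for c, r in zip(cm.classes, row_sums) if r == 0)
    if undefined:
        warnings.warn(
            f"classes never predicted (precision defined as 0): {undefined}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(row_sums > 0, diag / np.where(row_sums > 0, row_sums, 1), 0.0)
        recall = np.where(col_sums > 0, diag / np.where(col_sums > 0, col_sums, 1), 0.0)
        denom = precision + recall
        f_measure = np.where(denom > 0, 2 * precision * recall /
                             np.where(denom > 0, denom, 1), 0.0)
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f_measure": f_measure},
        index=list(cm.classes),
    )
    fold_accuracies = tuple(float(a) for a in fold_accuracies)
    return MetricsReport(
        accuracy=cm.accuracy(),
        per_class=per_class,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f_measure=float(f_measure.mean()),
        confusion=cm,
        fold_accuracies=fold_accuracies,
        mean_fold_accuracy=float(np.mean(fold_accuracies)) if fold_accuracies else None,
        seed=seed,
        undefined_precision_classes=undefined,
    )


def cross_validate(data: DataMatrix, config: CBCEConfig = CBCEConfig(),
                   folds: int = 5, seed: int | None = None) -> MetricsReport:
    """Stratified k-fold cross-validation of the ensemble.

    Folds are stratified by class when every class has at least ``folds``
    members; otherwise plain shuffled folds are used with a warning.  The
    pooled confusion matrix covers every instance exactly once; accuracy is
    reported both pooled and as the mean over folds.
    """
    if data.n_instances < folds:
        raise ValueError(f"need at least {folds} instances for {folds}-fold CV")
    _, class_sizes = np.unique(data.y, return_counts=True)
    idx = np.arange(data.n_instances)
    if class_sizes.min() >= folds:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(idx, data.y.astype(str))
    else:
        warnings.warn(
            f"smallest class has {class_sizes.min()} < {folds} members; "
            "falling back to non-stratified folds", stacklevel=2,
        )
        rng = np.random.default_rng(seed)
        perm = rng.permutation(idx)
        parts = np.array_split(perm, folds)
        split_iter = ((np.setdiff1d(idx, p), p) for p in parts)

    predicted = np.empty(data.n_instances, dtype=object)
    fold_accuracies = []
    for fold_no, (train_idx, test_idx) in enumerate(split_iter):
        train = DataMatrix(data.X[train_idx], data.y[train_idx],
                           data.inventory, data.encoding, data.classes)
        fold_seed = None if seed is None else (seed * folds + fold_no) % (2**31)
        ensemble = train_ensemble(train, config, fold_seed)
        pred = predict_matrix(data.X[test_idx], ensemble)
        predicted[test_idx] = pred
        fold_accuracies.append(float(np.mean(pred == data.y[test_idx])))
        logger.info("fold %d: accuracy %.4f", fold_no + 1, fold_accuracies[-1])
    cm = ConfusionMatrix.from_labels(predicted, data.y, data.classes)
    return metrics_from_confusion(cm, fold_accuracies, seed)


def davies_bouldin(X: np.ndarray, groups: Sequence) -> float:
    """Davies-Bouldin index of a grouping (lower = better-separated groups).

    Per-group scatter is the mean member-to-centroid Euclidean distance;
    the index is the mean over groups of the worst pairwise
    (scatter_i + scatter_j) / centroid distance.  Coincident group centroids
    make the ratio undefined and raise.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(groups)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    centroids, scatters = [], []
    for g in uniq:
        members = X[labels == g]
        if len(members) == 0:
            raise ValueError(f"group {g!r} is empty")
        c = members.mean(axis=0)
        centroids.append(c)
        scatters.append(float(np.linalg.norm(members - c, axis=1).mean()))
    centroids = np.array(centroids)
    scatters = np.array(scatters)
    sep = cdist(centroids, centroids)
    k = len(uniq)
    off_diag = ~np.eye(k, dtype=bool)
    if (sep[off_diag] == 0).any():
        raise ValueError("coincident group centroids: index undefined")
    with np.errstate(divide="ignore"):
        ratios = (scatters[:, None] + scatters[None, :]) / np.where(sep > 0, sep, np.inf)
    ratios[~off_diag] = -np.inf
    return float(ratios.max(axis=1).mean())


def stability_experiment(data: DataMatrix,
                         ensemble_sizes: Sequence[int] = (1, 10, 20, 30, 40, 50),
                         repetitions: int = 50,
                         test_fraction: float = 0.25,
                         config: CBCEConfig = CBCEConfig(),
                         seed: int | None = None) -> pd.DataFrame:
    """Standard deviation of accuracy across repeated trainings, per K.

    A single stratified train/test split is fixed from the seed; for each
    ensemble size the training is repeated with fresh sub-seeds and the
    accuracy's standard deviation over repetitions is reported.  Larger
    ensembles average over more random subset/cluster-count draws, so the
    spread should shrink as K grows.
    """
    rng = np.random.default_rng(seed)
    test_idx = []
    for c in data.classes:
        members = np.flatnonzero(data.y == c)
        n_test = max(1, int(round(test_fraction * len(members))))
        test_idx.extend(rng.permutation(members)[:n_test])
    test_idx = np.sort(np.array(test_idx))
    train_idx = np.setdiff1d(np.arange(data.n_instances), test_idx)
    train = DataMatrix(data.X[train_idx], data.y[train_idx],
                       data.inventory, data.encoding, data.classes)
    rows = []
    for K in ensemble_sizes:
        cfg = CBCEConfig(K, config.cluster_bound_multiplier, config.centroid_mode)
        accuracies = []
        for rep in range(repetitions):
            sub_seed = int(rng.integers(0, 2**31))
            ensemble = train_ensemble(train, cfg, sub_seed)
            pred = predict_matrix(data.X[test_idx], ensemble)
            accuracies.append(float(np.mean(pred == data.y[test_idx])))
        rows.append({
            "ensemble_size": K,
            "mean_accuracy": float(np.mean(accuracies)),
            "std_accuracy": float(np.std(accuracies, ddof=1)),
        })
        logger.info("stability K=%d: mean %.4f std %.4f", K,
                    rows[-1]["mean_accuracy"], rows[-1]["std_accuracy"])
    return pd.DataFrame(rows).set_index("ensemble_size")


def plot_confusion(cm: ConfusionMatrix, ax=None):
    """Heatmap of a confusion matrix (rows predicted, columns actual)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(len(cm.classes)), cm.classes, rotation=45, ha="right")
    ax.set_yticks(range(len(cm.classes)), cm.classes)
    ax.set_xlabel("actual class")
    ax.set_ylabel("predicted class")
    for i in range(len(cm.classes)):
        for j in range(len(cm.classes)):
            if cm.counts[i, j]:
                ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center")
    return ax
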