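"""Cross-validation protocols and per-class performance measures.

Two protocols are provided:

* UDT (user-dependent test): 10-fold stratified cross-validation over
  instances, ignoring subject identity;
* UIT (user-independent test): leave-one-subject-out cross-validation,
  training on all subjects but one and testing on the held-out subject.

In every fold, SMOTE balancing and CFS feature selection are fitted on
the training rows only; the test rows are merely projected onto the
selected feature subset. Accuracy and the per-class F-measure

    F = 2 TP / (2 TP + FP + FN)

are computed per fold and averaged, with the non-drowsy class as
positive for F1 and the drowsy class as positive for F2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balancing_selection import FeatureSubset, best_first_select, smote
from .classifiers import ClassifierAdapter
from .ground_truth import DROWSY, NON_DROWSY
from .hrv_features import FEATURE_NAMES
from .iodata import FEATURE_TABLE_META, FEATURE_TABLE_TAIL

log = logging.getLogger(__name__)

UDT = "udt"
UIT = "uit"


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; 'positive' is whichever class the caller
    treats as positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total


@dataclass
class FoldResult:
    accuracy: float  # %
    f1: float  # non-drowsy as positive
    f2: float  # drowsy as positive
    subset: FeatureSubset
    confusion: ConfusionCounts  # positive = non-drowsy
    test_size: int


@dataclass
class CVResult:
    protocol: str
    per_fold: list[FoldResult]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.accuracy for f in self.per_fold]))

    @property
    def mean_f1(self) -> float:
        return float(np.mean([f.f1 for f in self.per_fold]))

    @property
    def mean_f2(self) -> float:
        return float(np.mean([f.f2 for f in self.per_fold]))

    @property
    def selected_subsets(self) -> list[FeatureSubset]:
        return [f.subset for f in self.per_fold]

    def summary(self) -> pd.DataFrame:
        rows = [
            {"fold": i, "accuracy": f.accuracy, "F1": f.f1, "F2": f.f2,
             "test_size": f.test_size, "subset": ", ".join(f.subset.selected)}
            for i, f in enumerate(self.per_fold)
        ]
        return pd.DataFrame(rows)


def confusion(y_true: np.ndarray, y_pred: np.ndarray, positive) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)), fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)), fn=int(np.sum(t & ~p)),
    )


def f_measure(c: ConfusionCounts) -> float:
    """F = 2TP / (2TP + FP + FN); 0 with a warning when undefined."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("F-measure undefined (no positive instances or predictions); using 0")
        return 0.0
    return 2.0 * c.tp / denom


def stratified_kfold(
    y: np.ndarray, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k folds with per-fold class proportions within 1 instance of the
    global proportions: shuffle within each class, deal round-robin.

    Returns (train_idx, test_idx) pairs forming an exhaustive, disjoint
    partition of the instances.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if idx.size < k:
            raise ValueError(f"class {cls!r} has {idx.size} instances, fewer than k={k}")
        rng.shuffle(idx)
        fold_of[idx] = np.arange(idx.size) % k
    splits = []
    all_idx = np.arange(y.size)
    for f in range(k):
        test = all_idx[fold_of == f]
        train = all_idx[fold_of != f]
        splits.append((train, test))
    return splits


def losocv_splits(groups: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """One split per subject: test on that subject, train on the rest."""
    groups = np.asarray(groups)
    subjects = sorted(set(groups.tolist()))
    if len(subjects) < 2:
        raise ValueError(f"need >= 2 subjects for leave-one-subject-out, got {len(subjects)}")
    all_idx = np.arange(groups.size)
    return [
        (all_idx[groups != s], all_idx[groups == s])
        for s in subjects
    ]


@dataclass
class FeatureMatrix:
    """Instances x 26 named features with binary class and subject ids."""

    X: np.ndarray
    y: np.ndarray  # NON_DROWSY / DROWSY strings
    groups: np.ndarray  # subject ids per row
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.groups = np.asarray(self.groups)
        if self.X.shape != (self.y.size, len(self.feature_names)):
            raise ValueError(
                f"X shape {self.X.shape} inconsistent with {self.y.size} labels "
                f"and {len(self.feature_names)} features"
            )
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "FeatureMatrix":
        names = [c for c in table.columns
                 if c not in FEATURE_TABLE_META + FEATURE_TABLE_TAIL]
        return cls(
            X=table[names].to_numpy(dtype=float),
            y=table["binary_class"].to_numpy(),
            groups=table["subject"].to_numpy(),
            feature_names=names,
        )


def run_protocol(
    data: FeatureMatrix,
    clf: ClassifierAdapter,
    protocol: str = UDT,
    seed: int = 0,
    k_folds: int = 10,
    smote_k: int = 5,
    cfs_max_stale: int = 5,
) -> CVResult:
    """Run one cross-validation protocol with per-fold SMOTE + CFSS.

    Balancing and selection see only training rows; test rows are only
    projected onto each fold's selected subset before prediction.
    """
    if protocol == UDT:
        splits = stratified_kfold(data.y, k=k_folds, seed=seed)
    elif protocol == UIT:
        splits = losocv_splits(data.groups)
    else:
        raise ValueError(f"unknown protocol {protocol!r}; expected '{UDT}' or '{UIT}'")

    rng = np.random.default_rng(seed)
    folds: list[FoldResult] = []
    for fold_i, (train, test) in enumerate(splits):
        if test.size == 0:
            raise ValueError(f"fold {fold_i} has an empty test set")
        Xb, yb = smote(data.X[train], data.y[train], k=smote_k,
                       seed=np.random.default_rng(rng.integers(2 ** 31)))
        subset = best_first_select(Xb, yb, data.feature_names, max_stale=cfs_max_stale)
        cols = [data.feature_names.index(n) for n in subset.selected]
        clf.fit(Xb[:, cols], yb)
        pred = clf.predict(data.X[test][:, cols])
        c1 = confusion(data.y[test], pred, positive=NON_DROWSY)
        c2 = confusion(data.y[test], pred, positive=DROWSY)
        folds.append(FoldResult(
            accuracy=c1.accuracy, f1=f_measure(c1), f2=f_measure(c2),
            subset=subset, confusion=c1, test_size=int(test.size),
        ))
        log.debug("fold %d: acc %.2f%%, subset %s", fold_i, c1.accuracy, subset.selected)
    return CVResult(protocol=protocol, per_fold=folds)
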