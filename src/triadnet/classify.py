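"""KNN classification, stratified cross-validation and the metric suite.

The classifier is a plain k-nearest-neighbour majority vote under
Euclidean distance, with columns z-scored on the training portion only
(descriptors span wildly different scales). Distance ties are broken by
training-row index and vote ties toward the negative class, so every
prediction is deterministic. Performance is summarised by sensitivity
SN = TP/(TP+FN), specificity SP = TN/(TN+FP), overall accuracy
ACC = (TP+TN)/total, and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TN+FN)(TN+FP)(TP+FN)(TP+FP)),

with MCC defined as 0 when any denominator factor vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.spatial.distance import cdist

if TYPE_CHECKING:
    from .dataset import FeatureMatrix

__all__ = [
    "KNNConfig",
    "ConfusionCounts",
    "MetricReport",
    "knn_predict",
    "stratified_folds",
    "cross_validate",
    "metrics",
]


@dataclass(frozen=True)
class KNNConfig:
    k: int = 1
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k % 2 == 0:
            raise ValueError("k must be odd (binary-vote tie avoidance)")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    sn: float
    sp: float
    acc: float
    mcc: float


def _standardizer(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns pass through
    return mu, sd


def knn_predict(train_X: np.ndarray, train_y: np.ndarray, query_X: np.ndarray,
                cfg: KNNConfig = KNNConfig()) -> np.ndarray:
    """Predict binary labels for query rows by k-NN majority vote."""
    train_X = np.asarray(train_X, dtype=float)
    query_X = np.atleast_2d(np.asarray(query_X, dtype=float))
    train_y = np.asarray(train_y)
    if cfg.k > len(train_X):
        raise ValueError(f"k={cfg.k} exceeds training size {len(train_X)}")
    if train_X.shape[1] != query_X.shape[1]:
        raise ValueError("query columns do not match training columns")
    if cfg.standardize:
        mu, sd = _standardizer(train_X)
        train_X = (train_X - mu) / sd
        query_X = (query_X - mu) / sd
    d2 = cdist(query_X, train_X, metric="sqeuclidean")
    return _vote(d2, train_y, cfg.k)


def _vote(d2: np.ndarray, train_y: np.ndarray, k: int) -> np.ndarray:
    # np.argmin takes the first minimum, so repeated extraction breaks
    # distance ties by training-row index
    if k == 1:
        return train_y[np.argmin(d2, axis=1)].astype(np.int8)
    work = np.array(d2, dtype=float, copy=True)
    rows = np.arange(work.shape[0])
    votes = np.zeros(work.shape[0], dtype=np.int64)
    for _ in range(k):
        nn = np.argmin(work, axis=1)
        votes += train_y[nn]
        work[rows, nn] = np.inf
    # strict majority for the positive class; ties fall to negative
    return (2 * votes > k).astype(np.int8)


def stratified_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment: per class, shuffle then deal
    round-robin. Every class must have at least ``folds`` members."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=np.int32)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < folds:
            raise ValueError(
                f"class {cls} has {len(idx)} samples, fewer than {folds} folds")
        perm = rng.permutation(idx)
        assignment[perm] = np.arange(len(perm)) % folds
    return assignment


def cross_validate(m: "FeatureMatrix | tuple[np.ndarray, np.ndarray]",
                   cfg: KNNConfig = KNNConfig(),
                   folds: int = 10, seed: int = 0,
                   feature_names: list[str] | None = None) -> ConfusionCounts:
    """Pooled confusion counts from seeded stratified k-fold CV.

    Each row is predicted exactly once while held out; z-scoring (when
    enabled) is fitted on the training folds only.
    """
    if isinstance(m, tuple):
        X, y = m
        X = np.asarray(X, dtype=float)
    else:
        frame = m.X[feature_names] if feature_names else m.X
        X, y = frame.to_numpy(dtype=float), m.y
    y = np.asarray(y)
    assignment = stratified_folds(y, folds, seed)
    preds = np.empty(len(y), dtype=np.int8)
    for f in range(folds):
        test = assignment == f
        train = ~test
        preds[test] = knn_predict(X[train], y[train], X[test], cfg)
    return confusion_from_predictions(y, preds)


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics(c: ConfusionCounts) -> MetricReport:
    """SN/SP/ACC/MCC from pooled confusion counts."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    acc = (c.tp + c.tn) / c.total
    denom = ((c.tn + c.fn) * (c.tn + c.fp) * (c.tp + c.fn) * (c.tp + c.fp))
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricReport(sn=sn, sp=sp, acc=acc, mcc=mcc)
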