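"""Mutual-information feature ranking (MaxRel, mRMR) and the IFS sweep.

Features are discretized into three bins at mu +/- t*sigma (t = 0.5 by
default, computed on the full training matrix) and scored by the
plug-in mutual-information estimate in bits. MaxRel ranks features by
I(f; class) alone; mRMR ranks greedily by the MID (difference)
criterion

    score(f) = I(f; class) - (1/|S|) * sum_{s in S} I(f; s),

seeded with the MaxRel top feature. Incremental feature selection (IFS)
then evaluates every prefix D_1 subset D_2 subset ... of the ranking
with a cross-validated KNN classifier and picks the prefix maximizing
MCC (ties to the smallest prefix), yielding the IFS curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .classify import (KNNConfig, _standardizer, _vote, confusion_from_predictions,
                       metrics, stratified_folds)

if TYPE_CHECKING:
    from .dataset import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DiscretizationRule",
    "RankedFeatureTable",
    "IFSCurve",
    "discretize",
    "discretize_matrix",
    "mutual_information",
    "maxrel_rank",
    "mrmr_rank",
    "ifs",
]


@dataclass(frozen=True)
class DiscretizationRule:
    """Three-bin rule: category -1 below mu - t*sigma, +1 above
    mu + t*sigma, 0 between; constant vectors map to all-zero."""

    t: float = 0.5


@dataclass
class RankedFeatureTable:
    ordering: list[str]
    scores: np.ndarray
    scheme: str  # "maxrel" | "mrmr"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.ordering) + 1),
            "feature": self.ordering,
            "score": self.scores,
        })

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class IFSCurve:
    points: pd.DataFrame  # columns: size, SN, SP, ACC, MCC
    selected_size: int
    selected_features: list[str]

    def write_tsv(self, path: str | Path) -> None:
        self.points.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def plot(self, path: str | Path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(self.points["size"], self.points["MCC"], lw=1.2)
        ax.axvline(self.selected_size, color="crimson", ls="--", lw=0.8,
                   label=f"selected size = {self.selected_size}")
        ax.set_xlabel("number of features in prefix")
        ax.set_ylabel("MCC (10-fold CV)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


# --------------------------------------------------------------------------
# discretization and mutual information

def discretize(values: np.ndarray, rule: DiscretizationRule = DiscretizationRule()) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    mu = values.mean()
    sigma = values.std()  # population sigma
    if sigma == 0:
        return np.zeros(len(values), dtype=np.int8)
    lo, hi = mu - rule.t * sigma, mu + rule.t * sigma
    out = np.zeros(len(values), dtype=np.int8)
    out[values < lo] = -1
    out[values > hi] = 1
    return out


def discretize_matrix(X: np.ndarray, rule: DiscretizationRule = DiscretizationRule()) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape, dtype=np.int8)
    for j in range(X.shape[1]):
        out[:, j] = discretize(X[:, j], rule)
    return out


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information in bits over observed cells."""
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("vectors differ in length")
    if len(x) == 0:
        raise ValueError("empty vectors")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny) / len(x)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


# --------------------------------------------------------------------------
# rankings

def _discretized(m: "FeatureMatrix", rule: DiscretizationRule) -> tuple[np.ndarray, list[str]]:
    X = m.X.to_numpy(dtype=float)
    return discretize_matrix(X, rule), list(m.X.columns)


def maxrel_rank(m: "FeatureMatrix",
                rule: DiscretizationRule = DiscretizationRule()) -> RankedFeatureTable:
    """Rank all features by I(f; class), descending; ties broken by
    column index."""
    dX, names = _discretized(m, rule)
    rel = np.array([mutual_information(dX[:, j], m.y) for j in range(dX.shape[1])])
    order = np.lexsort((np.arange(len(rel)), -rel))  # stable on ties
    return RankedFeatureTable([names[j] for j in order], rel[order], "maxrel")


def mrmr_rank(m: "FeatureMatrix", n_select: int | None = None,
              rule: DiscretizationRule = DiscretizationRule(),
              variant: str = "mid") -> RankedFeatureTable:
    """Greedy mRMR ordering (MID criterion by default).

    The first feature is the MaxRel top; each subsequent pick maximizes
    relevance minus mean redundancy with the already-selected set
    (or relevance/mean-redundancy under ``variant="miq"``). Pairwise MI
    values are computed lazily, once per (selected, candidate) pair.
    Features whose discretized column is constant carry no relevance
    and no redundancy (their MID score is pinned at 0 while informative
    candidates can go negative), so they are deferred to the end of the
    ordering — the usual variance prefilter expressed as a tie policy.
    """
    dX, names = _discretized(m, rule)
    n_features = dX.shape[1]
    n_select = n_features if n_select is None else min(n_select, n_features)
    rel = np.array([mutual_information(dX[:, j], m.y) for j in range(n_features)])
    constant = np.array([(dX[:, j] == dX[0, j]).all() for j in range(n_features)])

    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(n_features)
    remaining = ~constant
    n_greedy = min(n_select, int(remaining.sum()))
    for step in range(n_greedy):
        if step == 0:
            crit = rel.copy()
        else:
            mean_red = redundancy_sum / len(selected)
            if variant == "mid":
                crit = rel - mean_red
            elif variant == "miq":
                crit = rel / np.maximum(mean_red, 1e-12)
            else:
                raise ValueError(f"unknown mRMR variant {variant!r}")
        crit_masked = np.where(remaining, crit, -np.inf)
        best = int(np.argmax(crit_masked))  # argmax takes lowest index on ties
        selected.append(best)
        scores.append(float(crit_masked[best]))
        remaining[best] = False
        if step < n_greedy - 1:
            for j in np.flatnonzero(remaining):
                redundancy_sum[j] += mutual_information(dX[:, j], dX[:, best])
    for j in np.flatnonzero(constant):  # deferred constants, column order
        if len(selected) == n_select:
            break
        selected.append(int(j))
        scores.append(0.0)
    return RankedFeatureTable([names[j] for j in selected], np.array(scores), "mrmr")


# --------------------------------------------------------------------------
# incremental feature selection

def ifs(m: "FeatureMatrix", table: RankedFeatureTable,
        knn: KNNConfig = KNNConfig(), folds: int = 10, seed: int = 0) -> IFSCurve:
    """Evaluate every prefix of the ranking with cross-validated KNN.

    Fold assignment is fixed across prefixes (same seed), so the curve
    isolates the effect of adding features. Distances are accumulated
    incrementally one feature at a time, which makes the full sweep
    O(folds * n_test * n_train * N) rather than quadratic in N.
    """
    missing = [n for n in table.ordering if n not in m.X.columns]
    if missing:
        raise KeyError(f"ranking names absent from matrix: {missing[:5]}")
    X = m.X[table.ordering].to_numpy(dtype=float)
    y = np.asarray(m.y)
    n_prefix = X.shape[1]
    assignment = stratified_folds(y, folds, seed)

    # per-prefix pooled predictions
    preds = np.empty((n_prefix, len(y)), dtype=np.int8)
    for f in range(folds):
        test = assignment == f
        train = ~test
        Xtr, Xte = X[train], X[test]
        if knn.standardize:
            mu, sd = _standardizer(Xtr)
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        d2 = np.zeros((Xte.shape[0], Xtr.shape[0]))
        ytr = y[train]
        for i in range(n_prefix):
            d2 += (Xte[:, i][:, None] - Xtr[:, i][None, :]) ** 2
            preds[i, test] = _vote(d2, ytr, knn.k)

    rows = []
    for i in range(n_prefix):
        rep = metrics(confusion_from_predictions(y, preds[i]))
        rows.append((i + 1, rep.sn, rep.sp, rep.acc, rep.mcc))
    points = pd.DataFrame(rows, columns=["size", "SN", "SP", "ACC", "MCC"])
    best = int(points["MCC"].idxmax())  # idxmax returns first (smallest) maximizer
    selected_size = int(points.loc[best, "size"])
    return IFSCurve(points, selected_size, table.ordering[:selected_size])
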