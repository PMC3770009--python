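"""Nearest-neighbour classification, jackknife evaluation, incremental feature
selection (IFS) and performance metrics.

The IFS procedure walks a ranked feature list: for each prefix of size k it
evaluates a 1-nearest-neighbour classifier by leave-one-out (jackknife)
cross-validation and records sensitivity, specificity, accuracy and the
Matthews correlation coefficient. The optimal feature set is the smallest
prefix attaining the maximal MCC. The sweep maintains the pairwise
squared-distance matrix incrementally, adding one feature's contribution per
step, so the full curve costs O(k_max · n²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .mrmr import RankedList


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity, specificity, accuracy, MCC (and optionally AUC).

    ``sn``/``sp`` are ``None`` when the corresponding class is absent (an
    undefined rate is reported as missing, never as 0); a zero factor in the
    MCC denominator yields MCC = 0 by convention.
    """

    sn: float | None
    sp: float | None
    ac: float
    mcc: float
    auc: float | None = None


@dataclass
class IFSCurve:
    """Jackknife metrics per prefix size k = 1..N of a ranked feature list."""

    ks: np.ndarray
    metric_sets: list[MetricSet]

    def __len__(self) -> int:
        return len(self.ks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.ks,
                "Sn": [m.sn for m in self.metric_sets],
                "Sp": [m.sp for m in self.metric_sets],
                "Ac": [m.ac for m in self.metric_sets],
                "MCC": [m.mcc for m in self.metric_sets],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def nna_predict(train_X, train_y, query, metric: str = "euclidean") -> int:
    """Label of the training sample nearest to ``query``.

    Distance ties break toward the lowest training-row index. ``metric`` is
    ``"euclidean"`` (default) or ``"cosine"`` (normalized dot-product
    similarity, maximized instead of minimized).
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    query = np.asarray(query, dtype=float).ravel()
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if train_X.shape[1] != query.size:
        raise ValueError("dimension mismatch between training matrix and query")
    if metric == "euclidean":
        d = np.sum((train_X - query) ** 2, axis=1)
        return int(train_y[int(np.argmin(d))])
    if metric == "cosine":
        norms = np.linalg.norm(train_X, axis=1) * np.linalg.norm(query)
        with np.errstate(divide="ignore", invalid="ignore"):
            sim = np.where(norms > 0, train_X @ query / norms, 0.0)
        return int(train_y[int(np.argmax(sim))])
    raise ValueError(f"unknown metric {metric!r}")


def jackknife_evaluate(X, y, classifier=None, groups=None) -> ConfusionCounts:
    """Leave-one-out evaluation; returns aggregated confusion counts.

    ``classifier(train_X, train_y, query) -> label`` defaults to
    :func:`nna_predict`. With ``groups`` (e.g. protein ids per window), the
    unit left out is the whole group: every sample of a group is predicted by
    a classifier trained on all other groups.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] < 2:
        raise ValueError("jackknife needs at least two samples")
    if np.unique(y).size < 2:
        raise ValueError("jackknife needs both classes present")
    if classifier is None:
        classifier = nna_predict
    n = X.shape[0]
    pred = np.empty(n, dtype=int)
    if groups is None:
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            pred[i] = classifier(X[mask], y[mask], X[i])
    else:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            mask = groups != g
            if np.unique(y[mask]).size < 2:
                raise ValueError(f"leaving out group {g!r} removes a whole class")
            for i in np.flatnonzero(~mask):
                pred[i] = classifier(X[mask], y[mask], X[i])
    return confusion(y, pred)


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricSet:
    """Sn, Sp, Ac and MCC from confusion counts.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), Ac = (TP+TN)/total,
    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with MCC = 0
    whenever any denominator factor is zero.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = counts.total
    if total == 0:
        raise ValueError("no evaluated samples")
    sn = tp / (tp + fn) if (tp + fn) > 0 else None
    sp = tn / (tn + fp) if (tn + fp) > 0 else None
    ac = (tp + tn) / total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    return MetricSet(sn=sn, sp=sp, ac=ac, mcc=float(mcc), auc=auc)


def _jackknife_nna_counts_from_sqdist(D: np.ndarray, y: np.ndarray) -> ConfusionCounts:
    D = D.copy()
    np.fill_diagonal(D, np.inf)
    nn = np.argmin(D, axis=1)  # first minimum → lowest-index tie rule
    return confusion(y, y[nn])


def run_ifs(X, y, ranked: RankedList, max_k: int | None = None) -> IFSCurve:
    """Jackknife-NNA metrics for every prefix of the ranked feature list.

    The squared-distance matrix is updated feature by feature in ranked
    order; for each prefix size k the leave-one-out nearest neighbour of
    every sample is read off the matrix (self excluded, ties to the lowest
    row index) and the confusion counts are converted to a
    :class:`MetricSet`. Deterministic; equivalent to evaluating
    :func:`jackknife_evaluate` with :func:`nna_predict` on each truncated
    matrix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    k_max = len(ranked) if max_k is None else min(max_k, len(ranked))
    D = np.zeros((n, n))
    ks = np.arange(1, k_max + 1)
    metric_sets = []
    for k in ks:
        col = X[:, int(ranked.order[k - 1]) - 1]
        diff = col[:, None] - col[None, :]
        D += diff * diff
        counts = _jackknife_nna_counts_from_sqdist(D, y)
        metric_sets.append(metrics(counts))
    return IFSCurve(ks=ks, metric_sets=metric_sets)


def find_optimum(curve: IFSCurve) -> tuple[int, MetricSet]:
    """Smallest k maximizing MCC along the IFS curve."""
    if len(curve) == 0:
        raise ValueError("empty IFS curve")
    mccs = np.array([m.mcc for m in curve.metric_sets])
    best = int(np.argmax(mccs))  # first occurrence → smallest k on a plateau
    return int(curve.ks[best]), curve.metric_sets[best]


def roc_auc(scores, y) -> float:
    """Area under the ROC curve by the midrank (Mann–Whitney) method.

    Equivalent to the probability that a random positive scores above a
    random negative, counting ties as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    ranks = rankdata(scores)  # midranks on ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores, y) -> pd.DataFrame:
    """ROC curve points (threshold, FPR, TPR) over all score thresholds."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thresholds = roc_curve(np.asarray(y, dtype=int), np.asarray(scores, dtype=float))
    return pd.DataFrame({"threshold": thresholds, "FPR": fpr, "TPR": tpr})


def jackknife_nna(X, y) -> ConfusionCounts:
    """Leave-one-out NNA confusion counts on the full feature matrix.

    Vectorized via the pairwise squared-distance matrix; equivalent to
    :func:`jackknife_evaluate` with :func:`nna_predict` up to floating-point
    tie perturbations of order machine epsilon.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] < 2 or np.unique(y).size < 2:
        raise ValueError("jackknife needs >= 2 samples and both classes")
    sq = np.sum(X * X, axis=1)
    D = sq[:, None] + sq[None, :] - 2 * (X @ X.T)
    return _jackknife_nna_counts_from_sqdist(D, y)


def nna_margin_scores(X, y) -> np.ndarray:
    """Leave-one-out NNA decision scores: nearest-negative minus
    nearest-positive squared distance (higher → more positive-like)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    sq = np.sum(X * X, axis=1)
    D = sq[:, None] + sq[None, :] - 2 * (X @ X.T)
    np.fill_diagonal(D, np.inf)
    pos_cols = y == 1
    d_pos = D[:, pos_cols].min(axis=1)
    d_neg = D[:, ~pos_cols].min(axis=1)
    return d_neg - d_pos
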