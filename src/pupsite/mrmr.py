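"""Feature ranking by maximum relevance (MaxRel) and minimum-redundancy
maximum-relevance (mRMR) on discretized features.

Continuous features are discretized per column at mean ± one standard
deviation into three states (below / within / above); mutual information is
the plug-in estimate in bits. MaxRel sorts features by I(f; y). mRMR is the
greedy forward selection that starts from the most relevant feature and then
repeatedly adds the feature maximizing relevance minus mean redundancy with
the already-selected set (the MID difference form; the MIQ quotient form is
available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


@dataclass
class DiscretizedMatrix:
    """Integer category matrix (samples × features), categories in {0, 1, 2}."""

    states: np.ndarray

    @property
    def shape(self):
        return self.states.shape


@dataclass
class RankedList:
    """A feature ordering with per-step criterion scores.

    ``order`` holds 1-based feature indices (matching the descriptor table);
    ``scores[i]`` is the criterion value of ``order[i]`` at selection time.
    """

    order: np.ndarray
    scores: np.ndarray
    criterion: str

    def __len__(self) -> int:
        return len(self.order)

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]

    def positions(self, k: int | None = None) -> np.ndarray:
        """0-based column positions of the top-k entries (all if k is None)."""
        sel = self.order if k is None else self.order[:k]
        return np.asarray(sel, dtype=int) - 1


def discretize(X: np.ndarray) -> DiscretizedMatrix:
    """Three-state discretization per feature at mean ± standard deviation.

    value < μ−σ → 0, value > μ+σ → 2, otherwise 1. A constant column (σ = 0)
    maps entirely to state 1. Non-finite input raises.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    states = np.ones(X.shape, dtype=np.int8)
    states[X < mu - sigma] = 0
    states[X > mu + sigma] = 2
    return DiscretizedMatrix(states=states)


def mutual_information(a, b) -> float:
    """Plug-in mutual information between two discrete vectors, in bits."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty vectors")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= a.size
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    ratio = joint[mask] / (pa @ pb)[mask]
    return float(np.sum(joint[mask] * np.log2(ratio)))


def _as_states(X) -> np.ndarray:
    return X.states if isinstance(X, DiscretizedMatrix) else np.asarray(X)


def _check_labels(y, n_samples: int) -> np.ndarray:
    y = np.asarray(y).ravel()
    if y.size != n_samples:
        raise ValueError("label/sample count mismatch")
    if np.unique(y).size < 2:
        raise ValueError("labels are degenerate (single class)")
    return y


def _onehot_states(S: np.ndarray) -> np.ndarray:
    """(n, 3f) indicator matrix of the {0,1,2} states, feature-major."""
    n, f = S.shape
    onehot = np.stack([(S == s) for s in (0, 1, 2)], axis=2)  # n, f, 3
    return onehot.reshape(n, 3 * f).astype(float)


def _mi_one_vs_all(v: np.ndarray, S: np.ndarray, onehot: np.ndarray | None = None) -> np.ndarray:
    """I(v; column) for every column of S at once, in bits.

    Both sides use states in {0, 1, 2}; the per-feature contingency tables
    are three vector–matrix products against the state indicator matrix.
    """
    n, f = S.shape
    if onehot is None:
        onehot = _onehot_states(S)
    joint = np.empty((3, f, 3))
    for a in (0, 1, 2):
        joint[a] = ((v == a).astype(float) @ onehot).reshape(f, 3)
    joint /= n
    pa = joint.sum(axis=(1, 2)) / f  # marginal of v, same for every feature
    pb = joint.sum(axis=0)  # f, 3
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (pa[:, None, None] * pb[None, :, :])
        terms = np.where(joint > 0, joint * np.log2(ratio), 0.0)
    return terms.sum(axis=(0, 2))


def maxrel_rank(X, y) -> RankedList:
    """Rank features by relevance I(f; y), descending; ties by ascending index."""
    S = _as_states(X)
    y = _check_labels(y, S.shape[0])
    rel = _mi_one_vs_all(y, S)
    order0 = np.lexsort((np.arange(S.shape[1]), -rel))
    return RankedList(order=order0 + 1, scores=rel[order0], criterion="MaxRel")


def mrmr_rank(X, y, n_select: int | None = None, form: str = "MID") -> RankedList:
    """Greedy mRMR ranking.

    The first feature maximizes relevance I(f; y); each later step selects the
    unselected feature maximizing ``relevance − mean redundancy`` (MID) or
    ``relevance / mean redundancy`` (MIQ), where redundancy is the mean mutual
    information with the already-selected features. Ties break toward the
    lower feature index. Scores record the criterion value at selection time.
    """
    if form not in ("MID", "MIQ"):
        raise ValueError(f"unknown mRMR form {form!r}")
    S = _as_states(X)
    y = _check_labels(y, S.shape[0])
    n, f = S.shape
    k = f if n_select is None else min(n_select, f)
    onehot = _onehot_states(S)
    rel = _mi_one_vs_all(y, S, onehot)
    selected = np.zeros(f, dtype=bool)
    red_sum = np.zeros(f)
    order = np.empty(k, dtype=int)
    scores = np.empty(k)
    for step in range(k):
        if step == 0:
            crit = rel.copy()
        elif form == "MID":
            crit = rel - red_sum / step
        else:
            crit = rel / (red_sum / step + _EPS)
        crit[selected] = -np.inf
        pick = int(np.argmax(crit))  # first occurrence → lowest index on ties
        order[step] = pick
        scores[step] = crit[pick]
        selected[pick] = True
        if step < k - 1:
            red_sum += _mi_one_vs_all(S[:, pick], S, onehot)
    return RankedList(order=order + 1, scores=scores, criterion=f"mRMR-{form}")


def write_ranked(ranked: RankedList, path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tfeature_index\tscore\tcriterion\n")
        for r, (idx, score) in enumerate(zip(ranked.order, ranked.scores), start=1):
            fh.write(f"{r}\t{int(idx)}\t{score:.10g}\t{ranked.criterion}\n")


def read_ranked(path) -> RankedList:
    order, scores, criterion = [], [], "?"
    with open(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                continue
            order.append(int(parts[1]))
            scores.append(float(parts[2]))
            criterion = parts[3]
    return RankedList(np.asarray(order), np.asarray(scores), criterion)
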