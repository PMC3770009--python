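"""Final RBF-kernel SVM: grid-searched training, prediction, persistence.

The classifier is trained on the optimal feature subset found by IFS. Both
the penalty C and the kernel width γ are selected from powers of two,
2⁻⁷ … 2⁸ by default (a 16 × 16 = 256-point grid), by mean accuracy under
stratified 5-fold cross-validation; ties break toward the smaller C, then
the smaller γ. The chosen pair is refit on all data.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

DEFAULT_GRID: np.ndarray = 2.0 ** np.arange(-7, 9)


@dataclass
class TrainedModel:
    """A fitted RBF-SVM plus everything needed to apply it reproducibly.

    ``selected_feature_indices`` are 1-based positions into the descriptor
    table; ``descriptor_checksum`` ties the model to the feature layout it
    was trained on. ``grid_scores`` holds the mean CV accuracy for every
    (C, γ) pair evaluated, ``grid_scores[i, j]`` for ``C_grid[i]`` and
    ``gamma_grid[j]``.
    """

    selected_feature_indices: np.ndarray
    C: float
    gamma: float
    classifier: SVC
    seed: int
    descriptor_checksum: str | None = None
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None
    C_grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    gamma_grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    grid_scores: np.ndarray | None = None

    @property
    def n_grid_evaluations(self) -> int:
        return 0 if self.grid_scores is None else int(self.grid_scores.size)


def _cv_accuracy(X, y, C, gamma, splits) -> float:
    correct = 0
    for train_idx, test_idx in splits:
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
        clf.fit(X[train_idx], y[train_idx])
        correct += int(np.sum(clf.predict(X[test_idx]) == y[test_idx]))
    return correct / sum(len(t) for _, t in splits)


def grid_search_train(
    X,
    y,
    C_grid=None,
    gamma_grid=None,
    folds: int = 5,
    seed: int = 0,
    selected_feature_indices=None,
    descriptor_checksum: str | None = None,
    standardize: bool = False,
) -> TrainedModel:
    """Grid-search C and γ by stratified k-fold CV accuracy, refit on all data.

    ``X`` must already be restricted to the selected feature subset;
    ``selected_feature_indices`` (1-based) is stored as metadata for
    prediction-time validation. Fold assignment is seeded and stratified.
    Every grid pair is evaluated; ties break toward smaller C, then smaller γ.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    C_grid = DEFAULT_GRID.copy() if C_grid is None else np.asarray(C_grid, dtype=float)
    gamma_grid = DEFAULT_GRID.copy() if gamma_grid is None else np.asarray(gamma_grid, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("grid search needs both classes present")
    if folds > counts.min():
        raise ValueError(
            f"{folds}-fold CV infeasible: minority class has only {counts.min()} samples"
        )
    mean = std = None
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        X = (X - mean) / std
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    scores = np.empty((C_grid.size, gamma_grid.size))
    best = (-np.inf, None, None)
    for i, C in enumerate(C_grid):
        for j, gamma in enumerate(gamma_grid):
            acc = _cv_accuracy(X, y, C, gamma, splits)
            scores[i, j] = acc
            if acc > best[0]:  # strict: ties keep the earlier (smaller C, γ) pair
                best = (acc, C, gamma)
    _, C_best, gamma_best = best
    clf = SVC(kernel="rbf", C=C_best, gamma=gamma_best)
    clf.fit(X, y)
    if selected_feature_indices is None:
        selected_feature_indices = np.arange(1, X.shape[1] + 1)
    return TrainedModel(
        selected_feature_indices=np.asarray(selected_feature_indices, dtype=int),
        C=float(C_best),
        gamma=float(gamma_best),
        classifier=clf,
        seed=seed,
        descriptor_checksum=descriptor_checksum,
        scaler_mean=mean,
        scaler_std=std,
        C_grid=C_grid,
        gamma_grid=gamma_grid,
        grid_scores=scores,
    )


def predict(model: TrainedModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Labels and decision scores for rows of ``X`` (already feature-subset).

    The decision score is the signed distance to the separating surface; its
    sign always agrees with the predicted label.
    """
    X = np.asarray(X, dtype=float)
    k = model.selected_feature_indices.size
    if X.ndim != 2 or X.shape[1] != k:
        raise ValueError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns; "
            f"model expects the {k} selected features "
            f"{model.selected_feature_indices.tolist()}"
        )
    if X.shape[0] == 0:
        return np.zeros(0, dtype=int), np.zeros(0)
    if model.scaler_mean is not None:
        X = (X - model.scaler_mean) / model.scaler_std
    labels = model.classifier.predict(X).astype(int)
    scores = model.classifier.decision_function(X)
    return labels, scores


def jackknife_svm(X, y, C: float, gamma: float) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out predictions and decision scores with fixed (C, γ)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    pred = np.empty(n, dtype=int)
    scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
        clf.fit(X[mask], y[mask])
        pred[i] = int(clf.predict(X[i: i + 1])[0])
        scores[i] = float(clf.decision_function(X[i: i + 1])[0])
        mask[i] = True
    return pred, scores


_MAGIC = b"pupsite-model-v1"


def save_model(model: TrainedModel, path) -> None:
    """Persist a model with an integrity digest over the pickled payload."""
    payload = pickle.dumps(model, protocol=4)
    digest = hashlib.sha256(payload).hexdigest().encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC + b"\n" + digest + b"\n" + payload)


def load_model(path, descriptors=None) -> TrainedModel:
    """Load a model; refuses tampered files and descriptor-layout mismatches.

    When ``descriptors`` (the current descriptor table) is given and the
    model carries a checksum, the two must agree.
    """
    with open(path, "rb") as fh:
        magic = fh.readline().rstrip(b"\n")
        digest = fh.readline().rstrip(b"\n")
        payload = fh.read()
    if magic != _MAGIC:
        raise ValueError(f"{path}: not a pupsite model file")
    if hashlib.sha256(payload).hexdigest().encode() != digest:
        raise ValueError(f"{path}: integrity check failed (file modified?)")
    model = pickle.loads(payload)
    if descriptors is not None and model.descriptor_checksum is not None:
        from .encoding import descriptor_checksum as checksum_fn

        if checksum_fn(descriptors) != model.descriptor_checksum:
            raise ValueError(
                f"{path}: descriptor-table checksum mismatch; the model was "
                "trained under a different feature layout"
            )
    return model
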