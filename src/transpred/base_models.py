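"""RBF-kernel SVM base classifiers over composition feature matrices.

Hyperparameters (C, gamma) are chosen by exhaustive grid search with
stratified k-fold cross-validated accuracy; ties break toward the
smaller C, then the smaller gamma, making selection deterministic.
Features are used as-is: composition components already share the [0, 1]
scale, so no extra standardization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .tcdb_transfer import Prediction

# 2^-5 .. 2^15 and 2^-15 .. 2^3, the classic coarse RBF grid
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-5, 17, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-15, 5, 2))


class ModelError(ValueError):
    """Raised for invalid training or prediction input."""


@dataclass
class FeatureMatrix:
    """Row-per-sequence real matrix with named columns and optional labels."""

    ids: list[str]
    columns: list[str]
    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ModelError("feature values must be a 2-D array")
        if self.values.shape != (len(self.ids), len(self.columns)):
            raise ModelError(
                f"shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.columns)} columns"
            )
        if self.labels is not None and len(self.labels) != len(self.ids):
            raise ModelError("label count does not match row count")
        if np.isnan(self.values).any():
            raise ModelError("feature matrix contains missing values")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.columns)
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def subset(self, indices: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            ids=[self.ids[i] for i in indices],
            columns=self.columns,
            values=self.values[indices],
            labels=None if self.labels is None else [self.labels[i] for i in indices],
        )


@dataclass
class FittedClassifier:
    """A trained SVM plus its schema and selection metadata."""

    feature_kind: str
    columns: list[str]
    C: float
    gamma: float
    estimator: SVC
    cv_accuracy: float
    seed: int
    grid_shape: tuple[int, int] = (0, 0)


def _check_labels(labels: list[str] | None) -> np.ndarray:
    if labels is None:
        raise ModelError("feature matrix has no labels")
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ModelError(f"training data has a single class: {classes.tolist()}")
    return y


def grid_search_train(
    features: FeatureMatrix,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
    feature_kind: str = "unknown",
) -> FittedClassifier:
    """Pick (C, gamma) by mean stratified k-fold CV accuracy, then refit on all rows."""
    if not c_grid or not gamma_grid:
        raise ModelError("hyperparameter grid is empty")
    y = _check_labels(features.labels)
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ModelError(
            f"folds={folds} exceeds the smallest class count {counts.min()}"
        )
    X = features.values
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(X, y))

    best: tuple[float, float, float] | None = None  # (accuracy, C, gamma)
    for C in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            accs = []
            for train_idx, test_idx in splits:
                clf = SVC(C=C, gamma=gamma, kernel="rbf", random_state=seed)
                clf.fit(X[train_idx], y[train_idx])
                accs.append(float((clf.predict(X[test_idx]) == y[test_idx]).mean()))
            acc = float(np.mean(accs))
            # strict > keeps the smallest C then gamma on ties
            if best is None or acc > best[0]:
                best = (acc, C, gamma)

    acc, C, gamma = best
    final = SVC(C=C, gamma=gamma, kernel="rbf", random_state=seed)
    final.fit(X, y)
    return FittedClassifier(
        feature_kind=feature_kind,
        columns=list(features.columns),
        C=C,
        gamma=gamma,
        estimator=final,
        cv_accuracy=acc,
        seed=seed,
        grid_shape=(len(c_grid), len(gamma_grid)),
    )


def fit_fixed(
    features: FeatureMatrix,
    C: float,
    gamma: float,
    seed: int = 0,
    feature_kind: str = "unknown",
) -> FittedClassifier:
    """Fit an SVM at fixed hyperparameters (used for per-fold refits)."""
    y = _check_labels(features.labels)
    clf = SVC(C=C, gamma=gamma, kernel="rbf", random_state=seed)
    clf.fit(features.values, y)
    return FittedClassifier(
        feature_kind=feature_kind,
        columns=list(features.columns),
        C=C,
        gamma=gamma,
        estimator=clf,
        cv_accuracy=float("nan"),
        seed=seed,
    )


def predict(classifier: FittedClassifier, features: FeatureMatrix) -> list[Prediction]:
    """One deterministic T/NT prediction per row.

    The column schema must match training exactly (names and order).
    """
    if list(features.columns) != classifier.columns:
        missing = set(classifier.columns) - set(features.columns)
        extra = set(features.columns) - set(classifier.columns)
        raise ModelError(
            f"feature schema mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            if missing or extra
            else "feature columns are permuted relative to the training schema"
        )
    if len(features) == 0:
        return []
    labels = classifier.estimator.predict(features.values)
    return [
        Prediction(seq_id, str(label), source=classifier.feature_kind)
        for seq_id, label in zip(features.ids, labels)
    ]
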