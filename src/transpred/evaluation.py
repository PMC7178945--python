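"""Confusion-matrix metrics, repeated stratified CV, and prediction correlation.

Sensitivity, specificity and accuracy are reported in percent; the
Matthews correlation coefficient (MCC) lies in [-1, 1] and is defined as
0 when its denominator vanishes (the "no better than random" convention).

Per-repeat CV metrics are computed from confusion counts pooled across
the k folds, not by averaging per-fold metrics: pooling is stable when
folds are small.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


class EvaluationError(ValueError):
    """Raised for invalid evaluation input."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts; reals are allowed for rate-implied matrices."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion counts must be nonnegative")
        if self.total == 0:
            raise EvaluationError("confusion matrix is all zeros")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


def confusion_from_predictions(
    true_labels: Sequence[str], predicted: Sequence[str], positive: str = "T"
) -> ConfusionMatrix:
    if len(true_labels) != len(predicted):
        raise EvaluationError("label/prediction length mismatch")
    tp = fp = fn = tn = 0
    for t, p in zip(true_labels, predicted):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity/specificity/accuracy in percent; MCC in [-1, 1]."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float

    def rounded(self, pct_dp: int = 2, mcc_dp: int = 2) -> "MetricsReport":
        return MetricsReport(
            round(self.sensitivity, pct_dp),
            round(self.specificity, pct_dp),
            round(self.accuracy, pct_dp),
            round(self.mcc, mcc_dp),
        )


def matthews_corrcoef(cm: ConfusionMatrix) -> float:
    """MCC from confusion counts; 0 when the denominator is 0."""
    num = cm.tp * cm.tn - cm.fp * cm.fn
    den = math.sqrt(
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    return num / den if den > 0 else 0.0


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, MCC.

    Sensitivity (specificity) is 0 when there are no positives (negatives);
    accuracy is always defined because the total is positive.
    """
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    sens = 100.0 * cm.tp / pos if pos > 0 else 0.0
    spec = 100.0 * cm.tn / neg if neg > 0 else 0.0
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    return MetricsReport(sens, spec, acc, matthews_corrcoef(cm))


def confusion_from_rates(
    sensitivity_pct: float,
    specificity_pct: float,
    n_pos: float,
    n_neg: float,
    rounding: str = "integer",
) -> ConfusionMatrix:
    """Reconstruct a confusion matrix from printed rates and class sizes.

    ``integer`` rounds TP and TN to the nearest integer before deriving
    FN and FP; ``exact`` keeps the real-valued products.
    """
    if not (0 <= sensitivity_pct <= 100 and 0 <= specificity_pct <= 100):
        raise EvaluationError("rates must lie in [0, 100]")
    if n_pos < 0 or n_neg < 0:
        raise EvaluationError("class sizes must be nonnegative")
    if rounding not in ("integer", "exact"):
        raise EvaluationError(f"unknown rounding mode {rounding!r}")
    tp = sensitivity_pct * n_pos / 100.0
    tn = specificity_pct * n_neg / 100.0
    if rounding == "integer":
        tp, tn = float(round(tp)), float(round(tn))
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)


@dataclass
class RepeatedCVReport:
    """Mean and sd of each metric over independent CV repeats."""

    k: int
    repeats: int
    seed: int
    per_repeat: list[MetricsReport] = field(default_factory=list)

    def _stat(self, attr: str) -> tuple[float, float]:
        vals = np.array([getattr(r, attr) for r in self.per_repeat])
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    @property
    def mean(self) -> MetricsReport:
        return MetricsReport(*(self._stat(a)[0] for a in
                               ("sensitivity", "specificity", "accuracy", "mcc")))

    @property
    def sd(self) -> MetricsReport:
        return MetricsReport(*(self._stat(a)[1] for a in
                               ("sensitivity", "specificity", "accuracy", "mcc")))


def repeated_cv(
    learner_factory: Callable[[], "CVLearner"],
    sequences_or_ids: Sequence,
    labels: Sequence[str],
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> RepeatedCVReport:
    """Repeated stratified k-fold CV with pooled-fold confusion counts.

    ``learner_factory`` returns a fresh object with ``fit(items, labels)``
    and ``predict(items) -> list[str]`` for each fold. Each repeat draws a
    fresh fold plan from the master seed.
    """
    labels = list(labels)
    items = list(sequences_or_ids)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < k:
        raise EvaluationError(
            f"each class needs >= k={k} members, got {dict(zip(classes, counts))}"
        )
    y = np.asarray(labels)
    report = RepeatedCVReport(k=k, repeats=repeats, seed=seed)
    for rep in range(repeats):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        pooled: ConfusionMatrix | None = None
        for train_idx, test_idx in splitter.split(np.zeros(len(y)), y):
            learner = learner_factory()
            learner.fit([items[i] for i in train_idx], [labels[i] for i in train_idx])
            preds = learner.predict([items[i] for i in test_idx])
            cm = confusion_from_predictions([labels[i] for i in test_idx], preds)
            pooled = cm if pooled is None else pooled + cm
        report.per_repeat.append(compute_metrics(pooled))
    return report


def prediction_correlation(meta: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between binary base-prediction columns.

    Input: one column per base classifier with values in {0, 1} (a
    trailing ``label`` column, if present, is ignored). Constant columns
    have undefined correlation and are reported as NaN.
    """
    cols = [c for c in meta.columns if c != "label"]
    if len(meta) < 2:
        raise EvaluationError("need at least 2 rows for correlation")
    data = meta[cols].astype(float)
    bad = data.apply(lambda s: ~s.isin([0.0, 1.0]).all())
    if bad.any():
        raise EvaluationError(
            f"non-binary prediction columns: {list(data.columns[bad])}"
        )
    corr = data.corr(method="pearson")
    # pandas leaves constant-column diagonals as NaN too; force diag to 1
    # only where the column is non-constant
    for c in cols:
        if data[c].nunique() > 1:
            corr.loc[c, c] = 1.0
    return corr
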