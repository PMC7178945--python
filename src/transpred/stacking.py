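"""Stacked ensemble: six base classifiers aggregated by gradient boosting.

Three SVM bases consume psi-composition features (psiAAC, psiPAAC,
psiPseAAC); three rule bases transfer annotation by homology under the
built-in threshold profiles. The meta-classifier is trained on base
predictions generated by stratified cross-validation, so that the
meta-feature row for an instance always comes from models that never saw
that instance; deterministic rule bases need no such care and are
evaluated directly.

Meta-features are hard labels encoded {NT: 0, T: 1}; the column order is
fixed to BASE_NAMES and serialized models reject permuted inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .base_models import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    FeatureMatrix,
    FittedClassifier,
    ModelError,
    fit_fixed,
    grid_search_train,
    predict as svm_predict,
)
from .descriptors import PseAACParams
from .homologs import HomologSet, psi_compose
from .seqio import LabeledDataset, ProteinSequence
from .tcdb_transfer import (
    BlastHit,
    Prediction,
    builtin_profiles,
    predict_by_homology,
)

logger = logging.getLogger(__name__)

SVM_BASE_NAMES: tuple[str, ...] = ("psiAAC", "psiPAAC", "psiPseAAC")
RULE_BASE_NAMES: tuple[str, ...] = ("TCDB_exact", "TCDB_high", "TCDB_med")
BASE_NAMES: tuple[str, ...] = SVM_BASE_NAMES + RULE_BASE_NAMES

_KIND_BY_BASE = {"psiAAC": "AAC", "psiPAAC": "PAAC", "psiPseAAC": "PseAAC"}
_LABEL_CODE = {"NT": 0, "T": 1}
_CODE_LABEL = {0: "NT", 1: "T"}

DEFAULT_META_GRID: tuple[tuple[int, int], ...] = tuple(
    (n, d) for n in (50, 100, 150) for d in (1, 2, 3)
)


@dataclass
class SearchArtifacts:
    """Pre-computed search results for a set of queries.

    ``homologs`` maps query id -> HomologSet (psi-composition input);
    ``tcdb_hits`` maps query id -> hit list against the transporter
    database (rule-base input). Queries absent from either mapping fall
    back to an empty homolog set / zero hits.
    """

    homologs: dict[str, HomologSet] = field(default_factory=dict)
    tcdb_hits: dict[str, list[BlastHit]] = field(default_factory=dict)

    def homolog_set(self, query: ProteinSequence) -> HomologSet:
        return self.homologs.get(query.id, HomologSet(query=query))

    def hits_for(self, query_id: str) -> list[BlastHit]:
        return self.tcdb_hits.get(query_id, [])


@dataclass
class StackingConfig:
    """Everything that parameterizes training, driven by one master seed."""

    seed: int = 0
    meta_folds: int = 10
    svm_inner_folds: int = 5
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    pseaac: PseAACParams = field(default_factory=PseAACParams)
    meta_grid: tuple[tuple[int, int], ...] = DEFAULT_META_GRID
    meta_learning_rate: float = 0.1


def compute_psi_features(
    data: LabeledDataset | list[ProteinSequence],
    artifacts: SearchArtifacts,
    kind: str,
    pseaac: PseAACParams | None = None,
    labels: list[str] | None = None,
) -> FeatureMatrix:
    """psi-composition feature matrix for every sequence, in dataset order."""
    if isinstance(data, LabeledDataset):
        sequences = data.sequences
        labels = data.labels
    else:
        sequences = data
    rows, components = [], None
    for seq in sequences:
        vec = psi_compose(artifacts.homolog_set(seq), kind, pseaac)
        rows.append(vec.values)
        components = vec.components
    return FeatureMatrix(
        ids=[s.id for s in sequences],
        columns=list(components),
        values=np.vstack(rows) if rows else np.empty((0, 0)),
        labels=labels,
    )


def rule_predictions(
    sequences: list[ProteinSequence], artifacts: SearchArtifacts
) -> dict[str, dict[str, str]]:
    """{profile name: {query id: label}} under the three built-in profiles."""
    out: dict[str, dict[str, str]] = {name: {} for name in RULE_BASE_NAMES}
    for profile in builtin_profiles():
        for seq in sequences:
            pred = predict_by_homology(
                artifacts.hits_for(seq.id), profile, query_id=seq.id
            )
            out[profile.name][seq.id] = pred.label
    return out


def generate_meta_features(
    data: LabeledDataset,
    artifacts: SearchArtifacts,
    config: StackingConfig,
    svm_hyperparams: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Cross-validated base predictions, one row per training instance.

    SVM columns: for each of the k stratified folds, the bases are
    retrained (at the given hyperparameters) on the other k-1 folds and
    predict the held-out fold. Rule columns are computed directly — the
    rules do not train, so their output is fold-independent.
    """
    k = config.meta_folds
    if k < 2:
        raise ModelError("meta_folds must be >= 2")
    labels = np.asarray(data.labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < k:
        raise ModelError(
            f"each class needs >= k={k} members, got {dict(zip(classes, counts.tolist()))}"
        )

    features = {
        name: compute_psi_features(data, artifacts, _KIND_BY_BASE[name], config.pseaac)
        for name in SVM_BASE_NAMES
    }
    meta = pd.DataFrame(
        index=[s.id for s in data.sequences], columns=list(BASE_NAMES), dtype=float
    )

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    for train_idx, test_idx in splitter.split(np.zeros(len(labels)), labels):
        for name in SVM_BASE_NAMES:
            C, gamma = svm_hyperparams[name]
            fold_model = fit_fixed(
                features[name].subset(train_idx), C, gamma,
                seed=config.seed, feature_kind=name,
            )
            for pred in svm_predict(fold_model, features[name].subset(test_idx)):
                meta.loc[pred.sequence_id, name] = _LABEL_CODE[pred.label]

    rules = rule_predictions(data.sequences, artifacts)
    for name in RULE_BASE_NAMES:
        for seq in data.sequences:
            meta.loc[seq.id, name] = _LABEL_CODE[rules[name][seq.id]]

    meta["label"] = [_LABEL_CODE[l] for l in data.labels]
    if meta.isna().any().any():
        raise ModelError("meta-feature generation left unassigned cells")
    return meta


def _train_meta(meta: pd.DataFrame, config: StackingConfig) -> GradientBoostingClassifier:
    """Small grid over (trees, depth) by inner 5-fold CV accuracy."""
    X = meta[list(BASE_NAMES)].to_numpy()
    y = meta["label"].to_numpy()
    inner = StratifiedKFold(n_splits=5, shuffle=True, random_state=config.seed)
    splits = list(inner.split(X, y))
    best = None
    for n_estimators, depth in config.meta_grid:
        accs = []
        for tr, te in splits:
            gbm = GradientBoostingClassifier(
                n_estimators=n_estimators,
                max_depth=depth,
                learning_rate=config.meta_learning_rate,
                random_state=config.seed,
            )
            gbm.fit(X[tr], y[tr])
            accs.append(float((gbm.predict(X[te]) == y[te]).mean()))
        acc = float(np.mean(accs))
        if best is None or acc > best[0]:
            best = (acc, n_estimators, depth)
    _, n_estimators, depth = best
    final = GradientBoostingClassifier(
        n_estimators=n_estimators,
        max_depth=depth,
        learning_rate=config.meta_learning_rate,
        random_state=config.seed,
    )
    final.fit(X, y)
    return final


@dataclass
class StackingModel:
    """Fitted base SVMs, rule profiles, and the meta-classifier."""

    svm_models: dict[str, FittedClassifier]
    meta_model: GradientBoostingClassifier
    config: StackingConfig
    meta_columns: tuple[str, ...] = BASE_NAMES

    def predict_from_meta(self, meta: pd.DataFrame) -> list[str]:
        """Predict from an explicit meta-feature frame.

        Column names and order must match the training schema exactly;
        permuted columns are rejected rather than silently reordered.
        """
        cols = [c for c in meta.columns if c != "label"]
        if tuple(cols) != tuple(self.meta_columns):
            raise ModelError(
                f"meta columns {cols} do not match schema {list(self.meta_columns)}"
            )
        codes = self.meta_model.predict(meta[cols].to_numpy())
        return [_CODE_LABEL[int(c)] for c in codes]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "StackingModel":
        model = joblib.load(path)
        if not isinstance(model, StackingModel):
            raise ModelError(f"{path} does not contain a stacking model bundle")
        return model


def train_stacking(
    data: LabeledDataset,
    artifacts: SearchArtifacts,
    config: StackingConfig | None = None,
) -> StackingModel:
    """Full training pass: grid-search the SVM bases, generate the
    cross-validated meta-dataset, fit the meta-classifier, and refit the
    bases on all rows."""
    config = config or StackingConfig()
    svm_models: dict[str, FittedClassifier] = {}
    for name in SVM_BASE_NAMES:
        features = compute_psi_features(data, artifacts, _KIND_BY_BASE[name], config.pseaac)
        svm_models[name] = grid_search_train(
            features,
            c_grid=config.c_grid,
            gamma_grid=config.gamma_grid,
            folds=config.svm_inner_folds,
            seed=config.seed,
            feature_kind=name,
        )
        logger.info(
            "base %s: C=%g gamma=%g (CV accuracy %.3f)",
            name, svm_models[name].C, svm_models[name].gamma,
            svm_models[name].cv_accuracy,
        )

    hyper = {name: (m.C, m.gamma) for name, m in svm_models.items()}
    meta = generate_meta_features(data, artifacts, config, hyper)
    meta_model = _train_meta(meta, config)
    return StackingModel(svm_models=svm_models, meta_model=meta_model, config=config)


def base_votes(
    model: StackingModel, query: ProteinSequence, artifacts: SearchArtifacts
) -> dict[str, str]:
    """The six base-classifier labels for one query."""
    votes: dict[str, str] = {}
    hset = artifacts.homolog_set(query)
    for name in SVM_BASE_NAMES:
        vec = psi_compose(hset, _KIND_BY_BASE[name], model.config.pseaac)
        fm = FeatureMatrix(
            ids=[query.id], columns=list(vec.components),
            values=vec.values.reshape(1, -1),
        )
        votes[name] = svm_predict(model.svm_models[name], fm)[0].label
    for profile in builtin_profiles():
        votes[profile.name] = predict_by_homology(
            artifacts.hits_for(query.id), profile, query_id=query.id
        ).label
    return votes


def predict_stacking(
    model: StackingModel,
    query: ProteinSequence,
    artifacts: SearchArtifacts,
) -> Prediction:
    """Final ensemble label for one query, plus the base votes as provenance."""
    votes = base_votes(model, query, artifacts)
    row = np.array([[_LABEL_CODE[votes[name]] for name in model.meta_columns]])
    final = _CODE_LABEL[int(model.meta_model.predict(row)[0])]
    return Prediction(query.id, final, source="ensemble")


def predict_report(
    model: StackingModel,
    queries: list[ProteinSequence],
    artifacts: SearchArtifacts,
) -> pd.DataFrame:
    """Per-query table of the six base votes and the final ensemble label."""
    rows = []
    for query in queries:
        votes = base_votes(model, query, artifacts)
        enc = np.array([[_LABEL_CODE[votes[n]] for n in model.meta_columns]])
        final = _CODE_LABEL[int(model.meta_model.predict(enc)[0])]
        rows.append({"id": query.id, **votes, "final": final})
    return pd.DataFrame(rows, columns=["id", *BASE_NAMES, "final"])
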