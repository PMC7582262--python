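"""Extremely randomized trees classification of hot spots.

The classifier is scikit-learn's ExtraTreesClassifier with the settings that
work well on small, imbalanced residue datasets: 500 trees, bootstrap
replicas, and per-subsample balanced class weights (class weights recomputed
inversely proportional to class frequencies inside each tree's bootstrap
sample, which counters the roughly 1:3 HS:NS imbalance). Hyperparameters not
listed in :class:`ModelParams` are frozen at documented defaults: unlimited
tree depth, sqrt(n_features) split candidates, minimum leaf size 1.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from hotseq.splitting import HS, NS


class ModelSchemaError(ValueError):
    """Feature matrix does not match the model's expected columns."""


class TrainingError(ValueError):
    """Invalid training inputs (e.g. a single class)."""


@dataclass(frozen=True)
class ModelParams:
    """Ensemble hyperparameters; defaults are the tuned production settings."""

    n_trees: int = 500
    bootstrap_replicas: bool = True
    class_weighting: str | None = "balanced_subsample"
    random_seed: int = 0
    max_features: str | float = "sqrt"
    max_depth: int | None = None
    min_samples_leaf: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def to_estimator(self) -> ExtraTreesClassifier:
        return ExtraTreesClassifier(
            n_estimators=self.n_trees,
            bootstrap=self.bootstrap_replicas,
            class_weight=self.class_weighting,
            random_state=self.random_seed,
            max_features=self.max_features,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
        )


@dataclass
class TrainedModel:
    """A fitted ensemble plus the frozen feature schema it expects."""

    estimator: ExtraTreesClassifier
    feature_names: tuple[str, ...]
    params: ModelParams
    training_fingerprint: dict[str, int] = field(default_factory=dict)
    property_checksum: str | None = None

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def _as_matrix(features: pd.DataFrame | np.ndarray, feature_names: Sequence[str] | None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(features, pd.DataFrame):
        from hotseq.features import ID_COLUMNS

        cols = [c for c in features.columns if c not in ID_COLUMNS]
        if feature_names is not None:
            missing = [c for c in feature_names if c not in features.columns]
            if missing:
                raise ModelSchemaError(f"feature columns missing: {missing[:5]}...")
            cols = list(feature_names)
        return features[cols].to_numpy(dtype=float), tuple(cols)
    matrix = np.asarray(features, dtype=float)
    names = tuple(feature_names) if feature_names is not None else tuple(f"f{i}" for i in range(matrix.shape[1]))
    if matrix.shape[1] != len(names):
        raise ModelSchemaError(f"matrix has {matrix.shape[1]} columns, expected {len(names)}")
    return matrix, names


def _binary_labels(labels: Sequence[str] | np.ndarray) -> np.ndarray:
    array = np.asarray(labels)
    if array.dtype.kind in "biu":
        return array.astype(int)
    return (array == HS).astype(int)


def train(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | np.ndarray,
    params: ModelParams | None = None,
    *,
    feature_names: Sequence[str] | None = None,
    amino_acids: Sequence[str] | None = None,
    property_checksum: str | None = None,
) -> TrainedModel:
    """Fit the extremely randomized trees ensemble.

    ``labels`` may be "HS"/"NS" strings or 0/1 integers (1 = hot spot).
    Training is reproducible under ``params.random_seed``.
    """
    params = params or ModelParams()
    matrix, names = _as_matrix(features, feature_names)
    y = _binary_labels(labels)
    if len(y) != matrix.shape[0]:
        raise TrainingError("one label required per feature row")
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")

    estimator = params.to_estimator()
    estimator.fit(matrix, y)

    fingerprint: dict[str, int] = {}
    if amino_acids is not None:
        for aa, label in zip(amino_acids, y):
            key = f"{aa}:{HS if label else NS}"
            fingerprint[key] = fingerprint.get(key, 0) + 1
    return TrainedModel(
        estimator=estimator,
        feature_names=names,
        params=params,
        training_fingerprint=fingerprint,
        property_checksum=property_checksum,
    )


def predict_hs_probability(model: TrainedModel, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-row probability of the hot-spot class, in [0, 1].

    The ensemble's positive-class leaf-frequency average; turning the
    probability into a class is the calibration module's job.
    """
    matrix, names = _as_matrix(features, model.feature_names if isinstance(features, pd.DataFrame) else None)
    if matrix.shape[1] != model.n_features:
        raise ModelSchemaError(
            f"feature width {matrix.shape[1]} does not match model expectation {model.n_features}"
        )
    positive_index = list(model.estimator.classes_).index(1)
    return model.estimator.predict_proba(matrix)[:, positive_index]


def grid_search(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | np.ndarray,
    grid: dict[str, list],
    folds: int = 10,
    *,
    scoring: str = "f1",
    random_seed: int = 0,
) -> tuple[ModelParams, pd.DataFrame]:
    """Exhaustive hyperparameter search by stratified k-fold cross-validation.

    ``grid`` maps :class:`ModelParams` field names (n_trees,
    bootstrap_replicas, class_weighting, ...) to candidate values. Returns the
    argmax candidate by mean validation score plus the full per-candidate
    score table (one row per candidate, one column per fold).
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    matrix, names = _as_matrix(features, None)
    y = _binary_labels(labels)
    minority = int(np.bincount(y).min())
    if folds > minority:
        raise TrainingError(f"fold count {folds} exceeds minority-class size {minority}")

    rename = {
        "n_trees": "n_estimators",
        "bootstrap_replicas": "bootstrap",
        "class_weighting": "class_weight",
    }
    sk_grid = {rename.get(k, k): v for k, v in grid.items()}
    base = ModelParams(random_seed=random_seed).to_estimator()
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_seed)
    search = GridSearchCV(base, sk_grid, scoring=scoring, cv=cv, refit=False)
    search.fit(matrix, y)

    results = pd.DataFrame(search.cv_results_)
    inverse = {v: k for k, v in rename.items()}
    best_raw = results.loc[results["rank_test_score"].idxmin(), "params"]
    best_kwargs = {inverse.get(k, k): v for k, v in best_raw.items()}
    best = ModelParams(random_seed=random_seed, **best_kwargs)

    fold_cols = [c for c in results.columns if c.startswith("split") and c.endswith("test_score")]
    table = results[["params"] + fold_cols + ["mean_test_score", "rank_test_score"]].copy()
    return best, table


def baseline_classifiers(random_seed: int = 0) -> dict[str, object]:
    """Default-settings comparison models (optional hook, not the pipeline).

    Neural network, random forest, AdaBoost and support-vector machine with
    library defaults, for side-by-side evaluation against the tree ensemble.
    """
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    return {
        "neural_network": MLPClassifier(random_state=random_seed, max_iter=500),
        "random_forest": RandomForestClassifier(random_state=random_seed),
        "adaboost": AdaBoostClassifier(random_state=random_seed),
        "svm": SVC(random_state=random_seed, probability=True),
    }


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize the fitted ensemble together with its schema and provenance."""
    bundle = {
        "format_version": 1,
        "estimator": model.estimator,
        "feature_names": list(model.feature_names),
        "params": asdict(model.params),
        "training_fingerprint": model.training_fingerprint,
        "property_checksum": model.property_checksum,
    }
    joblib.dump(bundle, path)


def load_model(path: str | Path, *, expected_property_checksum: str | None = None) -> TrainedModel:
    """Load a serialized model; refuses to predict against a mismatched property table."""
    bundle = joblib.load(path)
    if bundle.get("format_version") != 1:
        raise ValueError(f"unsupported model format: {bundle.get('format_version')!r}")
    stored = bundle.get("property_checksum")
    if expected_property_checksum is not None and stored is not None and stored != expected_property_checksum:
        raise ModelSchemaError(
            "property-table checksum mismatch: the model was trained with a different table"
        )
    return TrainedModel(
        estimator=bundle["estimator"],
        feature_names=tuple(bundle["feature_names"]),
        params=ModelParams(**bundle["params"]),
        training_fingerprint=bundle["training_fingerprint"],
        property_checksum=stored,
    )


def property_table_checksum(table) -> str:
    """Stable checksum of a property table, stored with trained models."""
    payload = table.frame.round(8).to_csv().encode()
    return hashlib.sha256(payload).hexdigest()
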