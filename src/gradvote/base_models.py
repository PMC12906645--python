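"""The five probabilistic base learners behind a uniform contract.

Logistic regression, decision tree, random forest, k-nearest neighbours
and a multi-layer perceptron — one statistical, one interpretable, one
bagged, one distance-based and one neural learner — are each tuned by
exhaustive grid search under stratified k-fold cross-validation and then
refitted on the full training part. Their positive-class probabilities
are what the ensemble weights combine; learner internals are delegated to
scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .datatable import FeatureTable

__all__ = [
    "FAMILIES",
    "DEFAULT_GRIDS",
    "BaseModelSpec",
    "FittedBaseModel",
    "tune",
    "predict_matrix",
    "save_models",
    "load_models",
]

FAMILIES = ("LR", "DTC", "RFC", "KNN", "MLP")

# Modest per-family grids; experiment configuration, overridable per run.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "LR": {"C": [0.1, 1.0, 10.0]},
    "DTC": {"max_depth": [3, 5, None]},
    "RFC": {"n_estimators": [50, 100]},
    "KNN": {"n_neighbors": [3, 5, 7]},
    "MLP": {"hidden_layer_sizes": [(25,), (50,)]},
}


def _make_estimator(family: str, seed: int):
    if family == "LR":
        return LogisticRegression(max_iter=1000)
    if family == "DTC":
        return DecisionTreeClassifier(random_state=seed)
    if family == "RFC":
        return RandomForestClassifier(random_state=seed)
    if family == "KNN":
        return KNeighborsClassifier()
    if family == "MLP":
        return MLPClassifier(max_iter=400, random_state=seed)
    raise ValueError(f"unknown base-model family {family!r}; expected one of {FAMILIES}")


@dataclass
class BaseModelSpec:
    """One family plus its hyperparameter grid and CV settings."""

    family: str
    grid: dict[str, list] | None = None
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class FittedBaseModel:
    """A tuned, refitted learner exposing positive-class probabilities."""

    family: str
    chosen_hyperparameters: dict
    cv_accuracy: float
    estimator: object
    feature_names: list[str]
    cv_results: list[tuple[dict, float]] = field(default_factory=list)

    def predict_proba_pos(self, table: FeatureTable) -> np.ndarray:
        """P(class 1) per instance; columns must match the training schema."""
        if list(table.X.columns) != self.feature_names:
            raise ValueError(
                f"feature schema mismatch for {self.family}: "
                f"expected {self.feature_names}, got {list(table.X.columns)}"
            )
        proba = self.estimator.predict_proba(table.X.to_numpy(dtype=float))
        pos_col = list(self.estimator.classes_).index(1)
        return np.clip(proba[:, pos_col], 0.0, 1.0)


def tune(spec: BaseModelSpec, train: FeatureTable) -> FittedBaseModel:
    """Grid search with stratified k-fold CV; refit the winner on all of train.

    Every grid configuration is scored by mean fold accuracy; ties go to
    the first-listed configuration. Deterministic given the spec seed
    (fold shuffling and stochastic learners share it).
    """
    train.require_binary()
    if len(set(train.y.tolist())) < 2:
        raise ValueError("both classes must be present in the training part")
    X = train.X.to_numpy(dtype=float)
    y = train.y
    cv = StratifiedKFold(n_splits=spec.k_folds, shuffle=True, random_state=spec.seed)
    base = _make_estimator(spec.family, spec.seed)

    results: list[tuple[dict, float]] = []
    for params in ParameterGrid(spec.grid):
        est = clone(base).set_params(**params)
        scores = cross_val_score(est, X, y, cv=cv, scoring="accuracy")
        results.append((params, float(np.mean(scores))))
    best_idx = int(np.argmax([acc for _, acc in results]))  # first max wins ties
    best_params, best_acc = results[best_idx]

    final = clone(base).set_params(**best_params)
    final.fit(X, y)
    return FittedBaseModel(
        family=spec.family,
        chosen_hyperparameters=dict(best_params),
        cv_accuracy=best_acc,
        estimator=final,
        feature_names=list(train.X.columns),
        cv_results=results,
    )


def predict_matrix(models: list[FittedBaseModel], table: FeatureTable) -> np.ndarray:
    """Stack per-model positive-class probabilities: row i = model i."""
    if not models:
        raise ValueError("need at least one fitted model")
    return np.vstack([m.predict_proba_pos(table) for m in models])


def save_models(models: list[FittedBaseModel], directory: str | Path) -> None:
    """Persist estimators (joblib) with a JSON sidecar of chosen settings."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {}
    for m in models:
        joblib.dump(m, directory / f"{m.family}.joblib")
        sidecar[m.family] = {
            "chosen_hyperparameters": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in m.chosen_hyperparameters.items()
            },
            "cv_accuracy": m.cv_accuracy,
        }
    (directory / "models.json").write_text(json.dumps(sidecar, indent=2))


def load_models(directory: str | Path, families=FAMILIES) -> list[FittedBaseModel]:
    directory = Path(directory)
    models = []
    for family in families:
        path = directory / f"{family}.joblib"
        if not path.exists():
            raise FileNotFoundError(f"no persisted model for family {family}: {path}")
        models.append(joblib.load(path))
    return models
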