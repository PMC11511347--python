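"""Classifier zoo, grid-search tuning and evaluation metrics.

Seven model families — logistic regression (LR), decision tree (DT),
k-nearest neighbours (kNN), linear discriminant analysis (LDA), RBF support
vector machine (SVM), random forest (RF) and multilayer perceptron (MLP) —
are tuned by exhaustive grid search scored with mean accuracy over
stratified cross-validation on the training pool, then refitted on the full
pool.  The task is 7-class classification over the mixing-ratio groups;
the AMP/ADP/ATP presence triplet is a deterministic map of the predicted
group, so per-analyte accuracy is also reported.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import GridSearchCV, ParameterGrid, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset import GROUP_RATIOS, PRESENCE_BY_GROUP, SpectrumSet

FAMILIES: tuple[str, ...] = ("LR", "DT", "kNN", "LDA", "SVM", "RF", "MLP")

#: Default hyperparameter grids: standard small-data ranges, fully exposed.
DEFAULT_GRIDS: dict[str, list[dict] | dict] = {
    "LR": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "DT": {"max_depth": [2, 3, 4, 5, 6, 7, 8, 9, 10, None]},
    "kNN": {"n_neighbors": [1, 3, 5, 7, 9]},
    "LDA": [{"solver": ["svd"]}, {"solver": ["lsqr"], "shrinkage": ["auto"]}],
    "SVM": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.001, 0.01, 0.1]},
    "RF": {"n_estimators": [100, 300], "max_depth": [None, 5, 10]},
    "MLP": {"hidden_layer_sizes": [(50,), (100,), (100, 50)], "alpha": [1e-4, 1e-3]},
}

#: Singleton grids for fast benchmark sweeps (no tuning search).
FAST_GRIDS: dict[str, dict] = {
    "LR": {"C": [1.0]},
    "DT": {"max_depth": [None]},
    "kNN": {"n_neighbors": [5]},
    "LDA": {"solver": ["svd"]},
    "SVM": {"C": [10.0], "gamma": ["scale"]},
    "RF": {"n_estimators": [100]},
    "MLP": {"hidden_layer_sizes": [(50,)], "alpha": [1e-4]},
}

GRID_PRESETS = {"default": DEFAULT_GRIDS, "fast": FAST_GRIDS}


def base_estimator(family: str, seed: int | None = 0):
    """Untuned scikit-learn estimator for a model family."""
    if family == "LR":
        return LogisticRegression(max_iter=5000, random_state=seed)
    if family == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if family == "kNN":
        return KNeighborsClassifier()
    if family == "LDA":
        return LinearDiscriminantAnalysis()
    if family == "SVM":
        return SVC(kernel="rbf", random_state=seed)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if family == "MLP":
        return MLPClassifier(
            random_state=seed, max_iter=300, early_stopping=True, n_iter_no_change=10
        )
    raise ValueError(f"unknown model family {family!r}; expected one of {FAMILIES}")


@dataclasses.dataclass
class ModelSpec:
    """A model family plus its tuning grid and CV protocol."""

    family: str
    grid: list[dict] | dict | None = None  # None -> preset grid for the family
    preset: str = "default"
    cv_folds: int = 5
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.grid is None:
            self.grid = GRID_PRESETS[self.preset][self.family]
        if len(list(ParameterGrid(self.grid))) == 0:
            raise ValueError("hyperparameter grid is empty")


@dataclasses.dataclass
class TrainedModel:
    family: str
    params: dict
    estimator: object  # fitted sklearn estimator
    n_features: int
    cv_accuracy: float | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"model was trained on {self.n_features} features, got {X.shape[1]}"
            )
        return self.estimator.predict(X)


def tune_and_train(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    """Grid search (stratified CV, accuracy) then refit on the full pool.

    Ties between grid points resolve to the earlier point in grid order.  A
    singleton grid skips the search entirely and is equivalent to a direct
    fit with those parameters.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y)
    points = list(ParameterGrid(spec.grid))
    est = base_estimator(spec.family, spec.seed)
    if len(points) == 1:
        model = clone(est).set_params(**points[0]).fit(X, y)
        return TrainedModel(spec.family, points[0], model, X.shape[1])
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(est, spec.grid, scoring="accuracy", cv=cv, refit=True, n_jobs=1)
    search.fit(X, y)
    return TrainedModel(
        spec.family,
        dict(search.best_params_),
        search.best_estimator_,
        X.shape[1],
        cv_accuracy=float(search.best_score_),
    )


def presence_from_groups(groups: np.ndarray) -> np.ndarray:
    """(n, 3) boolean presence matrix implied by group-id predictions."""
    return np.array([PRESENCE_BY_GROUP[int(g)] for g in np.asarray(groups)], dtype=bool)


@dataclasses.dataclass
class PredictionSet:
    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, int)
        self.y_pred = np.asarray(self.y_pred, int)
        if self.y_true.shape != self.y_pred.shape:
            raise ValueError("y_true and y_pred must align")

    @property
    def presence_true(self) -> np.ndarray:
        return presence_from_groups(self.y_true)

    @property
    def presence_pred(self) -> np.ndarray:
        return presence_from_groups(self.y_pred)


def predict_groups(model: TrainedModel, sset: SpectrumSet) -> PredictionSet:
    return PredictionSet(y_true=sset.y, y_pred=model.predict(sset.intensities))


def accuracy(pred: PredictionSet, level: str = "group") -> float:
    """Fraction correct: whole-group predictions, or individual presence bits."""
    if pred.y_true.size == 0:
        raise ValueError("cannot score an empty prediction set")
    if level == "group":
        return float(np.mean(pred.y_true == pred.y_pred))
    if level == "per_analyte":
        return float(np.mean(pred.presence_true == pred.presence_pred))
    raise ValueError(f"unknown accuracy level {level!r}")


def confusion_matrix(pred: PredictionSet) -> np.ndarray:
    """7x7 counts, rows true group, columns predicted group (ids 1..7)."""
    if pred.y_true.size == 0:
        raise ValueError("cannot build a confusion matrix from no predictions")
    labels = sorted(GROUP_RATIOS)
    return _sk_confusion(pred.y_true, pred.y_pred, labels=labels)


def split_train_test(
    sset: SpectrumSet, seed: int | None = 0
) -> tuple[SpectrumSet, SpectrumSet]:
    """Stratified random half split: each group contributes equal halves."""
    rng = np.random.default_rng(seed)
    y = sset.y
    train_rows: list[int] = []
    test_rows: list[int] = []
    for g in np.unique(y):
        rows = np.nonzero(y == g)[0]
        if rows.size % 2:
            raise ValueError(f"group {g} has odd size {rows.size}; cannot half-split")
        perm = rng.permutation(rows)
        half = rows.size // 2
        train_rows.extend(perm[:half])
        test_rows.extend(perm[half:])
    return sset.subset(sorted(train_rows)), sset.subset(sorted(test_rows))


def make_specs(
    families: Sequence[str] = FAMILIES,
    preset: str = "default",
    cv_folds: int = 5,
    seed: int | None = 0,
) -> list[ModelSpec]:
    return [ModelSpec(f, preset=preset, cv_folds=cv_folds, seed=seed) for f in families]
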