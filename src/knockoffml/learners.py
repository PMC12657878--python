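"""Registry of tree-ensemble learners with a shared tuning protocol.

Five algorithms are registered: lightgbm, xgboost, sklearn gradient boosting
(gbdt), random forest (rf), and extremely randomized trees (extra_trees).
Hyperparameters are chosen by grid search scored with five repeats of
stratified five-fold cross-validation (AUROC for dichotomous traits, RMSE
for quantitative), then the winner is refit on the full training set. A
singleton grid short-circuits to a direct fit, which is the default for the
augmented knockoff fit where selection stability, not held-out accuracy, is
what matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import (
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.model_selection import (
    GridSearchCV,
    RepeatedKFold,
    RepeatedStratifiedKFold,
    train_test_split,
)

from ._utils import as_frame, child_seed

__all__ = [
    "ALGORITHMS",
    "TuningSpec",
    "FittedModel",
    "default_grid",
    "make_estimator",
    "stratified_split",
    "tune_fit",
    "fit_single",
    "predict",
]

ALGORITHMS = ("lightgbm", "xgboost", "gbdt", "rf", "extra_trees")

_GRIDS: dict[str, dict[str, list]] = {
    "lightgbm": {
        "n_estimators": [100, 300, 500],
        "max_depth": [3, 6, 9],
        "learning_rate": [0.03, 0.1, 0.3],
    },
    "xgboost": {
        "n_estimators": [100, 300, 500],
        "max_depth": [3, 6, 9],
        "learning_rate": [0.03, 0.1, 0.3],
    },
    "gbdt": {
        "n_estimators": [100, 300, 500],
        "max_depth": [3, 6, 9],
        "learning_rate": [0.03, 0.1, 0.3],
    },
    "rf": {
        "n_estimators": [100, 300, 500],
        "max_depth": [3, 6, 9],
        "min_samples_split": [2, 10, 50],
    },
    "extra_trees": {
        "n_estimators": [100, 300, 500],
        "max_depth": [3, 6, 9],
        "min_samples_split": [2, 10, 50],
    },
}


def default_grid(algorithm: str) -> dict[str, list]:
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return {k: list(v) for k, v in _GRIDS[algorithm].items()}


@dataclass
class TuningSpec:
    algorithm: str
    grid: dict[str, list] = field(default_factory=dict)
    cv_folds: int = 5
    cv_repeats: int = 5
    seed: int = 0
    fixed_params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.grid:
            self.grid = default_grid(self.algorithm)
        allowed = set(default_grid(self.algorithm))
        extra = set(self.grid) - allowed
        if extra:
            raise ValueError(
                f"grid keys {sorted(extra)} are not tunable for {self.algorithm}"
            )

    def is_singleton(self) -> bool:
        return all(len(v) == 1 for v in self.grid.values())


@dataclass
class FittedModel:
    algorithm: str
    params: dict[str, Any]
    columns: list[str]
    estimator: Any
    trait: str

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


def make_estimator(algorithm: str, trait: str, seed: int = 0, **params):
    """Instantiate a registered learner, single-threaded and seeded."""
    if trait not in ("dichotomous", "quantitative"):
        raise ValueError(f"unknown trait {trait!r}")
    classify = trait == "dichotomous"
    if algorithm == "lightgbm":
        import lightgbm as lgb

        cls = lgb.LGBMClassifier if classify else lgb.LGBMRegressor
        return cls(random_state=seed, n_jobs=1, verbose=-1, **params)
    if algorithm == "xgboost":
        import xgboost as xgb

        cls = xgb.XGBClassifier if classify else xgb.XGBRegressor
        return cls(random_state=seed, n_jobs=1, tree_method="hist", **params)
    if algorithm == "gbdt":
        cls = GradientBoostingClassifier if classify else GradientBoostingRegressor
        return cls(random_state=seed, **params)
    if algorithm == "rf":
        cls = RandomForestClassifier if classify else RandomForestRegressor
        return cls(random_state=seed, n_jobs=1, **params)
    if algorithm == "extra_trees":
        cls = ExtraTreesClassifier if classify else ExtraTreesRegressor
        return cls(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def stratified_split(
    X,
    y: np.ndarray,
    train_fraction: float = 0.7,
    seed: int = 0,
    trait: str = "dichotomous",
) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of a train/test partition; case/control proportions are
    matched across splits for dichotomous traits, plain random otherwise."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    frame = as_frame(X)
    y = np.asarray(y)
    idx = np.arange(frame.shape[0])
    strata = y if trait == "dichotomous" else None
    if strata is not None and np.min(np.bincount(y.astype(int))) < 2:
        raise ValueError("each class needs at least two members to stratify")
    train, test = train_test_split(
        idx,
        train_size=train_fraction,
        random_state=child_seed(seed, 0),
        stratify=strata,
    )
    return np.sort(train), np.sort(test)


def fit_single(
    algorithm: str,
    X,
    y: np.ndarray,
    trait: str,
    seed: int = 0,
    **params,
) -> FittedModel:
    """Direct fit with explicit hyperparameters (no tuning)."""
    frame = as_frame(X)
    est = make_estimator(algorithm, trait, seed=seed, **params)
    est.fit(frame, np.asarray(y))
    return FittedModel(
        algorithm=algorithm,
        params=dict(params),
        columns=list(frame.columns),
        estimator=est,
        trait=trait,
    )


def tune_fit(spec: TuningSpec, X, y: np.ndarray, trait: str) -> FittedModel:
    """Grid search with cv_repeats x cv_folds cross-validation, then refit
    the best hyperparameters on the full training data."""
    frame = as_frame(X)
    y = np.asarray(y)
    if spec.is_singleton():
        params = {**{k: v[0] for k, v in spec.grid.items()}, **spec.fixed_params}
        return fit_single(spec.algorithm, frame, y, trait, seed=spec.seed, **params)
    if trait == "dichotomous":
        cv = RepeatedStratifiedKFold(
            n_splits=spec.cv_folds,
            n_repeats=spec.cv_repeats,
            random_state=child_seed(spec.seed, 1),
        )
        scoring = "roc_auc"
    else:
        cv = RepeatedKFold(
            n_splits=spec.cv_folds,
            n_repeats=spec.cv_repeats,
            random_state=child_seed(spec.seed, 1),
        )
        scoring = "neg_root_mean_squared_error"
    base = make_estimator(spec.algorithm, trait, seed=spec.seed, **spec.fixed_params)
    search = GridSearchCV(
        base, spec.grid, scoring=scoring, cv=cv, n_jobs=1, refit=True
    )
    search.fit(frame, y)
    return FittedModel(
        algorithm=spec.algorithm,
        params={**spec.fixed_params, **search.best_params_},
        columns=list(frame.columns),
        estimator=search.best_estimator_,
        trait=trait,
    )


def predict(model: FittedModel, X) -> np.ndarray:
    """Probabilities for dichotomous traits, real values otherwise."""
    frame = as_frame(X)
    if list(frame.columns) != model.columns:
        if set(frame.columns) >= set(model.columns):
            frame = frame[model.columns]
        else:
            raise ValueError("columns do not match the model's training columns")
    if model.trait == "dichotomous":
        return model.estimator.predict_proba(frame)[:, 1]
    return model.estimator.predict(frame)
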