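"""RBF-SVM and random-forest malignancy classifiers.

Both models are tuned by stratified 10-fold cross-validation on the
training rows only (decade-spaced hyperparameter grids) and emit per-case
malignancy probabilities: Platt-calibrated decision values for the SVM,
the fraction of trees voting malignant for the forest. The standardising
scaler is fitted on training rows only; validation and test rows never
influence the chosen hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "TrainedModel",
    "split_cohort",
    "train_svm",
    "train_rf",
    "predict_proba",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_N_ESTIMATORS_GRID",
]

#: Decade-spaced default grids bracketing the operating regime of a
#: few-hundred-case radiomics cohort.
DEFAULT_C_GRID: tuple[float, ...] = tuple(10.0**k for k in range(-2, 4))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(10.0**k for k in range(-4, 2))
DEFAULT_N_ESTIMATORS_GRID: tuple[int, ...] = (10, 100, 1000, 10000)


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reproduce it."""

    kind: str                       # "svm" | "rf"
    hyperparameters: dict
    feature_names: list[str]
    pipeline: Pipeline
    cv_score: float = float("nan")

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        return joblib.load(path)


def split_cohort(
    table: pd.DataFrame,
    test_fraction: float,
    val_fraction: float,
    seed: int,
    label_col: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stratified (train, validation, test) split.

    ``test_fraction`` is taken from the whole cohort first;
    ``val_fraction`` is then taken from the remaining train+validation
    pool (so 0.2 reproduces an 8:2 train:validation ratio). Either
    fraction may be 0 to skip that split. Splits are disjoint, exhaustive
    and reproducible under the seed.
    """
    for name, frac in (("test_fraction", test_fraction), ("val_fraction", val_fraction)):
        if not 0 <= frac < 1:
            raise ValueError(f"{name} must be in [0, 1), got {frac}")
    if test_fraction + val_fraction >= 1:
        raise ValueError("fractions must leave room for a training set")
    y = table[label_col]
    if test_fraction > 0:
        pool, test = train_test_split(
            table, test_size=test_fraction, stratify=y, random_state=seed
        )
    else:
        pool, test = table, table.iloc[0:0]
    if val_fraction > 0:
        train, val = train_test_split(
            pool, test_size=val_fraction, stratify=pool[label_col],
            random_state=seed,
        )
    else:
        train, val = pool, table.iloc[0:0]
    for part, name in ((train, "train"), (val, "validation"), (test, "test")):
        if len(part) and part[label_col].nunique() < 2:
            raise ValueError(f"{name} split contains a single class")
    return train, val, test


def _xy(table: pd.DataFrame, label_col: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    features = [c for c in table.columns if c != label_col]
    return (
        table[features].to_numpy(dtype=float),
        table[label_col].to_numpy(dtype=int),
        features,
    )


def _check_cv(y: np.ndarray, n_folds: int) -> None:
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < n_folds:
        raise ValueError(
            f"n_folds={n_folds} exceeds the smaller class count {counts.min()}"
        )


def train_svm(
    train: pd.DataFrame,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    n_folds: int = 10,
    seed: int = 0,
    scoring: str = "accuracy",
    refine: bool = False,
    label_col: str = "label",
) -> TrainedModel:
    """Grid-searched RBF-SVM with Platt-calibrated probabilities.

    The pipeline standardises (scaler fitted per CV training fold, then on
    the full training set for the final model) and fits an RBF SVM;
    (C, gamma) are chosen over the decade grids by mean CV ``scoring``
    (accuracy by default, ``"roc_auc"`` by configuration). With
    ``refine=True`` a second pass searches a finer multiplicative grid
    around the winning decade point.
    """
    if len(C_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("empty hyperparameter grid")
    x, y, features = _xy(train, label_col)
    _check_cv(y, n_folds)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    # sigmoid (Platt) calibration of the decision values via internal CV
    calibrated = CalibratedClassifierCV(
        SVC(kernel="rbf", random_state=seed), method="sigmoid", ensemble=False,
        cv=StratifiedKFold(n_splits=5, shuffle=True, random_state=seed),
    )
    pipe = Pipeline([("scale", StandardScaler()), ("svm", calibrated)])
    c_key, g_key = "svm__estimator__C", "svm__estimator__gamma"
    grid = {c_key: list(C_grid), g_key: list(gamma_grid)}
    search = GridSearchCV(pipe, grid, cv=cv, scoring=scoring, refit=True)
    search.fit(x, y)
    if refine:
        c0 = search.best_params_[c_key]
        g0 = search.best_params_[g_key]
        mult = (0.2, 0.33, 0.5, 1.0, 2.0, 3.0, 5.0)
        grid = {c_key: [c0 * m for m in mult], g_key: [g0 * m for m in mult]}
        search = GridSearchCV(pipe, grid, cv=cv, scoring=scoring, refit=True)
        search.fit(x, y)
    return TrainedModel(
        kind="svm",
        hyperparameters={"C": search.best_params_[c_key],
                         "gamma": search.best_params_[g_key]},
        feature_names=features,
        pipeline=search.best_estimator_,
        cv_score=float(search.best_score_),
    )


def train_rf(
    train: pd.DataFrame,
    n_estimators_grid: Sequence[int] = DEFAULT_N_ESTIMATORS_GRID,
    n_folds: int = 10,
    seed: int = 0,
    scoring: str = "accuracy",
    label_col: str = "label",
) -> TrainedModel:
    """Random forest with a CV-selected tree count.

    Probabilities are the fraction of trees voting malignant. A
    single-point grid skips the search.
    """
    if len(n_estimators_grid) == 0:
        raise ValueError("empty n_estimators grid")
    x, y, features = _xy(train, label_col)
    _check_cv(y, n_folds)
    if len(n_estimators_grid) == 1:
        best_n = int(n_estimators_grid[0])
        model = RandomForestClassifier(n_estimators=best_n, random_state=seed)
        model.fit(x, y)
        pipe = Pipeline([("rf", model)])
        return TrainedModel("rf", {"n_estimators": best_n}, features, pipe)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pipe = Pipeline([("rf", RandomForestClassifier(random_state=seed))])
    search = GridSearchCV(
        pipe, {"rf__n_estimators": [int(n) for n in n_estimators_grid]},
        cv=cv, scoring=scoring, refit=True,
    )
    search.fit(x, y)
    return TrainedModel(
        kind="rf",
        hyperparameters={"n_estimators": search.best_params_["rf__n_estimators"]},
        feature_names=features,
        pipeline=search.best_estimator_,
        cv_score=float(search.best_score_),
    )


def predict_proba(model: TrainedModel, table: pd.DataFrame,
                  label_col: str = "label") -> np.ndarray:
    """Per-row P(malignant) under a trained model.

    The table's feature columns must match the training schema exactly
    (order-insensitive); the error names any missing or extra features.
    """
    features = [c for c in table.columns if c != label_col]
    missing = sorted(set(model.feature_names) - set(features))
    extra = sorted(set(features) - set(model.feature_names))
    if missing or extra:
        raise ValueError(
            f"feature schema mismatch: missing={missing}, extra={extra}"
        )
    x = table[model.feature_names].to_numpy(dtype=float)
    return model.pipeline.predict_proba(x)[:, 1]
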