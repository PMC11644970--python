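"""Faller / non-faller classification under three feature conditions.

Models: random forest, SVM and k-NN with fixed hyperparameter grids;
selection by grid search scored with macro-F1 under leave-one-out
cross-validation on the 70% training split; reporting (per-class precision/
recall/F1, accuracy, LOOCV per-fold accuracy SD, ROC/AUC) on the untouched
30% test split. Imputation (median) and standardization are fit on training
data only, inside the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.metrics import accuracy_score, precision_recall_fscore_support, roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, LeaveOneOut, cross_val_predict, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .gaitmetrics import GAIT_FEATURE_COLUMNS
from .lifespace import GPS_FEATURE_COLUMNS

__all__ = [
    "MODELS",
    "CONDITIONS",
    "FeatureCondition",
    "ModelReport",
    "build_grid",
    "build_estimator",
    "condition_columns",
    "fit_evaluate",
    "run_conditions",
]

MODELS = ("rf", "svm", "knn")
CONDITIONS = ("gps", "accel", "combined")

POSITIVE_LABEL = "faller"
NEGATIVE_LABEL = "non_faller"


@dataclass
class FeatureCondition:
    name: str
    columns: list[str]


def condition_columns(name: str, available: list[str] | None = None) -> list[str]:
    if name == "gps":
        cols = list(GPS_FEATURE_COLUMNS)
    elif name == "accel":
        cols = list(GAIT_FEATURE_COLUMNS)
    elif name == "combined":
        cols = list(GPS_FEATURE_COLUMNS) + list(GAIT_FEATURE_COLUMNS)
    else:
        raise ValueError(f"unknown condition {name!r}")
    if available is not None:
        missing = [c for c in cols if c not in available]
        if missing:
            raise ValueError(f"condition {name!r}: columns absent from table: {missing}")
    return cols


@dataclass
class ModelReport:
    model: str
    condition: str
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    loocv_accuracy_sd: float
    auc: float
    best_params: dict = field(default_factory=dict)
    roc_points: tuple[np.ndarray, np.ndarray] | None = None

    def to_row(self) -> dict:
        return {
            "model": self.model,
            "condition": self.condition,
            "precision_non_faller": self.precision[NEGATIVE_LABEL],
            "precision_faller": self.precision[POSITIVE_LABEL],
            "recall_non_faller": self.recall[NEGATIVE_LABEL],
            "recall_faller": self.recall[POSITIVE_LABEL],
            "f1_non_faller": self.f1[NEGATIVE_LABEL],
            "f1_faller": self.f1[POSITIVE_LABEL],
            "accuracy": self.accuracy,
            "loocv_accuracy_sd": self.loocv_accuracy_sd,
            "auc": self.auc,
        }


def build_grid(model: str) -> dict:
    """The fixed hyperparameter grids (48 RF, 40 k-NN, 27 SVM combinations)."""
    if model == "rf":
        return {
            "clf__n_estimators": [100, 200, 300],
            "clf__max_depth": [2, 3],
            "clf__min_samples_split": [2, 5],
            "clf__min_samples_leaf": [3, 4],
            "clf__max_features": ["sqrt", "log2"],
        }
    if model == "knn":
        return {
            "clf__n_neighbors": list(range(1, 11)),
            "clf__weights": ["uniform", "distance"],
            "clf__metric": ["euclidean", "manhattan"],
        }
    if model == "svm":
        return {
            "clf__C": [0.1, 1, 10],
            "clf__gamma": [1, 0.1, 0.01],
            "clf__kernel": ["rbf", "poly", "sigmoid"],
        }
    raise ValueError(f"unknown model {model!r}")


def build_estimator(model: str, random_state: int = 0) -> Pipeline:
    if model == "rf":
        clf = RandomForestClassifier(random_state=random_state)
    elif model == "svm":
        clf = SVC(random_state=random_state)
    elif model == "knn":
        clf = KNeighborsClassifier()
    else:
        raise ValueError(f"unknown model {model!r}")
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", clf),
        ]
    )


def _scores(est: Pipeline, X: pd.DataFrame) -> np.ndarray:
    """Monotone score for the positive (faller) class."""
    clf = est.named_steps["clf"]
    if hasattr(clf, "decision_function"):
        s = est.decision_function(X)
        # decision_function orients toward classes_[1]
        return s if est.classes_[1] == POSITIVE_LABEL else -s
    proba = est.predict_proba(X)
    return proba[:, list(est.classes_).index(POSITIVE_LABEL)]


def fit_evaluate(
    cohort: pd.DataFrame,
    condition: str,
    model: str,
    split_seed: int = 0,
    search: bool = True,
    loocv_sd: bool = True,
    group_col: str = "group",
) -> ModelReport:
    """Train on a stratified 70% split, report on the held-out 30%.

    ``search=False`` skips the grid search and uses the base estimator
    defaults — used for fast large-scale simulation sweeps; the reporting
    path is identical.
    """
    cols = condition_columns(condition, list(cohort.columns))
    X = cohort[cols]
    y = cohort[group_col]
    if min((y == POSITIVE_LABEL).sum(), (y == NEGATIVE_LABEL).sum()) < 4:
        raise ValueError("need at least 4 subjects per class")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.3, stratify=y, random_state=split_seed
    )
    if set(y_tr) != set(y) or set(y_te) != set(y):
        raise ValueError("a class is absent from one split")

    base = build_estimator(model, random_state=split_seed)
    if search:
        gs = GridSearchCV(
            base, build_grid(model), scoring="f1_macro", cv=LeaveOneOut(), n_jobs=None
        )
        gs.fit(X_tr, y_tr)
        best = gs.best_estimator_
        best_params = {k.removeprefix("clf__"): v for k, v in gs.best_params_.items()}
    else:
        base.fit(X_tr, y_tr)
        best = base
        best_params = {}

    if loocv_sd:
        pred_loo = cross_val_predict(best, X_tr, y_tr, cv=LeaveOneOut())
        fold_acc = (pred_loo == y_tr.to_numpy()).astype(float)  # per-fold 0/1 accuracy
        sd = float(np.std(fold_acc))
    else:
        sd = float("nan")

    y_pred = best.predict(X_te)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_te, y_pred, labels=[NEGATIVE_LABEL, POSITIVE_LABEL], zero_division=0
    )
    scores = _scores(best, X_te)
    auc = float(roc_auc_score((y_te == POSITIVE_LABEL).astype(int), scores))
    fpr, tpr, _ = roc_curve((y_te == POSITIVE_LABEL).astype(int), scores)

    return ModelReport(
        model=model,
        condition=condition,
        precision={NEGATIVE_LABEL: float(prec[0]), POSITIVE_LABEL: float(prec[1])},
        recall={NEGATIVE_LABEL: float(rec[0]), POSITIVE_LABEL: float(rec[1])},
        f1={NEGATIVE_LABEL: float(f1[0]), POSITIVE_LABEL: float(f1[1])},
        accuracy=float(accuracy_score(y_te, y_pred)),
        loocv_accuracy_sd=sd,
        auc=auc,
        best_params=best_params,
        roc_points=(fpr, tpr),
    )


def run_conditions(
    cohort: pd.DataFrame, seed: int = 0, search: bool = True, loocv_sd: bool = True
) -> list[ModelReport]:
    """All 3 models × 3 feature conditions; deterministic given ``seed``."""
    return [
        fit_evaluate(cohort, condition, model, split_seed=seed, search=search, loocv_sd=loocv_sd)
        for condition in CONDITIONS
        for model in MODELS
    ]


def reports_to_frame(reports: list[ModelReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])
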