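"""Binary patient-risk classifiers: training, evaluation, benchmarking.

Six classifier families are benchmarked for the normal/abnormal patient-risk
task: random forest, logistic regression, decision tree, k-nearest
neighbours, a linear support-vector machine and XGBoost. Each comes with a
fixed hyperparameter registry (the study configuration); the estimators
themselves are scikit-learn / xgboost implementations — this module owns the
splitting, the confusion-matrix metric suite, K-fold validation and the
benchmark harness, not the classifier internals.

Features are used unnormalised: the deployed model scores manually entered
vital signs directly, so any scaling would have to be replicated at entry
time and is deliberately omitted.

Evaluation treats *abnormal* as the positive class (the alerting goal is to
find positives). Metrics derive from the confusion matrix::

    accuracy  = (TP + TN) / N        precision = TP / (TP + FP)
    recall    = TP / (TP + FN)       F1        = 2 P R / (P + R)

MAE and RMSE are computed on hard 0/1 predictions, so MAE = 1 - accuracy and
RMSE = sqrt(MAE) hold identically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

#: Independent variables of the risk model, in canonical column order.
FEATURE_COLUMNS: tuple[str, ...] = (
    "age",
    "bmi",
    "heart_rate",
    "systolic_bp",
    "resp_rate",
    "temperature",
    "spo2",
    "blood_sugar",
)

#: Binary label column: 0 = normal, 1 = abnormal (the positive class).
LABEL_COLUMN = "label"

# Study hyperparameter configuration per model. `pruning_confidence` for the
# decision tree is a C4.5-style confidence factor carried for configuration
# fidelity; scikit-learn has no equivalent control, so the effective pruning
# knobs are min_samples_leaf and (optionally) ccp_alpha.
CLASSIFIER_DEFAULTS: dict[str, dict] = {
    "random_forest": {"max_depth": 3, "n_estimators": 100},
    "logistic_regression": {"C": 1.0, "max_iter": 100, "class_weight": None},
    "decision_tree": {
        "pruning_confidence": 0.25,
        "min_samples_leaf": 2,
        "ccp_alpha": 0.0,
    },
    "knn": {"n_neighbors": 5, "weights": "uniform"},
    "svm": {"C": 1.0, "kernel": "linear", "max_iter": 100},
    "xgboost": {"max_depth": 3, "learning_rate": 0.1, "n_estimators": 100},
}

CLASSIFIER_NAMES: tuple[str, ...] = tuple(CLASSIFIER_DEFAULTS)


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus hyperparameter overrides.

    Overrides are validated against the registry: a hyperparameter name not
    listed for the model is rejected rather than silently ignored.
    """

    name: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_DEFAULTS:
            raise ValueError(
                f"unknown classifier {self.name!r}; expected one of "
                f"{sorted(CLASSIFIER_DEFAULTS)}"
            )
        allowed = CLASSIFIER_DEFAULTS[self.name].keys()
        unknown = set(self.hyperparameters) - set(allowed)
        if unknown:
            raise ValueError(
                f"unknown hyperparameter(s) for {self.name}: {sorted(unknown)}"
            )

    def resolved(self) -> dict:
        """Registry defaults overlaid with this spec's overrides."""
        hp = dict(CLASSIFIER_DEFAULTS[self.name])
        hp.update(self.hyperparameters)
        return hp


def build_estimator(spec: ClassifierSpec, seed: int = 0):
    """Instantiate the configured scikit-learn / xgboost estimator."""
    hp = spec.resolved()
    if spec.name == "random_forest":
        return RandomForestClassifier(
            max_depth=hp["max_depth"],
            n_estimators=hp["n_estimators"],
            random_state=seed,
            n_jobs=1,
        )
    if spec.name == "logistic_regression":
        return LogisticRegression(
            C=hp["C"], max_iter=hp["max_iter"], class_weight=hp["class_weight"]
        )
    if spec.name == "decision_tree":
        return DecisionTreeClassifier(
            min_samples_leaf=hp["min_samples_leaf"],
            ccp_alpha=hp["ccp_alpha"],
            random_state=seed,
        )
    if spec.name == "knn":
        return KNeighborsClassifier(
            n_neighbors=hp["n_neighbors"], weights=hp["weights"]
        )
    if spec.name == "svm":
        return SVC(C=hp["C"], kernel=hp["kernel"], max_iter=hp["max_iter"])
    return XGBClassifier(
        max_depth=hp["max_depth"],
        learning_rate=hp["learning_rate"],
        n_estimators=hp["n_estimators"],
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a binary evaluation, positive class = abnormal."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionMatrix":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape or yt.ndim != 1 or yt.size == 0:
            raise ValueError("y_true and y_pred must be equal-length 1-D, non-empty")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
        )


@dataclass(frozen=True)
class EvalMetrics:
    """Derived metrics of a hard-prediction binary evaluation."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    mae: float
    rmse: float

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "EvalMetrics":
        n = cm.n
        if n == 0:
            raise ValueError("empty confusion matrix")
        accuracy = (cm.tp + cm.tn) / n
        precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else 0.0
        recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        mae = (cm.fp + cm.fn) / n  # hard 0/1 predictions
        return cls(
            accuracy=accuracy,
            precision=precision,
            recall=recall,
            f1=f1,
            mae=mae,
            rmse=math.sqrt(mae),
        )


@dataclass(frozen=True)
class FittedModel:
    """A trained classifier plus the feature schema it was fitted on."""

    spec: ClassifierSpec
    estimator: object
    feature_columns: tuple[str, ...]

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_columns if c not in features.columns]
        if missing:
            raise ValueError(
                f"features outside training schema; missing column(s): {missing}"
            )
        X = features[list(self.feature_columns)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("features contain missing values; impute upstream")
        return np.asarray(self.estimator.predict(X), dtype=int)


def split_dataset(
    records: pd.DataFrame, train_fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shuffle and partition records into disjoint train/test sets.

    The training size is ``train_fraction * N`` rounded half away from zero,
    so a 1,177-record cohort at 70% yields 824 training and 353 test records.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction out of (0, 1): {train_fraction}")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(math.floor(train_fraction * n + 0.5))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"degenerate split: {n_train}/{n - n_train} from n={n}, "
            f"fraction={train_fraction}"
        )
    perm = np.random.default_rng(seed).permutation(n)
    train = records.iloc[perm[:n_train]].reset_index(drop=True)
    test = records.iloc[perm[n_train:]].reset_index(drop=True)
    return train, test


def _feature_columns_of(records: pd.DataFrame) -> tuple[str, ...]:
    if LABEL_COLUMN not in records.columns:
        raise ValueError(f"records lack a {LABEL_COLUMN!r} column")
    return tuple(c for c in records.columns if c != LABEL_COLUMN)


def train_classifier(
    spec: ClassifierSpec, train: pd.DataFrame, seed: int = 0
) -> FittedModel:
    """Fit the configured classifier on a labelled feature table.

    Deterministic given the seed. The training table must contain both
    classes and no missing values (imputation happens upstream).
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    cols = _feature_columns_of(train)
    y = train[LABEL_COLUMN].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    X = train[list(cols)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("training features contain missing values")
    estimator = build_estimator(spec, seed)
    with warnings.catch_warnings():
        # capped max_iter is part of the study configuration for LR/SVM
        warnings.simplefilter("ignore", ConvergenceWarning)
        estimator.fit(X, y)
    return FittedModel(spec=spec, estimator=estimator, feature_columns=cols)


def evaluate(
    model: FittedModel, test: pd.DataFrame
) -> tuple[ConfusionMatrix, EvalMetrics]:
    """Confusion matrix and metric suite of a model on a labelled test table."""
    if len(test) == 0:
        raise ValueError("empty test set")
    if LABEL_COLUMN not in test.columns:
        raise ValueError(f"test set lacks a {LABEL_COLUMN!r} column")
    y_true = test[LABEL_COLUMN].to_numpy(dtype=int)
    y_pred = model.predict(test)
    cm = ConfusionMatrix.from_labels(y_true, y_pred)
    return cm, EvalMetrics.from_confusion(cm)


@dataclass(frozen=True)
class CVResult:
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float


def kfold_cv(
    spec: ClassifierSpec, records: pd.DataFrame, k: int = 10, seed: int = 0
) -> CVResult:
    """K-fold cross-validated accuracy (shuffled folds, sizes differ by ≤1).

    The mean is the unweighted average of the per-fold accuracies.
    """
    n = len(records)
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of records ({n})")
    folds: list[float] = []
    for train_idx, test_idx in KFold(n_splits=k, shuffle=True, random_state=seed).split(
        records
    ):
        model = train_classifier(spec, records.iloc[train_idx], seed=seed)
        _, metrics = evaluate(model, records.iloc[test_idx])
        folds.append(metrics.accuracy)
    return CVResult(
        fold_accuracies=tuple(folds), mean_accuracy=float(np.mean(folds))
    )


@dataclass(frozen=True)
class BenchmarkResult:
    """Comparison table over all classifier specs plus the selected winner."""

    table: pd.DataFrame
    winner: Optional[str]


def select_winner(table: pd.DataFrame) -> Optional[str]:
    """Selection rule: highest accuracy, then highest recall, then lowest
    MAE, then lowest RMSE."""
    ok = table[table["error"].isna()]
    if ok.empty:
        return None
    ranked = ok.sort_values(
        by=["accuracy", "recall", "mae", "rmse"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    return str(ranked.iloc[0]["model"])


def benchmark_suite(
    records: pd.DataFrame,
    seed: int = 0,
    specs: Optional[Iterable[ClassifierSpec]] = None,
    train_fraction: float = 0.7,
    k: int = 10,
) -> BenchmarkResult:
    """Train and compare all classifiers on one labelled table.

    Each model is trained on a shared 70/30 split, evaluated on the held-out
    30%, and additionally 10-fold cross-validated on the full table. A model
    whose training fails is flagged in the ``error`` column; the others
    continue. Rows are sorted by hold-out accuracy, descending.
    """
    if specs is None:
        specs = [ClassifierSpec(name) for name in CLASSIFIER_NAMES]
    train, test = split_dataset(records, train_fraction, seed)
    rows = []
    for spec in specs:
        row: dict = {"model": spec.name, "error": None}
        try:
            model = train_classifier(spec, train, seed=seed)
            _, metrics = evaluate(model, test)
            cv = kfold_cv(spec, records, k=k, seed=seed)
            row.update(
                accuracy=metrics.accuracy,
                precision=metrics.precision,
                recall=metrics.recall,
                f1=metrics.f1,
                mae=metrics.mae,
                rmse=metrics.rmse,
                cv_mean_accuracy=cv.mean_accuracy,
            )
        except Exception as exc:  # flag and continue with the other models
            row.update(
                accuracy=np.nan,
                precision=np.nan,
                recall=np.nan,
                f1=np.nan,
                mae=np.nan,
                rmse=np.nan,
                cv_mean_accuracy=np.nan,
                error=str(exc),
            )
        rows.append(row)
    table = pd.DataFrame(rows)[
        [
            "model",
            "accuracy",
            "precision",
            "recall",
            "f1",
            "mae",
            "rmse",
            "cv_mean_accuracy",
            "error",
        ]
    ]
    table = table.sort_values(
        by="accuracy", ascending=False, na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return BenchmarkResult(table=table, winner=select_winner(table))


def plot_benchmark(table: pd.DataFrame, path: str) -> None:
    """Grouped bar chart comparing the benchmarked classifiers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = ["accuracy", "precision", "recall", "f1", "cv_mean_accuracy"]
    ok = table[table["error"].isna()]
    x = np.arange(len(ok))
    width = 0.8 / len(metrics)
    fig, ax = plt.subplots(figsize=(9, 4.5))
    for i, m in enumerate(metrics):
        ax.bar(x + i * width, ok[m], width, label=m)
    ax.set_xticks(x + width * (len(metrics) - 1) / 2)
    ax.set_xticklabels(ok["model"], rotation=20, ha="right")
    ax.set_ylabel("score")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
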