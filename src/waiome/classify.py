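"""Classifier zoo, cross-validation harness, and metric battery.

Five model families are benchmarked for normal-vs-OME diagnosis from the
vectorized frequency-pressure images: K-nearest neighbours (K in {1,3,15},
uniform weights, Euclidean), support vector machines (linear / degree-3
polynomial / RBF / sigmoid kernels), random forests (10/100/500 trees),
and two feedforward plus two convolutional neural networks. Evaluation is
stratified 10-fold cross-validation with the standardizer fit on training
folds only; families with randomized fitting (rf, fnn, cnn) are rerun with
three random initializations and metrics averaged over folds then restarts.

Class imbalance (the emulated cohort has 1.7 normal ears per OME ear) is
handled by cost-sensitive learning: OME misclassification errors are
weighted ``ome_weight`` times in the training loss (per-sample weights for
the neural models, ``class_weight`` for svm/rf).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .nn import NeuralNet, TrainConfig, count_parameters  # noqa: F401  (re-export)
from .preprocess import apply_scaler, fit_scaler, vectorize_cohort
from .surface import Cohort

FAMILIES = ("knn", "svm", "rf", "fnn", "cnn")
RANDOMIZED_FAMILIES = ("rf", "fnn", "cnn")
DEFAULT_RESTARTS = 3


@dataclass(frozen=True)
class ModelSpec:
    """One benchmark entry: a family plus its design parameter.

    family/design pairs: knn with n_neighbors (1, 3, 15); svm with kernel
    (linear, poly [degree 3], rbf, sigmoid); rf with n_trees (10, 100,
    500); fnn/cnn with an architecture id (FNN1, FNN2, CNN1, CNN2).
    ``ome_weight`` scales the loss of OME (minority) misclassifications.
    """

    family: str
    design: str | int
    ome_weight: float = 1.0
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.ome_weight <= 0:
            raise ValueError("ome_weight must be positive")

    @property
    def name(self) -> str:
        return f"{self.family}-{self.design}"


def benchmark_zoo(ome_weight: float = 1.0, train: TrainConfig | None = None) -> list[ModelSpec]:
    """The full fixed benchmark table (14 models)."""
    train = train or TrainConfig()
    specs = [ModelSpec("knn", k, ome_weight, train) for k in (1, 3, 15)]
    specs += [ModelSpec("svm", kern, ome_weight, train) for kern in ("linear", "poly", "rbf", "sigmoid")]
    specs += [ModelSpec("rf", t, ome_weight, train) for t in (10, 100, 500)]
    specs += [ModelSpec("fnn", a, ome_weight, train) for a in ("FNN1", "FNN2")]
    specs += [ModelSpec("cnn", a, ome_weight, train) for a in ("CNN1", "CNN2")]
    return specs


def recommended_weight(n_majority: int, n_minority: int) -> float:
    """Cost weight countering class imbalance, rounded to one decimal.

    The emulated cohort's 423/249 split gives 1.7.
    """
    if n_minority <= 0:
        raise ValueError("minority count must be positive")
    return round(n_majority / n_minority, 1)


def weighted_loss(ome_weight: float, y: np.ndarray) -> np.ndarray:
    """Per-sample loss weights: ``ome_weight`` for OME (label 1), 1 otherwise."""
    if ome_weight <= 0:
        raise ValueError("ome_weight must be positive")
    y = np.asarray(y)
    return np.where(y == 1, float(ome_weight), 1.0)


def build_model(spec: ModelSpec, seed: int = 0):
    """Instantiate an untrained model handle for a spec."""
    class_weight = None if spec.ome_weight == 1.0 else {0: 1.0, 1: float(spec.ome_weight)}
    if spec.family == "knn":
        # KNN has no training loss; cost weighting does not apply
        return KNeighborsClassifier(n_neighbors=int(spec.design), weights="uniform", metric="euclidean")
    if spec.family == "svm":
        return SVC(kernel=str(spec.design), degree=3, class_weight=class_weight, random_state=seed)
    if spec.family == "rf":
        return RandomForestClassifier(
            n_estimators=int(spec.design), max_features="sqrt",
            class_weight=class_weight, random_state=seed, n_jobs=1,
        )
    return NeuralNet(str(spec.design), seed=seed)


def _fit_and_score(spec: ModelSpec, model, X_train, y_train, X_test) -> np.ndarray:
    """Fit one model and return continuous scores for the test set."""
    if spec.family in ("fnn", "cnn"):
        model.fit(X_train, y_train, sample_weight=weighted_loss(spec.ome_weight, y_train),
                  config=spec.train)
        return model.predict_proba(X_test)
    model.fit(X_train, y_train)
    if spec.family == "svm":
        return model.decision_function(X_test)  # signed margin
    # knn: neighbour vote fraction; rf: class-probability
    return model.predict_proba(X_test)[:, 1]


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    auc_roc: float
    precision_normal: float
    precision_ome: float
    recall_normal: float
    recall_ome: float
    f1_normal: float
    f1_ome: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def auc_from_scores(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """AUROC as the pair-counting probability (ties counted 1/2)."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUROC undefined for single-class y_true")
    return float(roc_auc_score(y_true, y_score))


def compute_metrics(y_true: np.ndarray, y_score: np.ndarray, threshold: float = 0.5) -> Metrics:
    """Accuracy, AUROC and per-class precision/recall/F1 at a threshold.

    Scores are probabilities of OME unless they are real-valued margins, in
    which case the decision threshold is 0.
    """
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    if np.min(y_score) < 0 or np.max(y_score) > 1:
        y_pred = (y_score > 0).astype(int)  # signed decision margins
    else:
        y_pred = (y_score >= threshold).astype(int)
    auc = auc_from_scores(y_true, y_score)
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], zero_division=0
    )
    return Metrics(
        accuracy=float(np.mean(y_pred == y_true)),
        auc_roc=auc,
        precision_normal=float(precision[0]),
        precision_ome=float(precision[1]),
        recall_normal=float(recall[0]),
        recall_ome=float(recall[1]),
        f1_normal=float(f1[0]),
        f1_ome=float(f1[1]),
    )


@dataclass(frozen=True)
class CVResult:
    """Cross-validation outcome for one model spec."""

    spec: ModelSpec
    metrics: Metrics  # averaged over folds, then over restarts
    fold_metrics: tuple[tuple[Metrics, ...], ...]  # [restart][fold]
    oof_scores: np.ndarray  # out-of-fold scores aligned to cohort order, averaged over restarts
    fold_assignment: np.ndarray  # fold index per ear


def _average(metrics: list[Metrics]) -> Metrics:
    return Metrics(**{
        k: float(np.mean([m.as_dict()[k] for m in metrics])) for k in metrics[0].as_dict()
    })


def cross_validate(
    cohort: Cohort,
    spec: ModelSpec,
    folds: int = 10,
    restarts: int | None = None,
    seed: int = 0,
    group_by_participant: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation of one model spec.

    The standardizer is fit on each training fold only (no leakage into the
    test fold). ``restarts`` defaults to 3 for the randomized families (rf,
    fnn, cnn) and 1 for knn/svm. ``group_by_participant=True`` keeps both
    ears of one participant in the same fold. Deterministic given
    (cohort, spec, folds, seed).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = vectorize_cohort(cohort)
    y = cohort.labels
    if len(np.unique(y)) < 2:
        raise ValueError("cross_validate needs both classes present")
    if restarts is None:
        restarts = DEFAULT_RESTARTS if spec.family in RANDOMIZED_FAMILIES else 1

    if group_by_participant:
        groups = np.array([s.meta.participant_id for s in cohort])
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = list(splitter.split(X, y, groups))
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = list(splitter.split(X, y))

    fold_assignment = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(split):
        fold_assignment[test_idx] = f
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[np.setdiff1d(np.arange(len(y)), test_idx)])) < 2:
            raise ValueError(
                f"fold {f} contains a single class; reduce the number of folds "
                f"for this cohort size"
            )

    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(2**31 - 1, size=restarts)
    all_fold_metrics: list[tuple[Metrics, ...]] = []
    oof = np.zeros(len(y), dtype=float)
    for r_seed in restart_seeds:
        per_fold: list[Metrics] = []
        for train_idx, test_idx in split:
            scaler = fit_scaler(X[train_idx])
            X_train = apply_scaler(X[train_idx], scaler)
            X_test = apply_scaler(X[test_idx], scaler)
            model = build_model(spec, seed=int(r_seed))
            scores = _fit_and_score(spec, model, X_train, y[train_idx], X_test)
            per_fold.append(compute_metrics(y[test_idx], scores))
            oof[test_idx] += scores / restarts
        all_fold_metrics.append(tuple(per_fold))
    restart_means = [_average(list(f)) for f in all_fold_metrics]
    return CVResult(
        spec=spec,
        metrics=_average(restart_means),
        fold_metrics=tuple(all_fold_metrics),
        oof_scores=oof,
        fold_assignment=fold_assignment,
    )


def metrics_table(results: list[CVResult]) -> "pandas.DataFrame":  # noqa: F821
    """Benchmark-table view: one row per model, metric columns in [0, 1]."""
    import pandas as pd

    rows = []
    for res in results:
        row = {"family": res.spec.family, "design": str(res.spec.design)}
        row.update(res.metrics.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
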