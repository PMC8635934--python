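"""SVM classification of gait features and the two evaluation protocols.

A support-vector machine with an RBF kernel separates the 13 locomotion
states in the 72-dimensional coefficient space.  Features are z-score
standardised with statistics fitted on the training partition only, and the
kernel hyper-parameters are chosen by a small inner cross-validated grid —
both inside the per-fold training pipeline, so no information from any test
partition ever reaches the model.

Two protocols mirror how such recognisers are evaluated:

* user-dependent: all subjects' windows pooled, stratified 10-fold
  cross-validation (with a repeated 90/10 hold-out variant for small
  single-subject datasets);
* user-independent: leave-one-subject-out — every fold trains on the other
  subjects and tests on all windows of the held-out subject, measuring
  generalisation to an unseen person.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import (GridSearchCV, LeaveOneGroupOut,
                                     StratifiedKFold, StratifiedShuffleSplit)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureVector
from .segmentation import ALL_LABELS, STEADY_LABELS, TRANSITIONAL_LABELS

__all__ = [
    "ClassifierConfig",
    "EvaluationReport",
    "train_classifier",
    "evaluate_user_dependent",
    "evaluate_user_independent",
    "confusion_matrix",
    "stack_features",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """RBF-SVM settings: the C grid, kernel-width factors and inner CV."""

    c_grid: tuple = (1.0, 10.0, 100.0)
    gamma_factors: tuple = (0.5, 1.0, 2.0)
    inner_folds: int = 3
    seed: int = 0


def stack_features(dataset: list[FeatureVector]):
    """Stack feature vectors into (X, y, groups) arrays."""
    if not dataset:
        raise ValueError("empty feature dataset")
    X = np.vstack([fv.values for fv in dataset])
    y = np.array([fv.label for fv in dataset])
    groups = np.array([fv.subject_id for fv in dataset])
    return X, y, groups


def _make_model(config: ClassifierConfig, n_features: int):
    # data are standardised first, so the scale heuristic reduces to 1/d
    gammas = [f / n_features for f in config.gamma_factors]
    pipe = Pipeline([("scale", StandardScaler()),
                     ("svm", SVC(kernel="rbf", random_state=config.seed))])
    inner = StratifiedKFold(n_splits=config.inner_folds, shuffle=True,
                            random_state=config.seed)
    return GridSearchCV(pipe, {"svm__C": list(config.c_grid),
                               "svm__gamma": gammas},
                        cv=inner, n_jobs=None)


def train_classifier(features: list[FeatureVector],
                     config: ClassifierConfig | None = None):
    """Fit the standardise + grid-searched RBF-SVM pipeline; deterministic."""
    config = config or ClassifierConfig()
    X, y, _ = stack_features(features)
    if not np.isfinite(X).all():
        raise ValueError("features contain NaN or infinite values")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training requires at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 training samples")
    model = _make_model(config, X.shape[1])
    model.fit(X, y)
    return model


def confusion_matrix(true_labels, predicted_labels,
                     labels: tuple | None = None) -> np.ndarray:
    """K x K count matrix, entry (i, j) = true class i predicted as class j.

    Class order is the fixed vocabulary order (steady states first, then
    transitional), restricted to ``labels`` when given.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    vocab = tuple(labels) if labels is not None else ALL_LABELS
    unknown = set(true_labels) | set(predicted_labels)
    unknown -= set(vocab)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}; "
                         f"expected labels from {vocab}")
    return _sk_confusion(true_labels, predicted_labels, labels=list(vocab))


@dataclass
class EvaluationReport:
    """Confusion matrix and fold-wise accuracy summary for one protocol run.

    ``mean_accuracy`` is the pooled accuracy trace(confusion)/total, which
    coincides with the fold-weighted mean; ``std_accuracy`` is the standard
    deviation of the per-fold accuracies.
    """

    protocol: str
    state_set: str
    labels: tuple
    per_fold_accuracy: list
    confusion: np.ndarray
    fold_test_counts: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return int(self.confusion.sum())

    @property
    def mean_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.total)

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.per_fold_accuracy))

    def validate(self) -> None:
        if self.confusion.shape != (len(self.labels), len(self.labels)):
            raise ValueError("confusion matrix shape does not match labels")
        if self.fold_test_counts and self.total != sum(self.fold_test_counts):
            raise ValueError("confusion total does not match fold test counts")
        pooled = np.trace(self.confusion) / self.total
        weighted = (np.array(self.per_fold_accuracy)
                    * np.array(self.fold_test_counts)).sum() / self.total
        if abs(pooled - weighted) > 1e-12:
            raise ValueError("per-fold accuracies inconsistent with the "
                             "pooled confusion matrix")

    def summary(self) -> dict:
        return {"protocol": self.protocol, "state_set": self.state_set,
                "mean_accuracy": self.mean_accuracy,
                "std_accuracy": self.std_accuracy,
                "per_fold_accuracy": list(map(float, self.per_fold_accuracy)),
                "n_windows": self.total}


def _state_labels(state_set: str) -> tuple:
    try:
        return {"steady": STEADY_LABELS,
                "transitional": TRANSITIONAL_LABELS,
                "all": ALL_LABELS}[state_set]
    except KeyError:
        raise ValueError(f"unknown state set {state_set!r}") from None


def _filter_state_set(dataset, state_set):
    labels = _state_labels(state_set)
    subset = [fv for fv in dataset if fv.label in labels]
    if not subset:
        raise ValueError(f"no windows with labels in state set {state_set!r}")
    present = tuple(l for l in labels if any(fv.label == l for fv in subset))
    return subset, present


def _run_folds(X, y, splits, labels, config):
    per_fold, counts = [], []
    pooled = np.zeros((len(labels), len(labels)), dtype=int)
    for train_idx, test_idx in splits:
        model = _make_model(config, X.shape[1])
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        cm = confusion_matrix(y[test_idx], pred, labels)
        pooled += cm
        per_fold.append(float(np.trace(cm) / cm.sum()))
        counts.append(int(cm.sum()))
    return per_fold, counts, pooled


def evaluate_user_dependent(dataset: list[FeatureVector], folds: int = 10,
                            seed: int = 0, state_set: str = "all",
                            config: ClassifierConfig | None = None,
                            repeated_holdout: bool = False) -> EvaluationReport:
    """Pooled stratified k-fold cross-validation over all subjects' windows.

    ``repeated_holdout=True`` runs ``folds`` independent stratified 90/10
    splits instead (the protocol used for a single subject with few
    windows).
    """
    config = config or ClassifierConfig(seed=seed)
    subset, labels = _filter_state_set(dataset, state_set)
    X, y, _ = stack_features(subset)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > len(subset):
        raise ValueError(f"folds={folds} exceeds the {len(subset)} windows")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds and not repeated_holdout:
        import warnings
        warnings.warn("some classes have fewer samples than folds; "
                      "stratification will degrade", stacklevel=2)
    if repeated_holdout:
        splitter = StratifiedShuffleSplit(n_splits=folds, test_size=0.1,
                                          random_state=seed)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=seed)
    per_fold, fold_counts, pooled = _run_folds(
        X, y, splitter.split(X, y), labels, config)
    report = EvaluationReport(protocol="user_dependent", state_set=state_set,
                              labels=labels, per_fold_accuracy=per_fold,
                              confusion=pooled, fold_test_counts=fold_counts)
    report.validate()
    return report


def evaluate_user_independent(dataset: list[FeatureVector], seed: int = 0,
                              state_set: str = "all",
                              config: ClassifierConfig | None = None
                              ) -> EvaluationReport:
    """Leave-one-subject-out rotation over every subject in the dataset."""
    config = config or ClassifierConfig(seed=seed)
    subset, labels = _filter_state_set(dataset, state_set)
    X, y, groups = stack_features(subset)
    if np.unique(groups).size < 2:
        raise ValueError("user-independent evaluation requires at least "
                         "2 distinct subjects")
    splitter = LeaveOneGroupOut()
    per_fold, fold_counts, pooled = _run_folds(
        X, y, splitter.split(X, y, groups), labels, config)
    report = EvaluationReport(protocol="user_independent", state_set=state_set,
                              labels=labels, per_fold_accuracy=per_fold,
                              confusion=pooled, fold_test_counts=fold_counts)
    report.validate()
    return report
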