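"""Dataset splitting, standardization/fusion, and the classifier families.

The screening model is deliberately classical: an RBF support vector
machine, a k-nearest-neighbor voter and a random forest, trained on one
feature row per subject (never per frame, so a subject can never leak
across the train/test boundary) drawn from three feature sets — geometric
mouth angles, eye/mouth texture descriptors, or their concatenation.
Features are z-scored with statistics estimated on the training rows only.
All scores are monotone class-1 propensities in [0, 1] so a single Youden
threshold turns them into hard labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import LayoutMismatchError

ALGORITHMS = ("svm", "knn", "rf")

#: Conventional defaults, all overridable per call.  The forest deliberately
#: considers every feature at each split (bagging provides tree diversity):
#: with per-split candidate subsampling, a narrow feature block fused to a
#: block three orders of magnitude wider (6 mouth angles next to ~8000
#: texture columns) is almost never offered as a split candidate, which
#: silently reduces the combined model to a texture model.
DEFAULT_HYPERPARAMS = {
    "svm": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "knn": {"n_neighbors": 5, "metric": "euclidean"},
    "rf": {"n_estimators": 100, "max_features": None},
}


@dataclass
class FeatureMatrix:
    """Subjects x named-features matrix with binary labels
    (patient=1, control=0)."""

    X: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, p = self.X.shape
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match matrix width")
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError("labels/subject_ids length does not match row count")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def rows(self, ids: Sequence[str]) -> "FeatureMatrix":
        index = {s: i for i, s in enumerate(self.subject_ids)}
        sel = [index[s] for s in ids]
        return FeatureMatrix(self.X[sel], self.feature_names,
                             self.labels[sel], [self.subject_ids[i] for i in sel])


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int


@dataclass(frozen=True)
class StandardizationStats:
    """Per-feature location/scale estimated on training rows only."""

    mean: np.ndarray
    sd: np.ndarray
    zero_sd: np.ndarray  # boolean flags for constant training features

    @classmethod
    def fit(cls, X: np.ndarray) -> "StandardizationStats":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        return cls(mean, sd, sd < 1e-12)

    def transform(self, X: np.ndarray) -> np.ndarray:
        sd = np.where(self.zero_sd, 1.0, self.sd)
        Z = (np.asarray(X, dtype=float) - self.mean) / sd
        Z[:, self.zero_sd] = 0.0
        return Z


@dataclass
class TrainedModel:
    algorithm: str
    hyperparams: dict
    estimator: object
    feature_names: list[str]
    stats: StandardizationStats | None
    seed: int


def split_dataset(matrix: FeatureMatrix, n_train: int, n_test: int,
                  seed: int = 0) -> DatasetSplit:
    """Stratified random train/test split by subject id.

    Class proportions in each part match the overall proportion within one
    subject; deterministic given the seed.
    """
    if n_train + n_test != matrix.n:
        raise ValueError(
            f"n_train + n_test = {n_train + n_test} does not equal "
            f"the {matrix.n} rows of the matrix"
        )
    train_idx, test_idx = train_test_split(
        np.arange(matrix.n), train_size=n_train, test_size=n_test,
        stratify=matrix.labels, random_state=seed, shuffle=True,
    )
    ids = matrix.subject_ids
    return DatasetSplit(tuple(ids[i] for i in sorted(train_idx)),
                        tuple(ids[i] for i in sorted(test_idx)), seed)


def combine_features(geom: FeatureMatrix, tex: FeatureMatrix) -> FeatureMatrix:
    """Concatenate geometric and texture blocks, [geometric | texture]."""
    if geom.subject_ids != tex.subject_ids:
        raise ValueError("subject ordering differs between feature blocks")
    if not np.array_equal(geom.labels, tex.labels):
        raise ValueError("labels differ between feature blocks")
    return FeatureMatrix(
        np.hstack([geom.X, tex.X]),
        list(geom.feature_names) + list(tex.feature_names),
        geom.labels, geom.subject_ids,
    )


def standardize_and_combine(geom: FeatureMatrix, tex: FeatureMatrix,
                            stats: StandardizationStats) -> FeatureMatrix:
    """Z-score the combined [geometric | texture] matrix with training-row
    statistics; constant training features become 0 everywhere."""
    combined = combine_features(geom, tex)
    return FeatureMatrix(stats.transform(combined.X), combined.feature_names,
                         combined.labels, combined.subject_ids)


def train_classifier(matrix: FeatureMatrix, algo: str,
                     hyperparams: dict | None = None, seed: int = 0,
                     stats: StandardizationStats | None = None) -> TrainedModel:
    """Fit one classifier family on (already standardized) training rows."""
    if algo not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algo!r}; expected one of {ALGORITHMS}")
    classes = np.unique(matrix.labels)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    if min(np.sum(matrix.labels == c) for c in classes) < 2:
        raise ValueError("need at least 2 training rows per class")
    hp = dict(DEFAULT_HYPERPARAMS[algo])
    hp.update(hyperparams or {})
    if algo == "svm":
        est = SVC(**hp)
    elif algo == "knn":
        est = KNeighborsClassifier(**hp)
    else:
        est = RandomForestClassifier(random_state=seed, **hp)
    est.fit(matrix.X, matrix.labels)
    return TrainedModel(algo, hp, est, list(matrix.feature_names), stats, seed)


def score(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Continuous class-1 propensity in [0, 1] per subject.

    Random forest: fraction of trees voting patient (fully grown trees have
    pure leaves, so the averaged leaf distribution is the vote fraction).
    KNN: neighbor vote fraction.  SVM: the signed decision value squashed
    through a logistic, which preserves the ranking the ROC analysis needs.
    """
    if list(matrix.feature_names) != model.feature_names:
        raise LayoutMismatchError(
            "feature layout does not match the layout the model was trained on"
        )
    if model.algorithm == "svm":
        d = model.estimator.decision_function(matrix.X)
        return 1.0 / (1.0 + np.exp(-d))
    proba = model.estimator.predict_proba(matrix.X)
    class_idx = int(np.where(model.estimator.classes_ == 1)[0][0])
    return proba[:, class_idx]
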