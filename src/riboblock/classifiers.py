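"""The four classifiers (LDA, PNN, decision tree, KNN) and V-fold CV.

The decision tree wraps scikit-learn; LDA, KNN and the probabilistic
neural network (PNN, a Parzen-window density classifier) are implemented
here because their exact conventions matter to the method: LDA uses
class-wise means with a pooled covariance regularized by an additive
ridge (so block columns that are constant within every class — common
for planted-block features — stay well-posed), KNN breaks voting ties by
the nearest neighbour belonging to a tied class, and the PNN assigns by
Bayes' rule over Gaussian-kernel class-conditional densities with class
priors proportional to training counts.

Location features span very different ranges (0 to 200+ nt), so features
are z-scored on the training fold for the scale-sensitive classifiers
(LDA, PNN, KNN); the decision tree sees raw values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.tree import DecisionTreeClassifier

from .evaluation import ConfusionStats, confusion_from_predictions
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("lda", "pnn", "tree", "knn")


@dataclass(frozen=True)
class CVConfig:
    """V-fold cross-validation settings (V=10 by default, stratified)."""

    v: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.v < 2:
            raise ValueError(f"CVConfig: need v >= 2, got {self.v}")


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to run and its hyperparameters.

    k — neighbours for KNN (default 4); sigma — PNN Gaussian kernel
    bandwidth on standardized features; shrinkage — LDA pooled-covariance
    regularizer; min_leaf — decision-tree minimum leaf size.
    """

    kind: str
    k: int = 4
    sigma: float = 1.0
    shrinkage: float = 1e-3
    min_leaf: int = 5

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"ClassifierSpec: unknown kind {self.kind!r} "
                             f"(expected one of {CLASSIFIER_KINDS})")
        if self.k < 1:
            raise ValueError(f"ClassifierSpec: k must be >= 1, got {self.k}")
        if self.sigma <= 0:
            raise ValueError(f"ClassifierSpec: sigma must be > 0, got {self.sigma}")
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ValueError(f"ClassifierSpec: shrinkage {self.shrinkage} not in [0, 1]")
        if self.min_leaf < 1:
            raise ValueError(f"ClassifierSpec: min_leaf must be >= 1, got {self.min_leaf}")


def vfold_split(n: int, labels: Sequence[str] | None, config: CVConfig) -> list[np.ndarray]:
    """Partition indices 0..n-1 into V disjoint near-equal folds.

    Fold sizes differ by at most one.  When stratified (labels required),
    each class's indices are dealt one at a time to the currently smallest
    fold (ties: fewest members of that class, then lowest fold index), so
    every class is spread across folds as evenly as possible while keeping
    totals balanced.  Deterministic given the seed.
    """
    if n < config.v:
        raise ValueError(f"vfold_split: n={n} smaller than v={config.v}")
    rng = np.random.default_rng(config.seed)
    folds: list[list[int]] = [[] for _ in range(config.v)]

    if config.stratified and labels is not None:
        labels = np.asarray(labels)
        if len(labels) != n:
            raise ValueError("vfold_split: labels length does not match n")
        totals = np.zeros(config.v, dtype=int)
        for cls in sorted(set(labels.tolist())):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            counts = np.zeros(config.v, dtype=int)
            for i in idx:
                # lexicographic: smallest fold, then fewest of this class
                f = min(range(config.v), key=lambda j: (totals[j], counts[j], j))
                folds[f].append(int(i))
                totals[f] += 1
                counts[f] += 1
    else:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, config.v)):
            folds[f] = [int(i) for i in chunk]

    return [np.array(sorted(f), dtype=int) for f in folds]


def _standardize(X_train: np.ndarray, X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both matrices with training-fold statistics.

    Zero-variance columns are centred but left unscaled.
    """
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X_train - mu) / sd, (X_test - mu) / sd


def pnn_posteriors(X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray,
                   sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Class posterior probabilities of the Parzen-window classifier.

    The class-conditional density at x is the mean of isotropic Gaussian
    kernels centred on the class's training points; with priors
    proportional to class counts the posterior reduces to the class-wise
    kernel sum normalized over all training points.  Computed in the log
    domain for stability at small bandwidths.
    """
    classes = np.unique(y_train)
    d2 = (
        np.sum(X_test ** 2, axis=1)[:, None]
        + np.sum(X_train ** 2, axis=1)[None, :]
        - 2.0 * X_test @ X_train.T
    )
    log_kernel = -d2 / (2.0 * sigma ** 2)
    log_scores = np.column_stack([
        logsumexp(log_kernel[:, y_train == c], axis=1) for c in classes
    ])
    log_post = log_scores - logsumexp(log_scores, axis=1, keepdims=True)
    return classes, np.exp(log_post)


def _predict_lda(spec, X_train, y_train, X_test):
    """Linear discriminant scores from class means and a ridge-regularized
    pooled covariance, equal priors; ties go to the first class."""
    classes = np.unique(y_train)
    n, d = X_train.shape
    means = np.vstack([X_train[y_train == c].mean(axis=0) for c in classes])
    centered = X_train - means[np.searchsorted(classes, y_train)]
    dof = max(n - len(classes), 1)
    cov = centered.T @ centered / dof + spec.shrinkage * np.eye(d)
    weights = np.linalg.solve(cov, means.T)              # d x K
    scores = X_test @ weights - 0.5 * np.sum(means.T * weights, axis=0)
    return classes[np.argmax(scores, axis=1)]


def _predict_pnn(spec, X_train, y_train, X_test):
    classes, post = pnn_posteriors(X_train, y_train, X_test, spec.sigma)
    return classes[np.argmax(post, axis=1)]


def _predict_knn(spec, X_train, y_train, X_test):
    k = min(spec.k, len(y_train))
    d2 = (
        np.sum(X_test ** 2, axis=1)[:, None]
        + np.sum(X_train ** 2, axis=1)[None, :]
        - 2.0 * X_test @ X_train.T
    )
    preds = []
    for row in d2:
        order = np.argsort(row, kind="stable")[:k]
        votes: dict[str, int] = {}
        for i in order:
            votes[y_train[i]] = votes.get(y_train[i], 0) + 1
        top = max(votes.values())
        tied = {c for c, v in votes.items() if v == top}
        if len(tied) == 1:
            preds.append(next(iter(tied)))
        else:
            # tie rule: the nearest neighbour whose class is tied wins
            preds.append(next(y_train[i] for i in order if y_train[i] in tied))
    return np.array(preds)


def train_predict(spec: ClassifierSpec, X_train: np.ndarray, y_train: Sequence[str],
                  X_test: np.ndarray) -> np.ndarray:
    """Fit one classifier on the training rows and label the test rows."""
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    if X_test.shape[1] != X_train.shape[1]:
        raise ValueError("train_predict: train/test column mismatch")
    classes = np.unique(y_train)
    if len(classes) < 2:
        raise ValueError("train_predict: training set contains a single class")

    if spec.kind == "tree":
        tree = DecisionTreeClassifier(
            criterion="gini", min_samples_leaf=spec.min_leaf, random_state=0
        )
        tree.fit(X_train, y_train)
        return np.asarray(tree.predict(X_test))

    Xtr, Xte = _standardize(X_train, X_test)
    if spec.kind == "lda":
        return _predict_lda(spec, Xtr, y_train, Xte)
    if spec.kind == "pnn":
        return _predict_pnn(spec, Xtr, y_train, Xte)
    return _predict_knn(spec, Xtr, y_train, Xte)


@dataclass
class CVResult:
    """Cross-validated predictions with both CCR conventions.

    ``ccr_mean`` averages the per-fold correct classification rates (the
    V-fold definition); ``ccr_pooled`` is trace/total of the pooled
    confusion matrix.  They coincide only when all folds have equal size.
    """

    confusion: ConfusionStats
    fold_ccrs: list[float]
    predictions: np.ndarray
    classes: list[str] = field(default_factory=list)

    @property
    def ccr_mean(self) -> float:
        return float(np.mean(self.fold_ccrs))

    @property
    def ccr_pooled(self) -> float:
        counts = self.confusion.counts
        return float(np.trace(counts) / counts.sum())


def cross_validate(spec: ClassifierSpec, features: FeatureMatrix,
                   config: CVConfig = CVConfig()) -> CVResult:
    """Run V-fold CV: each fold is held out once, confusion counts pooled."""
    labels = np.asarray(features.families)
    folds = vfold_split(features.n_observations, labels, config)
    classes = features.class_labels
    predictions = np.empty(features.n_observations, dtype=object)
    fold_ccrs: list[float] = []
    all_idx = np.arange(features.n_observations)
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(features.n_observations, dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        missing = set(classes) - set(labels[train_idx].tolist())
        if missing:
            logger.warning("fold %d: training split lacks class(es) %s", f, sorted(missing))
        preds = train_predict(spec, features.values[train_idx], labels[train_idx],
                              features.values[test_idx])
        predictions[test_idx] = preds
        fold_ccrs.append(float(np.mean(preds == labels[test_idx])))
    stats = confusion_from_predictions(labels.tolist(), predictions.tolist(), classes)
    return CVResult(confusion=stats, fold_ccrs=fold_ccrs,
                    predictions=np.asarray(predictions, dtype=str), classes=classes)
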