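"""PCA reduction, one-against-rest linear SVMs, LOOCV and permutation test.

For a k-class problem, k soft-margin linear SVMs are trained, each with
one class positive and the rest negative; prediction is the class whose
SVM outputs the highest decision value (ties broken by class order).
Generalization is estimated by leave-one-out cross-validation, with the
PCA transform refit inside every fold so the held-out subject never
leaks into the model. Significance is assessed by re-running the full
LOOCV under randomly permuted labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .synthetic import CLASS_ORDER

__all__ = [
    "PCATransform",
    "TrainedOvRModel",
    "LabeledCohort",
    "CVResult",
    "PermutationResult",
    "fit_pca",
    "train_ovr",
    "loocv",
    "permutation_test",
]


@dataclass
class PCATransform:
    """Mean vector plus orthonormal loading columns (p x d)."""

    mean: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.shape[0] != self.mean.size:
            raise ValueError("loadings rows must match mean length")

    @property
    def d(self) -> int:
        return self.loadings.shape[1]

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Project (x - mean) onto the principal directions."""
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.p:
            raise ValueError(f"expected {self.p} features, got {x.shape[-1]}")
        return (x - self.mean) @ self.loadings


def fit_pca(train_features: np.ndarray, d: int | None = None) -> PCATransform:
    """Principal directions of mean-centered training data.

    ``d`` defaults to min(n_train - 1, p), the maximal count that is
    lossless for a linear classifier acting in the training span.
    Component sign is fixed by making each column's largest-magnitude
    element positive, so the transform is fully deterministic.
    """
    x = np.asarray(train_features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 training rows")
    n, p = x.shape
    d_max = min(n - 1, p)
    if d is None:
        d = d_max
    if not 1 <= d <= d_max:
        raise ValueError(f"d must be in [1, {d_max}], got {d}")
    mean = x.mean(axis=0)
    _, s, vt = np.linalg.svd(x - mean, full_matrices=False)
    loadings = vt[:d].T
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    return PCATransform(
        mean=mean,
        loadings=loadings,
        explained_variance=(s[:d] ** 2) / (n - 1),
    )


@dataclass
class TrainedOvRModel:
    """PCA transform plus k linear decision functions (one per class)."""

    pca: PCATransform
    weights: np.ndarray  # k x d, in PCA space
    biases: np.ndarray  # k
    class_order: tuple[str, ...]
    cost_C: float

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        """All k decision values for feature vector(s) in original space."""
        z = self.pca.transform(np.atleast_2d(np.asarray(x, dtype=float)))
        return z @ self.weights.T + self.biases

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class with the highest decision value; first class wins ties."""
        dv = self.decision_values(x)
        idx = dv.argmax(axis=1)
        return np.asarray(self.class_order)[idx]


def _binary_svm(z: np.ndarray, ybin: np.ndarray, cost_c: float) -> SVC:
    clf = SVC(kernel="linear", C=cost_c, shrinking=False)
    clf.fit(z, ybin)
    return clf


def train_ovr(
    svm_inputs: np.ndarray,
    labels: Sequence[str],
    cost_c: float = 1.0,
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> tuple[np.ndarray, np.ndarray]:
    """Train one linear SVM per class (that class vs. the rest).

    Returns the k x d weight matrix and length-k bias vector; decision
    value row ``w_k . z + b_k`` is positive on the side of class k.
    """
    z = np.asarray(svm_inputs, dtype=float)
    labels = np.asarray(labels)
    weights = np.empty((len(class_order), z.shape[1]))
    biases = np.empty(len(class_order))
    for k, cls in enumerate(class_order):
        ybin = np.where(labels == cls, 1, -1)
        if np.all(ybin == -1) or np.all(ybin == 1):
            raise ValueError(f"class {cls!r} absent from training data")
        clf = _binary_svm(z, ybin, cost_c)
        weights[k] = clf.coef_[0]
        biases[k] = clf.intercept_[0]
    return weights, biases


def train_model(
    features: np.ndarray,
    labels: Sequence[str],
    d: int | None = None,
    cost_c: float = 1.0,
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> TrainedOvRModel:
    """Fit PCA then the one-against-rest SVMs on raw feature rows."""
    pca = fit_pca(features, d)
    z = pca.transform(np.asarray(features, dtype=float))
    weights, biases = train_ovr(z, labels, cost_c, class_order)
    return TrainedOvRModel(
        pca=pca,
        weights=weights,
        biases=biases,
        class_order=class_order,
        cost_C=cost_c,
    )


@dataclass
class LabeledCohort:
    """Feature matrix with one class label per subject."""

    features: np.ndarray  # n x p
    labels: np.ndarray  # n class names
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("one label per feature row required")
        if not self.subject_ids:
            self.subject_ids = tuple(
                f"sub-{i + 1:03d}" for i in range(self.features.shape[0])
            )

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]


@dataclass
class CVResult:
    """Leave-one-out predictions, confusion matrix and per-fold models."""

    true_labels: np.ndarray
    predicted_labels: np.ndarray
    accuracy: float
    confusion_percent: np.ndarray  # rows true class, columns predicted, %
    class_order: tuple[str, ...]
    fold_weights: list[np.ndarray] = field(default_factory=list)  # each k x d
    fold_biases: list[np.ndarray] = field(default_factory=list)
    fold_pcas: list[PCATransform] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return self.true_labels.size

    def per_class_accuracy(self) -> dict[str, float]:
        return {
            cls: float(self.confusion_percent[k, k])
            for k, cls in enumerate(self.class_order)
        }


def _confusion_percent(
    true_labels: np.ndarray,
    predicted: np.ndarray,
    class_order: tuple[str, ...],
) -> np.ndarray:
    k = len(class_order)
    counts = np.zeros((k, k))
    pos = {cls: i for i, cls in enumerate(class_order)}
    for t, p in zip(true_labels, predicted):
        counts[pos[t], pos[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        raise ValueError("a class has no subjects")
    return counts / row_sums * 100.0


def loocv(
    cohort: LabeledCohort,
    d: int | None = None,
    cost_c: float = 1.0,
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> CVResult:
    """Leave-one-out cross-validation with per-fold PCA refit (no leakage).

    Each fold stores its weight vectors and PCA transform so that the
    discriminative edge maps can be reconstructed afterwards.
    """
    x, y = cohort.features, cohort.labels
    n = cohort.n_subjects
    for cls in class_order:
        if np.sum(y == cls) < 2:
            raise ValueError(
                f"class {cls!r} has fewer than 2 subjects; a fold would "
                "lose the class"
            )
    predicted = np.empty(n, dtype=y.dtype)
    fold_weights: list[np.ndarray] = []
    fold_biases: list[np.ndarray] = []
    fold_pcas: list[PCATransform] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = train_model(x[mask], y[mask], d, cost_c, class_order)
        predicted[i] = model.predict(x[i : i + 1])[0]
        fold_weights.append(model.weights)
        fold_biases.append(model.biases)
        fold_pcas.append(model.pca)
    return CVResult(
        true_labels=y.copy(),
        predicted_labels=predicted,
        accuracy=float(np.mean(predicted == y)),
        confusion_percent=_confusion_percent(y, predicted, class_order),
        class_order=class_order,
        fold_weights=fold_weights,
        fold_biases=fold_biases,
        fold_pcas=fold_pcas,
    )


@dataclass
class PermutationResult:
    """Observed accuracy against a label-permutation null distribution."""

    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    n_perm: int


def _fold_caches(
    x: np.ndarray, d: int | None
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-fold (rest-index, Gram, test-kernel-row) for permutation reruns.

    PCA is unsupervised, so each fold's transform is identical under any
    relabeling; precomputing the projected training Gram matrix makes the
    permutation loop label-only work.
    """
    n = x.shape[0]
    caches = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pca = fit_pca(x[mask], d)
        z_train = pca.transform(x[mask])
        z_test = pca.transform(x[i])
        caches.append((mask, z_train @ z_train.T, z_train @ z_test))
    return caches


def permutation_test(
    cohort: LabeledCohort,
    d: int | None = None,
    cost_c: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    class_order: tuple[str, ...] = CLASS_ORDER,
    cv_result: CVResult | None = None,
) -> PermutationResult:
    """Label-permutation null for the LOOCV accuracy.

    Every iteration permutes all subject labels uniformly at random and
    reruns the complete LOOCV; the p-value uses the add-one estimator
    (#{null >= observed} + 1) / (n_perm + 1), so it is never zero.
    Permutation i draws from a stream spawned from (seed, i) for
    reproducibility.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if cv_result is None:
        cv_result = loocv(cohort, d, cost_c, class_order)
    observed = cv_result.accuracy

    x, y = cohort.features, cohort.labels
    caches = _fold_caches(x, d)
    streams = np.random.SeedSequence(seed).spawn(n_perm)
    nulls = np.empty(n_perm)
    k = len(class_order)
    for it in range(n_perm):
        rng = np.random.default_rng(streams[it])
        y_perm = rng.permutation(y)
        correct = 0
        for i, (mask, gram, g_test) in enumerate(caches):
            y_rest = y_perm[mask]
            decisions = np.empty(k)
            for c, cls in enumerate(class_order):
                ybin = np.where(y_rest == cls, 1, -1)
                clf = SVC(kernel="precomputed", C=cost_c, shrinking=False)
                clf.fit(gram, ybin)
                decisions[c] = (
                    clf.dual_coef_[0] @ g_test[clf.support_] + clf.intercept_[0]
                )
            if class_order[int(decisions.argmax())] == y_perm[i]:
                correct += 1
        nulls[it] = correct / y.size

    p_value = (np.sum(nulls >= observed) + 1.0) / (n_perm + 1.0)
    return PermutationResult(
        observed_accuracy=observed,
        null_accuracies=nulls,
        p_value=float(p_value),
        n_perm=n_perm,
    )
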