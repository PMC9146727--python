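"""Classifiers and the k-fold evaluation harness.

Random-subspace ensembles (k-NN or regularised nearest-mean discriminant
bases with majority voting) are implemented here; the standard learners —
polynomial-kernel SVMs and boosted trees — are delegated to scikit-learn.
``crossval_evaluate`` produces a :class:`CVReport` with per-fold accuracies,
the pooled confusion matrix and the mean accuracy in percent.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

__all__ = [
    "ClassifierSpec",
    "CVReport",
    "NearestMeanDiscriminant",
    "SubspaceEnsembleClassifier",
    "make_classifier",
    "subspace_ensemble_fit",
    "fit_predict_standard",
    "crossval_evaluate",
]

KINDS = ("ESKNN", "ESD", "EBT", "CSVM", "QSVM", "LSVM")


@dataclass
class ClassifierSpec:
    kind: str
    n_learners: int = 30
    subspace_dim: int | None = None
    knn_k: int = 1
    seed: int = 0

    def __post_init__(self):
        self.kind = self.kind.upper()
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.n_learners < 1:
            raise ValueError("need at least one learner")


@dataclass
class CVReport:
    fold_accuracies: np.ndarray
    mean_accuracy: float            # percent, pooled over folds
    confusion: np.ndarray           # K x K counts, rows = true class
    train_time: float               # seconds, informational only
    classifier: ClassifierSpec
    fold_scheme: int
    seed: int
    class_names: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy_pct": round(float(self.mean_accuracy), 2),
            "confusion": self.confusion.tolist(),
            "train_time_s": float(self.train_time),
            "classifier": self.classifier.kind,
            "fold_scheme": self.fold_scheme,
            "seed": self.seed,
            "class_names": list(self.class_names),
        }

    def save(self, json_path, confusion_csv=None) -> None:
        with open(json_path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        if confusion_csv is not None:
            names = self.class_names or [str(i) for i in range(len(self.confusion))]
            pd.DataFrame(self.confusion, index=names, columns=names).to_csv(
                confusion_csv)


class NearestMeanDiscriminant(BaseEstimator, ClassifierMixin):
    """Linear discriminant with class means and pooled covariance + lambda*I."""

    def __init__(self, reg: float = 1e-3):
        self.reg = reg

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("discriminant needs at least 2 classes")
        n, d = X.shape
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        pooled = np.zeros((d, d))
        for c in self.classes_:
            Xc = X[y == c]
            pooled += (Xc - Xc.mean(axis=0)).T @ (Xc - Xc.mean(axis=0))
        pooled /= max(n - self.classes_.size, 1)
        pooled[np.diag_indices(d)] += self.reg
        self._w = np.linalg.solve(pooled, self.means_.T)          # d x K
        self._b = -0.5 * np.einsum("kd,dk->k", self.means_, self._w)
        priors = np.array([(y == c).mean() for c in self.classes_])
        self._b += np.log(priors)
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self._w + self._b

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]


class SubspaceEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Random-subspace ensemble with majority voting.

    Each of ``n_estimators`` base learners (1..k-NN or a regularised
    nearest-mean discriminant) is trained on a seeded random feature subspace
    of ``subspace_dim`` columns; prediction is by majority vote with ties
    broken toward the lowest class index.

    ``base='knn'`` gives the subspace-KNN ensemble, ``base='discriminant'``
    the subspace-discriminant ensemble.
    """

    def __init__(self, base: str = "knn", n_estimators: int = 30,
                 subspace_dim: int | None = None, knn_k: int = 1,
                 reg: float = 1e-3, random_state: int = 0):
        self.base = base
        self.n_estimators = n_estimators
        self.subspace_dim = subspace_dim
        self.knn_k = knn_k
        self.reg = reg
        self.random_state = random_state

    def _make_base(self):
        if self.base == "knn":
            return KNeighborsClassifier(n_neighbors=self.knn_k)
        if self.base == "discriminant":
            return NearestMeanDiscriminant(reg=self.reg)
        raise ValueError(f"unknown base learner {self.base!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        d = X.shape[1]
        dim = self.subspace_dim if self.subspace_dim is not None else -(-d // 2)
        if not 1 <= dim <= d:
            raise ValueError(f"subspace_dim must lie in 1..{d}")
        rng = np.random.default_rng(self.random_state)
        self.subspaces_ = [np.sort(rng.choice(d, size=dim, replace=False))
                           for _ in range(self.n_estimators)]
        self.estimators_ = [self._make_base().fit(X[:, idx], y)
                            for idx in self.subspaces_]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], self.classes_.size), dtype=int)
        lookup = {c: i for i, c in enumerate(self.classes_)}
        for est, idx in zip(self.estimators_, self.subspaces_):
            pred = est.predict(X[:, idx])
            for r, p in enumerate(pred):
                votes[r, lookup[p]] += 1
        return self.classes_[votes.argmax(axis=1)]  # argmax -> lowest index on ties


def make_classifier(spec: ClassifierSpec):
    """Instantiate the estimator named by ``spec.kind``."""
    k = spec.kind
    if k == "ESKNN":
        return SubspaceEnsembleClassifier(
            base="knn", n_estimators=spec.n_learners,
            subspace_dim=spec.subspace_dim, knn_k=spec.knn_k,
            random_state=spec.seed)
    if k == "ESD":
        return SubspaceEnsembleClassifier(
            base="discriminant", n_estimators=spec.n_learners,
            subspace_dim=spec.subspace_dim, random_state=spec.seed)
    if k == "EBT":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=3, random_state=spec.seed),
            n_estimators=50, random_state=spec.seed)
    if k == "LSVM":
        return SVC(kernel="linear", C=1.0)
    if k == "QSVM":
        return SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=10.0)
    if k == "CSVM":
        return SVC(kernel="poly", degree=3, coef0=1.0, gamma="scale", C=10.0)
    raise ValueError(f"unknown classifier kind {k!r}")


def _xy(fm):
    if isinstance(fm, FeatureMatrix):
        return fm.values, fm.labels
    X, y = fm
    return np.asarray(X, dtype=float), np.asarray(y)


def subspace_ensemble_fit(fm, spec: ClassifierSpec) -> SubspaceEnsembleClassifier:
    """Fit a subspace ensemble (spec.kind must be ESKNN or ESD)."""
    if spec.kind not in ("ESKNN", "ESD"):
        raise ValueError("subspace_ensemble_fit takes ESKNN or ESD specs")
    X, y = _xy(fm)
    return make_classifier(spec).fit(X, y)


def fit_predict_standard(fm, spec: ClassifierSpec):
    """Fit one of the delegated standard learners (EBT / CSVM / QSVM / LSVM)."""
    if spec.kind not in ("EBT", "CSVM", "QSVM", "LSVM"):
        raise ValueError("fit_predict_standard takes EBT/CSVM/QSVM/LSVM specs")
    X, y = _xy(fm)
    if np.unique(y).size < 2:
        raise ValueError("cannot fit on single-class training data")
    return make_classifier(spec).fit(X, y)


def crossval_evaluate(fm, spec: ClassifierSpec, k_folds: int,
                      seed: int = 0, class_names=None) -> CVReport:
    """Stratified k-fold CV: each sample predicted exactly once; confusion
    matrix pooled over folds; mean accuracy = 100 * trace / total."""
    X, y = _xy(fm)
    if k_folds < 2:
        raise ValueError("need k_folds >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members < {k_folds} folds")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    K = classes.size
    confusion = np.zeros((K, K), dtype=int)
    idx_of = {c: i for i, c in enumerate(classes)}
    fold_accs = []
    t0 = time.perf_counter()
    proto = make_classifier(spec)
    for tr, te in skf.split(X, y):
        clf = clone(proto).fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        fold_accs.append(float((pred == y[te]).mean()))
        for t, p in zip(y[te], pred):
            confusion[idx_of[t], idx_of[p]] += 1
    elapsed = time.perf_counter() - t0
    mean_acc = 100.0 * np.trace(confusion) / confusion.sum()
    return CVReport(fold_accuracies=np.asarray(fold_accs),
                    mean_accuracy=float(mean_acc), confusion=confusion,
                    train_time=elapsed, classifier=spec, fold_scheme=k_folds,
                    seed=seed,
                    class_names=list(class_names) if class_names else
                    [str(c) for c in classes])
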