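"""Hypertensive-retinopathy grade classifiers.

Two boosted ("improved") classifiers over 24-feature vectors, the six
plain SVM and five plain KNN variants they are compared against, a
stratified k-fold cross-validation driver and the stratified 80:20
train/test split.

*Improved SVM* — an iterative scheme over one-vs-rest linear SVMs: each
round fits on the current sample weights, evaluates the per-sample
multiclass hinge loss, up-weights the poorly scored samples
(``w <- w * exp(loss)``, renormalized) and stores the round's scorer.
The final decision averages the rounds' score vectors with per-round
weights proportional to each round's weighted training accuracy.  With
one round and uniform weights it reduces exactly to the plain linear
variant.

*Improved KNN* — boosting over weak KNN learners, each a small-k KNN
(k drawn from {1, 3, 5}) on a random feature subset, fitted to a
weighted resample of the training set.  Rounds reweight samples by the
weighted error (multiclass AdaBoost/SAMME votes); prediction is the
weighted vote over the ensemble, and the weak learner with the lowest
weighted training error is recorded as ``best_learner_``.

Both estimators follow the sklearn fit/predict idiom and are
deterministic under their ``seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Hashable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .metrics import ConfusionCounts, confusion, macro_metrics

__all__ = [
    "ImprovedSVM", "ImprovedKNN", "CVResult",
    "make_svm_variant", "make_knn_variant", "kfold_cv", "split_80_20",
]

_N_FEATURES = 24


def _check_xy(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.isfinite(X).all():
        raise ValueError("features contain NaN or infinity")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    return X, y


class ImprovedSVM:
    """Boosted one-vs-rest linear SVM (multiclass hinge reweighting)."""

    def __init__(self, n_rounds: int = 5, C: float = 1.0, seed: int = 0) -> None:
        if n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        self.n_rounds = n_rounds
        self.C = C
        self.seed = seed

    def get_params(self, deep: bool = True) -> Dict[str, object]:
        return {"n_rounds": self.n_rounds, "C": self.C, "seed": self.seed}

    def set_params(self, **kw) -> "ImprovedSVM":
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ImprovedSVM":
        X, y = _check_xy(X, y)
        n = len(y)
        self.classes_ = np.unique(y)
        w = np.full(n, 1.0 / n)
        self.rounds_: List[SVC] = []
        self.round_weights_: List[float] = []
        self.sample_weight_trace_: List[np.ndarray] = []
        for _ in range(self.n_rounds):
            est = SVC(kernel="linear", C=self.C, decision_function_shape="ovr",
                      random_state=self.seed)
            est.fit(X, y, sample_weight=w * n)  # scale-invariant, keeps C meaning
            scores = self._scores_of(est, X)
            yi = np.searchsorted(self.classes_, y)
            true_s = scores[np.arange(n), yi]
            masked = scores.copy()
            masked[np.arange(n), yi] = -np.inf
            margin_loss = np.maximum(0.0, 1.0 + masked.max(axis=1) - true_s)
            acc = float(np.sum(w * (scores.argmax(axis=1) == yi)))
            self.rounds_.append(est)
            self.round_weights_.append(max(acc, 1e-12))
            w = w * np.exp(np.minimum(margin_loss, 30.0))
            w = w / w.sum()
            self.sample_weight_trace_.append(w.copy())
        return self

    def _scores_of(self, est: SVC, X: np.ndarray) -> np.ndarray:
        s = est.decision_function(X)
        if s.ndim == 1:  # binary: expand to two-column ovr scores
            s = np.stack([-s, s], axis=1)
        return s

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        wsum = float(np.sum(self.round_weights_))
        out = np.zeros((len(X), len(self.classes_)))
        for est, rw in zip(self.rounds_, self.round_weights_):
            out += (rw / wsum) * self._scores_of(est, X)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.decision_function(X).argmax(axis=1)]


class ImprovedKNN:
    """Boosted ensemble of weak KNN learners with weighted voting."""

    def __init__(self, n_learners: int = 15, seed: int = 0) -> None:
        if n_learners < 1:
            raise ValueError("n_learners must be >= 1")
        self.n_learners = n_learners
        self.seed = seed

    def get_params(self, deep: bool = True) -> Dict[str, object]:
        return {"n_learners": self.n_learners, "seed": self.seed}

    def set_params(self, **kw) -> "ImprovedKNN":
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ImprovedKNN":
        X, y = _check_xy(X, y)
        rng = np.random.default_rng(self.seed)
        n, d = X.shape
        self.classes_ = np.unique(y)
        K = len(self.classes_)
        w = np.full(n, 1.0 / n)
        self.learners_: List[Tuple[KNeighborsClassifier, np.ndarray]] = []
        self.vote_weights_: List[float] = []
        self.train_errors_: List[float] = []
        n_sub = max(2, int(np.ceil(np.sqrt(d))))
        for _ in range(self.n_learners):
            feats = np.sort(rng.choice(d, size=n_sub, replace=False))
            k = int(rng.choice([1, 3, 5]))
            if self.n_learners == 1:
                idx = np.arange(n)  # degenerate ensemble: plain KNN on the data
            else:
                idx = rng.choice(n, size=n, replace=True, p=w)
            est = KNeighborsClassifier(n_neighbors=min(k, len(idx)))
            est.fit(X[np.ix_(idx, feats)], y[idx])
            pred = est.predict(X[:, feats])
            err = float(np.sum(w * (pred != y)))
            err = min(max(err, 1e-12), 1 - 1e-12)
            alpha = np.log((1 - err) / err) + np.log(K - 1)
            self.learners_.append((est, feats))
            self.vote_weights_.append(max(alpha, 1e-6))
            self.train_errors_.append(err)
            w = w * np.exp(alpha * (pred != y))
            w = w / w.sum()
        self.training_variance_ = float(np.var(self.train_errors_))
        self.best_learner_ = int(np.argmin(self.train_errors_))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        votes = np.zeros((len(X), len(self.classes_)))
        for (est, feats), vw in zip(self.learners_, self.vote_weights_):
            pred = est.predict(X[:, feats])
            ci = np.searchsorted(self.classes_, pred)
            votes[np.arange(len(X)), ci] += vw
        return self.classes_[votes.argmax(axis=1)]


# ----------------------------------------------------------------------
# plain variants

_SVM_KINDS = ("linear", "quadratic", "cubic",
              "fine_gaussian", "medium_gaussian", "coarse_gaussian")
_KNN_KINDS = ("fine", "medium", "coarse", "cosine", "weighted")


def make_svm_variant(kind: str, C: float = 1.0, seed: int = 0,
                     n_features: int = _N_FEATURES) -> SVC:
    """One of the six SVM variants.

    Polynomial kernels are ``(x.z + 1)^degree`` (degree 1/2/3); Gaussian
    kernels use bandwidth ``gamma`` = 4/d (fine), 1/d (medium), 0.25/d
    (coarse) for feature dimension ``d``, so fine < medium < coarse in
    kernel width.
    """
    d = n_features
    if kind == "linear":
        return SVC(kernel="linear", C=C, decision_function_shape="ovr",
                   random_state=seed)
    if kind in ("quadratic", "cubic"):
        degree = 2 if kind == "quadratic" else 3
        return SVC(kernel="poly", degree=degree, gamma=1.0, coef0=1.0, C=C,
                   decision_function_shape="ovr", random_state=seed)
    gammas = {"fine_gaussian": 4.0 / d, "medium_gaussian": 1.0 / d,
              "coarse_gaussian": 0.25 / d}
    if kind in gammas:
        return SVC(kernel="rbf", gamma=gammas[kind], C=C,
                   decision_function_shape="ovr", random_state=seed)
    raise ValueError(f"unknown SVM variant {kind!r}; expected one of {_SVM_KINDS}")


def make_knn_variant(kind: str, n_train: Optional[int] = None) -> KNeighborsClassifier:
    """One of the five KNN variants (fine k=1, medium k=10, coarse k=100,
    cosine distance k=10, inverse-distance-weighted votes k=10).

    For the coarse variant with fewer than 100 training points, k is
    clipped to ``n_train`` with a warning.
    """
    if kind == "fine":
        return KNeighborsClassifier(n_neighbors=1)
    if kind == "medium":
        return KNeighborsClassifier(n_neighbors=10)
    if kind == "coarse":
        k = 100
        if n_train is not None and n_train < 100:
            warnings.warn(f"coarse KNN: clipping k=100 to n_train={n_train}",
                          RuntimeWarning)
            k = n_train
        return KNeighborsClassifier(n_neighbors=k)
    if kind == "cosine":
        return KNeighborsClassifier(n_neighbors=10, metric="cosine")
    if kind == "weighted":
        return KNeighborsClassifier(n_neighbors=10, weights="distance")
    raise ValueError(f"unknown KNN variant {kind!r}; expected one of {_KNN_KINDS}")


# ----------------------------------------------------------------------
# cross-validation and splitting


@dataclass
class CVResult:
    """Stratified k-fold cross-validation summary."""

    k: int
    fold_counts: List[Dict[Hashable, ConfusionCounts]]
    fold_metrics: List[Dict[str, float]]
    aggregate: Dict[str, float]     # mean of per-fold macro metrics
    seed: int
    fold_test_indices: List[np.ndarray] = None


def _clone_est(est):
    try:
        return clone(est)
    except TypeError:
        return est.__class__(**est.get_params())


def kfold_cv(X: np.ndarray, y: np.ndarray, k: int, estimator, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation of any fit/predict estimator.

    Each fold serves exactly once as the test set; aggregate metrics are
    the mean of the per-fold macro metrics.  Falls back to plain k-fold
    with a warning when the smallest class has fewer than ``k`` members.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(y) < k:
        raise ValueError("need at least k samples")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        warnings.warn("a class has fewer members than k; using non-stratified folds",
                      RuntimeWarning)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    classes = list(np.unique(y))
    fold_counts, fold_metrics, fold_idx = [], [], []
    for train_idx, test_idx in splitter.split(X, y):
        est = _clone_est(estimator)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        cc = confusion(list(pred), list(y[test_idx]), classes)
        fm = macro_metrics(cc)
        # classification accuracy (fraction correct); the macro-averaged
        # one-vs-rest accuracy is kept under its own key
        fm["accuracy_ovr_macro"] = fm["accuracy"]
        fm["accuracy"] = float(np.mean(pred == y[test_idx]))
        fold_counts.append(cc)
        fold_metrics.append(fm)
        fold_idx.append(test_idx)
    agg = {m: float(np.mean([fm[m] for fm in fold_metrics]))
           for m in fold_metrics[0]}
    return CVResult(k=k, fold_counts=fold_counts, fold_metrics=fold_metrics,
                    aggregate=agg, seed=seed, fold_test_indices=fold_idx)


def split_80_20(labels: Sequence[Hashable], seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Stratified 80:20 train/test split over class labels.

    The test count per class is ``round(0.2 * n_c)`` (remainder to
    train), so the printed five-class distribution (200, 400, 200, 200,
    200) yields 960 training and 240 test indices.
    """
    y = np.asarray(labels)
    if len(y) < 5:
        raise ValueError("need at least 5 samples for an 80:20 split")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if idx.size == 0:
            raise ValueError(f"empty class {c!r}")
        rng.shuffle(idx)
        n_test = int(round(0.2 * idx.size))
        test.extend(idx[:n_test])
        train.extend(idx[n_test:])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))
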