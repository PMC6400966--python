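"""Uniform training/prediction contract over the four classifier families.

Four probabilistic binary classifiers are supported: logistic regression
(LR), k-nearest neighbours (kNN), quadratic discriminant analysis (QDA) and
a linear-kernel support vector classifier (SVC).  All operate on
standardized feature vectors; a trained model bundles the fitted estimator
with the standardization parameters and the feature subset it was trained
on, so it can score a raw feature vector standalone.

The positive class (label 1) is "phage" throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy.special import logsumexp
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import StandardizationParams

__all__ = ["ALGORITHMS", "Hyperparameters", "TrainedModel", "train", "save", "load"]

ALGORITHMS = ("lr", "knn", "qda", "svc")

_MODEL_FORMAT_VERSION = 1

#: powers-of-two grid for the regularization strength of LR and SVC
C_GRID = tuple(2.0 ** p for p in range(-5, 6))
#: odd neighbour counts evaluated for kNN
K_GRID = (1, 3, 5, 7, 9)


@dataclass(frozen=True)
class Hyperparameters:
    """Algorithm choice plus its tunables.

    ``C`` is the inverse regularization strength for LR/SVC (the search grid
    is the consecutive powers of two from 2^-5 to 2^5); ``k`` the odd
    neighbour count for kNN.  ``feature_subset`` holds the column indices the
    model is restricted to (None = all features).
    """

    algorithm: str
    C: float = 1.0
    k: int = 5
    feature_subset: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be a positive odd integer")

    def with_subset(self, subset: Sequence[int] | None) -> "Hyperparameters":
        return replace(
            self, feature_subset=tuple(subset) if subset is not None else None
        )


class RidgeQDA:
    """Quadratic discriminant analysis with regularized class covariances.

    Class-conditional Gaussians with full per-class covariance matrices.
    By default each class covariance is estimated with Ledoit-Wolf
    shrinkage, which stays well-conditioned even when a class has fewer
    samples than features; ``shrinkage="none"`` uses the plain sample
    covariance (matching textbook QDA on full-rank data).  A small ridge
    (default 1e-9) is additionally added so degenerate inputs never make
    the fit raise.  Posteriors are computed with log-sum-exp for numerical
    stability.
    """

    def __init__(self, ridge: float = 1e-9, shrinkage: str = "ledoit-wolf"):
        if ridge < 0:
            raise ValueError("ridge must be non-negative")
        if shrinkage not in ("ledoit-wolf", "none"):
            raise ValueError("shrinkage must be 'ledoit-wolf' or 'none'")
        self.ridge = ridge
        self.shrinkage = shrinkage

    def _class_covariance(self, Xc: np.ndarray) -> np.ndarray:
        if self.shrinkage == "ledoit-wolf" and len(Xc) > 1:
            from sklearn.covariance import LedoitWolf

            return LedoitWolf().fit(Xc).covariance_
        return np.atleast_2d(np.cov(Xc, rowvar=False, ddof=1))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RidgeQDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        p = X.shape[1]
        self.priors_: list[float] = []
        self.means_: list[np.ndarray] = []
        self._precision: list[np.ndarray] = []
        self._logdet: list[float] = []
        for c in self.classes_:
            Xc = X[y == c]
            self.priors_.append(len(Xc) / len(X))
            self.means_.append(Xc.mean(axis=0))
            cov = self._class_covariance(Xc) + self.ridge * np.eye(p)
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:  # only possible with ridge == 0 on degenerate data
                raise np.linalg.LinAlgError(
                    f"class {c} covariance is singular; increase ridge"
                )
            self._precision.append(np.linalg.inv(cov))
            self._logdet.append(float(logdet))
        return self

    def _log_posterior(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lp = np.empty((X.shape[0], len(self.classes_)))
        for j, (pi, mu, prec, ld) in enumerate(
            zip(self.priors_, self.means_, self._precision, self._logdet)
        ):
            d = X - mu
            maha = np.einsum("ij,jk,ik->i", d, prec, d)
            lp[:, j] = np.log(pi) - 0.5 * ld - 0.5 * maha
        return lp

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        lp = self._log_posterior(X)
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._log_posterior(X), axis=1)]


class PlattSVC:
    """Linear-kernel SVC with Platt-style probability calibration.

    The margin classifier itself has no probability output; after fitting,
    a one-dimensional sigmoid (logistic regression on the decision scores
    of the training data) maps margins to class probabilities.  Because
    the sigmoid is monotone, rankings - hence AUC - equal those of the raw
    decision function, and the whole fit is invariant to sample order.
    """

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PlattSVC":
        self.svc_ = SVC(kernel="linear", C=self.C, random_state=self.seed)
        self.svc_.fit(X, y)
        scores = self.svc_.decision_function(X).reshape(-1, 1)
        self.calibrator_ = LogisticRegression(C=1e6, max_iter=2000)
        self.calibrator_.fit(scores, y)
        self.classes_ = self.calibrator_.classes_
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        scores = self.svc_.decision_function(X).reshape(-1, 1)
        return self.calibrator_.predict_proba(scores)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    @property
    def coef_(self) -> np.ndarray:
        return self.svc_.coef_


def _build_estimator(hp: Hyperparameters, seed: int):
    if hp.algorithm == "lr":
        return LogisticRegression(C=hp.C, max_iter=2000, random_state=seed)
    if hp.algorithm == "knn":
        # brute-force search so equidistant neighbours resolve to the lowest
        # training index, keeping votes deterministic
        return KNeighborsClassifier(n_neighbors=hp.k, algorithm="brute")
    if hp.algorithm == "qda":
        # shrinkage keeps class covariances well-conditioned below n = p;
        # the tiny ridge guards truly degenerate inputs
        return RidgeQDA(ridge=1e-9, shrinkage="ledoit-wolf")
    if hp.algorithm == "svc":
        return PlattSVC(C=hp.C, seed=seed)
    raise AssertionError(hp.algorithm)


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed for standalone prediction."""

    hyperparameters: Hyperparameters
    estimator: object
    standardization: StandardizationParams
    feature_names: tuple[str, ...]
    classes: tuple[int, int] = (0, 1)
    seed: int = 0

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        subset = self.hyperparameters.feature_subset
        if subset is not None and X.shape[1] != len(subset):
            if X.shape[1] == len(self.feature_names) or X.shape[1] > max(subset):
                X = X[:, list(subset)]
            else:
                raise ValueError(
                    f"expected {len(subset)} (or full-schema) features, got {X.shape[1]}"
                )
        return self.standardization.transform(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, columns ordered as ``self.classes``."""
        proba = self.estimator.predict_proba(self._prepare(X))
        return proba

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Hard labels by thresholding P(positive class) at ``threshold``."""
        return (self.predict_proba(X)[:, 1] >= threshold).astype(int)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """P(positive class) for ranking/ROC purposes."""
        return self.predict_proba(X)[:, 1]


def train(
    X: np.ndarray,
    y: np.ndarray,
    hp: Hyperparameters,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit one classifier on raw (unstandardized) feature rows.

    Standardization parameters are estimated on ``X`` restricted to the
    hyperparameters' feature subset, then applied before fitting, so the
    model carries its own scaling.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains NaN/inf values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes in y, got {list(classes)}")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")

    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
    feature_names = tuple(feature_names)

    subset = hp.feature_subset
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("feature subset must be non-empty")
        Xs = X[:, list(subset)]
        used_names = tuple(feature_names[i] for i in subset)
    else:
        Xs = X
        used_names = feature_names

    params = StandardizationParams.fit(Xs, used_names)
    est = _build_estimator(hp, seed)
    est.fit(params.transform(Xs), y)
    return TrainedModel(
        hyperparameters=hp,
        estimator=est,
        standardization=params,
        feature_names=feature_names,
        classes=tuple(int(c) for c in classes),
        seed=seed,
    )


def save(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model as a single-file bundle."""
    bundle = {
        "format_version": _MODEL_FORMAT_VERSION,
        "algorithm": model.hyperparameters.algorithm,
        "hyperparameters": model.hyperparameters,
        "estimator": model.estimator,
        "standardization_mean": model.standardization.mean,
        "standardization_std": model.standardization.std,
        "standardization_names": model.standardization.feature_names,
        "feature_names": model.feature_names,
        "classes": model.classes,
        "seed": model.seed,
    }
    joblib.dump(bundle, path)


def load(path: str | Path) -> TrainedModel:
    """Load a model bundle written by :func:`save`.

    Raises ``ValueError`` on corrupted files or unknown bundle versions
    rather than returning a partially constructed model.
    """
    try:
        bundle = joblib.load(path)
    except Exception as exc:  # unreadable / truncated / not a bundle
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(bundle, dict) or "format_version" not in bundle:
        raise ValueError(f"{path} is not a hostsieve model bundle")
    if bundle["format_version"] != _MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model bundle version {bundle['format_version']!r}"
        )
    params = StandardizationParams(
        mean=bundle["standardization_mean"],
        std=bundle["standardization_std"],
        feature_names=tuple(bundle["standardization_names"]),
    )
    return TrainedModel(
        hyperparameters=bundle["hyperparameters"],
        estimator=bundle["estimator"],
        standardization=params,
        feature_names=tuple(bundle["feature_names"]),
        classes=tuple(bundle["classes"]),
        seed=bundle["seed"],
    )
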