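"""Maximum-likelihood discriminant (MLHD) classification.

A Gaussian discriminant with class-specific means and a single pooled
within-class covariance — the fitness engine of the genetic-algorithm
selector.  Error estimation is two-level: an inner k-fold cross-validation
(default k = 5) scores candidate gene subsets during search, and an outer
estimate over repeated random splits (default 40 splits, 2/3 training)
gives the final accuracy of selected models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.model_selection import KFold, StratifiedKFold, StratifiedShuffleSplit

from .datasets import ExpressionDataset


class FitError(ValueError):
    """The discriminant cannot be fitted on the given data."""


@dataclass(frozen=True)
class CVConfig:
    """Resampling settings for the two-level error estimation.

    ``inner_k`` folds score subsets during search; ``outer_splits`` random
    ``train_fraction`` splits estimate the final accuracy.
    """

    inner_k: int = 5
    outer_splits: int = 40
    train_fraction: float = 2.0 / 3.0
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_k < 2:
            raise ValueError("inner_k must be >= 2")
        if self.outer_splits < 1:
            raise ValueError("outer_splits must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class MLHDModel:
    """Fitted discriminant over a gene subset.

    ``class_means`` is (n_classes, p); ``pooled_covariance`` the within-class
    covariance pooled with denominator (n - n_classes), after adding
    ``ridge`` to the diagonal where needed for invertibility.
    """

    genes: list[int]
    classes: np.ndarray
    class_means: np.ndarray
    pooled_covariance: np.ndarray
    priors: np.ndarray
    ridge: float

    def __post_init__(self) -> None:
        if abs(float(self.priors.sum()) - 1.0) > 1e-12:
            raise ValueError("priors must sum to 1")


def _regularised_cholesky(cov: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factor of cov, escalating a trace-scaled ridge until SPD.

    Ridge starts at 1e-6 * trace/p and multiplies by 10; p can approach the
    training-fold size, so exact singularity is routine rather than
    exceptional.
    """
    p = cov.shape[0]
    scale = max(float(np.trace(cov)) / p, np.finfo(float).tiny)
    ridge = 0.0
    eps = 1e-6
    while True:
        try:
            chol = linalg.cholesky(cov + ridge * np.eye(p), lower=True)
            return chol, ridge
        except linalg.LinAlgError:
            ridge = eps * scale
            eps *= 10.0
            if eps > 1e12:
                raise FitError("pooled covariance could not be regularised to SPD")


def fit_mlhd(
    ds: ExpressionDataset,
    endpoint: str,
    genes,
    priors: str = "empirical",
) -> MLHDModel:
    """Fit the discriminant on ``ds`` restricted to ``genes``.

    ``priors`` is ``"empirical"`` (training class frequencies) or
    ``"equal"``.  Every class needs at least 2 samples.
    """
    genes = list(genes)
    if not genes:
        raise FitError("gene subset is empty")
    if len(set(genes)) != len(genes):
        raise FitError(f"duplicate gene index in subset {genes}")
    y = ds.endpoint(endpoint)
    x = ds.matrix[:, genes]
    return _fit_arrays(x, y, genes, priors)


def _fit_arrays(x: np.ndarray, y: np.ndarray, genes, priors: str) -> MLHDModel:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise FitError("need at least two classes")
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise FitError(f"class {small} has fewer than 2 samples")
    n, p = x.shape
    means = np.vstack([x[y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((p, p))
    for c, mu in zip(classes, means):
        d = x[y == c] - mu
        pooled += d.T @ d
    pooled /= n - len(classes)
    pooled = (pooled + pooled.T) / 2.0
    _, ridge = _regularised_cholesky(pooled)
    if priors == "equal":
        pri = np.full(len(classes), 1.0 / len(classes))
    elif priors == "empirical":
        pri = counts / n
    else:
        raise ValueError("priors must be 'empirical' or 'equal'")
    return MLHDModel(
        genes=list(genes),
        classes=classes,
        class_means=means,
        pooled_covariance=pooled + ridge * np.eye(p),
        priors=pri,
        ridge=ridge,
    )


def predict_mlhd(model: MLHDModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and per-class discriminant scores for rows of ``x``.

    Score of class c at x is  x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + log prior_c;
    the predicted label is the argmax, ties resolved to the lowest class index.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    p = len(model.genes)
    if x.shape[1] != p:
        raise ValueError(f"expected {p} columns (model genes), got {x.shape[1]}")
    chol = linalg.cholesky(model.pooled_covariance, lower=True)
    alpha = linalg.cho_solve((chol, True), model.class_means.T)  # (p, n_classes)
    scores = x @ alpha - 0.5 * np.sum(model.class_means.T * alpha, axis=0) + np.log(model.priors)
    labels = model.classes[np.argmax(scores, axis=1)]  # argmax takes lowest index on ties
    return labels, scores


def _fold_accuracy(x, y, train, test, priors: str) -> float:
    model = _fit_arrays(x[train], y[train], genes=range(x.shape[1]), priors=priors)
    pred, _ = predict_mlhd(model, x[test])
    return float(np.mean(pred == y[test]))


def _check_train_classes(y, splits) -> bool:
    return all(len(np.unique(y[tr])) == len(np.unique(y)) for tr, _ in splits)


def inner_cv_accuracy(
    ds: ExpressionDataset,
    endpoint: str,
    genes,
    cv: CVConfig,
    priors: str = "empirical",
) -> float:
    """Mean k-fold test accuracy of the MLHD on the given gene subset."""
    genes = list(genes)
    y = ds.endpoint(endpoint)
    x = ds.matrix[:, genes]
    n = len(y)
    if n < cv.inner_k:
        raise FitError(f"n_samples={n} smaller than inner_k={cv.inner_k}")
    if cv.inner_k == n:  # leave-one-out
        splits = list(KFold(n_splits=n).split(x, y))
    elif cv.stratified:
        splits = list(
            StratifiedKFold(cv.inner_k, shuffle=True, random_state=cv.seed).split(x, y)
        )
        if not _check_train_classes(y, splits):
            splits = list(
                StratifiedKFold(cv.inner_k, shuffle=True, random_state=cv.seed + 1).split(x, y)
            )
    else:
        splits = list(KFold(cv.inner_k, shuffle=True, random_state=cv.seed).split(x, y))
    if not _check_train_classes(y, splits):
        raise FitError("a class is absent from a training fold; reduce inner_k")
    return float(np.mean([_fold_accuracy(x, y, tr, te, priors) for tr, te in splits]))


def outer_accuracy(
    ds: ExpressionDataset,
    endpoint: str,
    genes,
    cv: CVConfig,
    priors: str = "empirical",
) -> tuple[float, np.ndarray]:
    """Mean and per-split accuracy over repeated stratified random splits."""
    genes = list(genes)
    y = ds.endpoint(endpoint)
    x = ds.matrix[:, genes]
    splitter = StratifiedShuffleSplit(
        n_splits=cv.outer_splits, train_size=cv.train_fraction, random_state=cv.seed
    )
    accs = np.array(
        [_fold_accuracy(x, y, tr, te, priors) for tr, te in splitter.split(x, y)]
    )
    return float(accs.mean()), accs
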