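"""Fisher linear discriminant analysis from scratch.

Given labeled samples, the between-class scatter M_Q and within-class
scatter M_Y are formed, and the discriminant directions are the leading
eigenvectors of the generalized eigenproblem

    M_Q y = lambda (M_Y + eps I) y,

which maximize the Fisher criterion |Y' M_Q Y| / |Y' M_Y Y| — the ratio of
between- to within-class scatter of the projected data.  Classification is
by nearest projected class centroid.  A small ridge eps keeps M_Y
positive-definite on ill-conditioned clinical data with correlated
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "LabeledDataset",
    "ScatterMatrices",
    "LDAModel",
    "compute_scatter",
    "fisher_criterion",
    "fit_lda",
    "project",
    "predict",
]


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix ``X`` (n_samples x n_dims) with integer class labels
    ``y``; every class must have at least one sample and there must be at
    least two classes."""

    X: np.ndarray
    y: np.ndarray
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if y.shape != (X.shape[0],):
            raise ValueError("y must have one label per row of X")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite entries")
        if np.unique(y).size < 2:
            raise ValueError("need at least two classes")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class ScatterMatrices:
    between: np.ndarray       # M_Q: count-weighted between-class scatter
    within: np.ndarray        # M_Y: sum of per-class scatters O_j
    class_means: np.ndarray   # R x n_dims
    grand_mean: np.ndarray
    class_counts: np.ndarray
    classes: np.ndarray


@dataclass
class LDAModel:
    projection: np.ndarray        # n_dims x d, eigenvector columns
    eigenvalues: np.ndarray       # length d, descending
    centroids: np.ndarray         # R x d, projected class means
    classes: np.ndarray
    ridge: float
    n_features: int


def compute_scatter(data: LabeledDataset) -> ScatterMatrices:
    """Between-class, within-class scatter matrices and class statistics.

    With o_j the mean of class j (n_j samples) and o the grand mean:
    within M_Y = sum_j O_j where O_j = sum_{z in class j} (z-o_j)(z-o_j)',
    between M_Q = sum_j n_j (o_j-o)(o_j-o)'.  The count weighting makes
    M_Q + M_Y equal the total scatter about o.
    """
    X, y = data.X, data.y
    classes = data.classes
    d = X.shape[1]
    grand_mean = X.mean(axis=0)

    between = np.zeros((d, d))
    within = np.zeros((d, d))
    means = np.empty((classes.size, d))
    counts = np.empty(classes.size, dtype=int)
    for j, c in enumerate(classes):
        Xc = X[y == c]
        if Xc.shape[0] == 0:
            raise ValueError(f"class {c!r} has no samples")
        mu = Xc.mean(axis=0)
        means[j] = mu
        counts[j] = Xc.shape[0]
        centered = Xc - mu
        within += centered.T @ centered
        diff = (mu - grand_mean)[:, None]
        between += counts[j] * (diff @ diff.T)

    # enforce exact symmetry against floating-point drift
    between = (between + between.T) / 2.0
    within = (within + within.T) / 2.0
    return ScatterMatrices(
        between=between,
        within=within,
        class_means=means,
        grand_mean=grand_mean,
        class_counts=counts,
        classes=classes,
    )


def fisher_criterion(Y: np.ndarray, scatter: ScatterMatrices, ridge: float = 0.0) -> float:
    """Determinant-ratio Fisher criterion |Y' M_Q Y| / |Y' (M_Y + eps I) Y|."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != scatter.within.shape[0]:
        Y = Y.T
    num = np.linalg.det(Y.T @ scatter.between @ Y)
    den_mat = Y.T @ (scatter.within + ridge * np.eye(scatter.within.shape[0])) @ Y
    den = np.linalg.det(den_mat)
    if den == 0.0:
        cond = np.linalg.cond(den_mat)
        raise np.linalg.LinAlgError(
            f"singular within-class projection (condition number {cond:.3e}); "
            "add a ridge term"
        )
    return float(num / den)


def _default_ridge(within: np.ndarray) -> float:
    tr = float(np.trace(within))
    d = within.shape[0]
    if tr <= 0.0:
        return 1e-6
    return 1e-6 * tr / d


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    """Sign convention: first component of magnitude > 1e-12 is positive."""
    for x in vec:
        if abs(x) > 1e-12:
            return vec if x > 0 else -vec
    return vec


def fit_lda(data: LabeledDataset, ridge: float | None = None) -> LDAModel:
    """Fit the discriminant projection by solving the generalized
    eigenproblem M_Q y = lambda (M_Y + ridge I) y.

    Keeps the d = min(R-1, rank M_Q) leading eigenvectors (floored at one
    direction when class means coincide), each unit-normalized with its
    first nonzero component positive; eigenvalues are sorted descending.
    """
    R = data.classes.size
    if data.X.shape[0] <= R:
        raise ValueError("need more samples than classes")
    scatter = compute_scatter(data)
    eps = _default_ridge(scatter.within) if ridge is None else float(ridge)
    regularized = scatter.within + eps * np.eye(data.n_features)

    eigvals, eigvecs = scipy.linalg.eigh(scatter.between, regularized)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    bvals = np.linalg.eigvalsh(scatter.between)
    tol = max(abs(bvals).max(), 1.0) * 1e-9
    rank = int(np.sum(bvals > tol))
    d = min(R - 1, rank) if rank > 0 else 1

    W = np.empty((data.n_features, d))
    lams = np.empty(d)
    for j in range(d):
        v = eigvecs[:, j]
        v = v / np.linalg.norm(v)
        W[:, j] = _fix_sign(v)
        lams[j] = max(eigvals[j], 0.0)

    centroids = scatter.class_means @ W
    return LDAModel(
        projection=W,
        eigenvalues=lams,
        centroids=centroids,
        classes=scatter.classes,
        ridge=eps,
        n_features=data.n_features,
    )


def project(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Map samples into the discriminant space: X @ Y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    return X @ model.projection


def predict(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Nearest projected class centroid; ties go to the lowest class index."""
    if model.projection is None:  # defensive; dataclass always sets it
        raise RuntimeError("model is not fitted")
    Z = project(model, X)
    # squared Euclidean distance to each centroid
    d2 = ((Z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    # argmin returns the first (lowest-index) class on exact ties
    return model.classes[np.argmin(d2, axis=1)]
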