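"""Feature transformation: PCA dimension reduction, then Z-score normalization.

The pipeline applies PCA to the raw feature table first and standardizes the
principal-component scores afterwards (scores of different components can
differ by orders of magnitude, which is exactly the situation Z-scoring is
meant to fix). Both transforms are *fitted* on training data and *applied*
frozen to held-out data, so no information leaks from the test split.

Conventions
-----------
* The standard deviation is the **population** form (divide by ``n``), for
  both Z-scoring and the PCA covariance.
* Eigenvectors are sign-fixed so that the loading of largest magnitude is
  positive, making outputs reproducible across linear-algebra backends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import (
    DegenerateCovariance,
    DimensionMismatch,
    FeatureMatrix,
    SvmSwarmError,
    ZeroVarianceColumn,
)

__all__ = [
    "StandardizationParams",
    "PCAModel",
    "zscore_fit",
    "zscore_apply",
    "zscore_invert",
    "pca_fit",
    "pca_transform",
    "preprocess_fit",
    "preprocess_apply",
]


@dataclass
class StandardizationParams:
    """Per-column mean and population standard deviation.

    ``kept`` marks columns with nonzero variance; dropped columns are
    removed by :func:`zscore_apply` rather than divided by zero.
    """

    means: np.ndarray
    sds: np.ndarray
    kept: np.ndarray  # boolean mask over the original columns
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.kept = np.asarray(self.kept, dtype=bool)
        if not (self.means.shape == self.sds.shape == self.kept.shape):
            raise DimensionMismatch("standardization parameter lengths differ")
        if np.any(self.sds < 0):
            raise SvmSwarmError("standard deviations must be nonnegative")


@dataclass
class PCAModel:
    """Eigendecomposition of the (population) covariance of training data.

    Attributes
    ----------
    component_matrix : (d, k) ndarray
        Orthonormal columns; the retained principal axes.
    eigenvalues : (k,) ndarray
        Variance along each retained axis, nonincreasing.
    column_means : (d,) ndarray
        Training-column means used for centering.
    variance_retained : float
        Fraction of total variance carried by the ``k`` retained axes.
    """

    component_matrix: np.ndarray
    eigenvalues: np.ndarray
    column_means: np.ndarray
    variance_retained: float

    def __post_init__(self) -> None:
        W = np.asarray(self.component_matrix, dtype=float)
        gram = W.T @ W
        if not np.allclose(gram, np.eye(W.shape[1]), atol=1e-8):
            raise SvmSwarmError("component columns must be orthonormal")
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-12):
            raise SvmSwarmError("eigenvalues must be nonincreasing")
        self.component_matrix = W
        self.eigenvalues = ev

    @property
    def k(self) -> int:
        return self.component_matrix.shape[1]


def zscore_fit(X: FeatureMatrix, on_zero_variance: str = "drop") -> StandardizationParams:
    """Fit per-column mean and population SD  (``s = sqrt(sum (x-mean)^2 / n)``).

    Parameters
    ----------
    X : FeatureMatrix
        Training data; needs at least two rows.
    on_zero_variance : {"drop", "raise"}
        A constant column has ``s = 0`` and no Z-score. ``"drop"`` flags it
        for removal with a warning; ``"raise"`` raises
        :class:`ZeroVarianceColumn` naming the offending column(s).
    """
    if X.n < 2:
        raise SvmSwarmError("zscore_fit needs at least 2 rows")
    means = X.values.mean(axis=0)
    sds = X.values.std(axis=0)  # population convention (ddof=0)
    zero = sds == 0
    if zero.any():
        bad = [X.feature_names[j] for j in np.flatnonzero(zero)]
        if on_zero_variance == "raise":
            raise ZeroVarianceColumn(bad)
        warnings.warn(
            f"dropping zero-variance column(s): {', '.join(bad)}", UserWarning
        )
    return StandardizationParams(
        means=means, sds=sds, kept=~zero, feature_names=list(X.feature_names)
    )


def zscore_apply(X: FeatureMatrix, p: StandardizationParams) -> FeatureMatrix:
    """Standardize columns: ``z = (x - mean) / s``; labels pass through."""
    if X.d != p.means.shape[0]:
        raise DimensionMismatch(
            f"data has {X.d} columns, params expect {p.means.shape[0]}"
        )
    keep = np.flatnonzero(p.kept)
    Z = (X.values[:, keep] - p.means[keep]) / p.sds[keep]
    names = [p.feature_names[j] for j in keep]
    return X.with_values(Z, feature_names=names)


def zscore_invert(Z: FeatureMatrix, p: StandardizationParams) -> FeatureMatrix:
    """Undo :func:`zscore_apply` (kept columns only): ``x = z * s + mean``."""
    keep = np.flatnonzero(p.kept)
    if Z.d != keep.size:
        raise DimensionMismatch("standardized data width does not match params")
    Xv = Z.values * p.sds[keep] + p.means[keep]
    return Z.with_values(Xv, feature_names=[p.feature_names[j] for j in keep])


def pca_fit(
    X: FeatureMatrix,
    variance_threshold: float = 0.95,
    n_components: int | None = None,
) -> PCAModel:
    """Eigendecompose the column-centered population covariance.

    The number of retained components ``k`` is either given directly
    (``n_components``) or chosen as the smallest count of leading components
    whose eigenvalue sum reaches ``variance_threshold`` of the total
    variance.
    """
    if X.n < 2:
        raise SvmSwarmError("pca_fit needs at least 2 rows")
    if n_components is None and not (0 < variance_threshold <= 1):
        raise SvmSwarmError("variance_threshold must lie in (0, 1]")
    mu = X.values.mean(axis=0)
    Xc = X.values - mu
    cov = (Xc.T @ Xc) / X.n  # population convention
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise DegenerateCovariance("all eigenvalues are zero")
    if n_components is not None:
        if not 1 <= n_components <= X.d:
            raise SvmSwarmError("n_components out of range")
        k = int(n_components)
    else:
        cum = np.cumsum(evals) / total
        k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
        k = min(k, X.d)
    W = evecs[:, :k].copy()
    # sign convention: the largest-magnitude loading of each axis is positive
    flip = W[np.abs(W).argmax(axis=0), np.arange(k)] < 0
    W[:, flip] *= -1.0
    return PCAModel(
        component_matrix=W,
        eigenvalues=evals[:k],
        column_means=mu,
        variance_retained=float(evals[:k].sum() / total),
    )


def pca_transform(X: FeatureMatrix, m: PCAModel) -> FeatureMatrix:
    """Project centered data onto the retained axes; labels pass through."""
    if X.d != m.column_means.shape[0]:
        raise DimensionMismatch(
            f"data has {X.d} columns, PCA model expects {m.column_means.shape[0]}"
        )
    scores = (X.values - m.column_means) @ m.component_matrix
    return X.with_values(scores, feature_names=[f"PC{j + 1}" for j in range(m.k)])


def preprocess_fit(
    X: FeatureMatrix,
    variance_threshold: float = 0.95,
    n_components: int | None = None,
) -> tuple[PCAModel, StandardizationParams]:
    """Fit the full chain on training data: PCA first, Z-score on the scores."""
    pca = pca_fit(X, variance_threshold, n_components)
    scores = pca_transform(X, pca)
    std = zscore_fit(scores)
    return pca, std


def preprocess_apply(
    X: FeatureMatrix, pca: PCAModel, std: StandardizationParams
) -> FeatureMatrix:
    """Apply a fitted PCA + Z-score chain to new data."""
    return zscore_apply(pca_transform(X, pca), std)
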