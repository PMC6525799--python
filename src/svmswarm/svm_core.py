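"""Kernel SVM trained by solving its dual quadratic program.

The binary soft-margin SVM is trained in its dual form::

    max_a  sum_i a_i - 1/2 a' Q a,   Q_ij = y_i y_j K(x_i, x_j)
    s.t.   0 <= a_i <= C,  sum_i a_i y_i = 0

and classifies with ``f(x) = sum_i a_i y_i K(x_i, x) + b``, the sign of
``f`` giving the class (an exact zero maps to +1).

Kernels
-------
gaussian    ``K(x, y) = exp(-||x - y||^2 / phi^2)``  — width ``phi``; the
            hyperparameter exposed to optimizers is ``gamma = 1 / phi^2``.
polynomial  ``K(x, y) = (x . y + a)^b``
linear      ``K(x, y) = x . y``

Solver
------
A sequential-minimal-optimization (SMO) coordinate ascent with
maximal-violating-pair working-set selection: at each step the pair of
multipliers most violating the KKT conditions is updated analytically.
Selection is deterministic, so training is invariant to permutations of the
training rows (up to exact fitness ties). The inner loop is JIT-compiled
with numba when available and falls back to pure numpy otherwise.

Numerical constants (module level, not per call site): multipliers below
``ALPHA_EPS`` are treated as zero; the solver stops when the maximal KKT
violation falls below ``STOP_TOL`` (well inside the ``KKT_TOL`` guarantee
stated for trained models); the pair-update budget is
``MAX_UPDATES_PER_ROW * n + MAX_UPDATES_BASE``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import (
    DimensionMismatch,
    FeatureMatrix,
    NoConvergenceWarning,
    NonPositivePhi,
    SingleClassInput,
    SvmSwarmError,
)

__all__ = [
    "KernelSpec",
    "SVMModel",
    "kernel_eval",
    "kernel_matrix",
    "gram_matrix",
    "svm_train",
    "svm_train_from_kernel",
    "decision_value",
    "decision_values",
    "svm_predict",
    "model_to_json",
    "model_from_json",
    "ALPHA_EPS",
    "KKT_TOL",
    "STOP_TOL",
]

ALPHA_EPS = 1e-8     # multipliers below this are dropped from the model
KKT_TOL = 1e-3       # KKT satisfaction guaranteed for returned models
STOP_TOL = 1e-6      # solver's internal stopping tolerance (stricter)
MAX_UPDATES_PER_ROW = 10
MAX_UPDATES_BASE = 1_000


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus parameters.

    ``phi`` is the Gaussian width; ``a`` (offset) and ``b`` (integer degree
    >= 1) parameterize the polynomial kernel.
    """

    family: str = "gaussian"
    phi: float | None = 1.0
    a: float = 1.0
    b: int = 3

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "polynomial", "linear"):
            raise SvmSwarmError(f"unknown kernel family {self.family!r}")
        if self.family == "gaussian":
            if self.phi is None or self.phi <= 0:
                raise NonPositivePhi("gaussian width phi must be > 0")
        if self.family == "polynomial":
            if int(self.b) != self.b or self.b < 1:
                raise SvmSwarmError("polynomial degree b must be an integer >= 1")

    @property
    def gamma(self) -> float:
        """Gaussian exponent coefficient ``1 / phi^2``."""
        if self.family != "gaussian":
            raise SvmSwarmError("gamma is defined for the gaussian kernel only")
        return 1.0 / (self.phi * self.phi)

    @staticmethod
    def gaussian_from_gamma(gamma: float) -> "KernelSpec":
        """Construct a Gaussian kernel from ``gamma = 1 / phi^2``."""
        if gamma <= 0:
            raise NonPositivePhi("gamma must be > 0")
        return KernelSpec(family="gaussian", phi=float(1.0 / np.sqrt(gamma)))


def kernel_eval(k: KernelSpec, x: np.ndarray, y: np.ndarray) -> float:
    """Evaluate ``K(x, y)`` for a single pair of vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise DimensionMismatch("kernel arguments differ in dimension")
    if k.family == "gaussian":
        d2 = float(np.sum((x - y) ** 2))
        return float(np.exp(-d2 / (k.phi * k.phi)))
    if k.family == "polynomial":
        return float((x @ y + k.a) ** k.b)
    return float(x @ y)


def kernel_matrix(k: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Cross-kernel matrix ``K[i, j] = K(A_i, B_j)`` (vectorized)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise DimensionMismatch("kernel arguments differ in dimension")
    if k.family == "gaussian":
        d2 = (
            np.sum(A * A, axis=1)[:, None]
            + np.sum(B * B, axis=1)[None, :]
            - 2.0 * (A @ B.T)
        )
        np.clip(d2, 0.0, None, out=d2)
        return np.exp(-d2 / (k.phi * k.phi))
    if k.family == "polynomial":
        return (A @ B.T + k.a) ** k.b
    return A @ B.T


def gram_matrix(k: KernelSpec, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Symmetric (unweighted) Gram matrix of the rows of ``X``."""
    V = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    K = kernel_matrix(k, V, V)
    return 0.5 * (K + K.T)  # symmetrize away floating-point asymmetry


# --------------------------------------------------------------------------
# SMO solver (maximal violating pair)

def _smo_numpy(K, y, C, tol, max_iter):
    n = y.shape[0]
    alpha = np.zeros(n)
    grad = -np.ones(n)  # gradient of 1/2 a'Qa - e'a
    Q = (y[:, None] * y[None, :]) * K
    it = 0
    obj = 0.0  # running dual objective (sum a - 1/2 a'Qa)
    gap = np.inf
    while it < max_iter:
        yg = -y * grad
        up = ((alpha < C) & (y > 0)) | ((alpha > 0) & (y < 0))
        low = ((alpha < C) & (y < 0)) | ((alpha > 0) & (y > 0))
        if not up.any() or not low.any():
            gap = 0.0
            break
        i = int(np.argmax(np.where(up, yg, -np.inf)))
        m = yg[i]
        M = np.min(np.where(low, yg, np.inf))
        gap = m - M
        if gap < tol:
            break
        # second-order selection of j: maximal gain against i
        diff = m - yg
        quads = np.maximum(K[i, i] + np.diag(K) - 2.0 * K[:, i], 1e-12)
        gains = np.where(low & (diff > 0), diff * diff / quads, -np.inf)
        j = int(np.argmax(gains))
        if not np.isfinite(gains[j]):
            break
        quad = max(K[i, i] + K[j, j] - 2.0 * K[i, j], 1e-12)
        step = (m - yg[j]) / quad
        di = C - alpha[i] if y[i] > 0 else alpha[i]
        dj = alpha[j] if y[j] > 0 else C - alpha[j]
        step = min(step, di, dj)
        improvement = step * (m - yg[j]) - 0.5 * step * step * quad
        alpha[i] += y[i] * step
        alpha[j] -= y[j] * step
        grad += step * (y[i] * Q[:, i] - y[j] * Q[:, j])
        obj += improvement
        it += 1
        # stagnation: box-clamped micro-steps on an ill-conditioned dual
        if improvement <= 1e-9 * (1.0 + abs(obj)):
            break
    return alpha, grad, it, gap


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True)
    def _smo_numba(K, y, C, tol, max_iter):  # pragma: no cover
        n = y.shape[0]
        alpha = np.zeros(n)
        grad = -np.ones(n)
        it = 0
        obj = 0.0
        gap = np.inf
        while it < max_iter:
            # i: maximal violator in I_up
            m = -np.inf
            M = np.inf
            i = -1
            for t in range(n):
                ygt = -y[t] * grad[t]
                if (alpha[t] < C and y[t] > 0) or (alpha[t] > 0 and y[t] < 0):
                    if ygt > m:
                        m = ygt
                        i = t
                if (alpha[t] < C and y[t] < 0) or (alpha[t] > 0 and y[t] > 0):
                    if ygt < M:
                        M = ygt
            if i < 0:
                gap = 0.0
                break
            gap = m - M
            if gap < tol:
                break
            # j: second-order selection — maximal objective gain against i
            j = -1
            best_gain = -np.inf
            for t in range(n):
                if (alpha[t] < C and y[t] < 0) or (alpha[t] > 0 and y[t] > 0):
                    ygt = -y[t] * grad[t]
                    diff = m - ygt
                    if diff > 0:
                        quad = K[i, i] + K[t, t] - 2.0 * K[i, t]
                        if quad < 1e-12:
                            quad = 1e-12
                        gain = diff * diff / quad
                        if gain > best_gain:
                            best_gain = gain
                            j = t
            if j < 0:
                break
            quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
            if quad < 1e-12:
                quad = 1e-12
            diff_ij = m - (-y[j] * grad[j])
            step = diff_ij / quad
            di = C - alpha[i] if y[i] > 0 else alpha[i]
            dj = alpha[j] if y[j] > 0 else C - alpha[j]
            if di < step:
                step = di
            if dj < step:
                step = dj
            improvement = step * diff_ij - 0.5 * step * step * quad
            alpha[i] += y[i] * step
            alpha[j] -= y[j] * step
            # d(grad)_t = Q_ti * da_i + Q_tj * da_j = step * y_t * (K_ti - K_tj)
            for t in range(n):
                grad[t] += step * y[t] * (K[t, i] - K[t, j])
            obj += improvement
            it += 1
            # stagnation: box-clamped micro-steps on an ill-conditioned dual
            if improvement <= 1e-9 * (1.0 + abs(obj)):
                break
        return alpha, grad, it, gap

    _SMO = _smo_numba
except ImportError:  # pragma: no cover
    _SMO = _smo_numpy


@dataclass
class SVMModel:
    """Trained dual solution (only vectors with ``alpha > ALPHA_EPS`` kept)."""

    support_vectors: np.ndarray
    alphas: np.ndarray
    sv_labels: np.ndarray
    bias: float
    C: float
    kernel: KernelSpec
    feature_names: list[str] = field(default_factory=list)
    converged: bool = True
    dual_objective: float = float("nan")

    @property
    def n_support(self) -> int:
        return self.alphas.shape[0]


def svm_train_from_kernel(
    K: np.ndarray, y: np.ndarray, C: float
) -> tuple[np.ndarray, float, bool, float]:
    """Solve the dual on a precomputed (unweighted) kernel matrix.

    Returns ``(alpha, bias, converged, dual_objective)`` over *all* training
    rows. This is the fast path used by cross-validation fitness functions,
    where the squared-distance matrix is cached and only re-exponentiated.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if C <= 0:
        raise SvmSwarmError("C must be positive")
    if np.all(y > 0) or np.all(y < 0):
        raise SingleClassInput("training data contain a single class")
    max_iter = MAX_UPDATES_PER_ROW * n + MAX_UPDATES_BASE
    alpha, grad, it, gap = _SMO(
        np.ascontiguousarray(K, dtype=float), y, float(C), STOP_TOL, max_iter
    )
    converged = bool(gap < KKT_TOL)
    if not converged:
        warnings.warn(
            f"SMO stopped with KKT gap {gap:.2e}; returning best iterate",
            NoConvergenceWarning,
        )
    # dual objective: sum a - 1/2 a'Qa ; grad = Qa - e  =>  a'Qa = a'(grad + e)
    dual_obj = float(alpha.sum() - 0.5 * (alpha @ (grad + 1.0)))
    # bias averaged over free support vectors; -y*grad equals y - sum a y K
    yg = -y * grad
    free = (alpha > ALPHA_EPS) & (alpha < C - ALPHA_EPS)
    if free.any():
        bias = float(yg[free].mean())
    else:
        up = ((alpha < C) & (y > 0)) | ((alpha > 0) & (y < 0))
        low = ((alpha < C) & (y < 0)) | ((alpha > 0) & (y > 0))
        hi = yg[up].max() if up.any() else 0.0
        lo = yg[low].min() if low.any() else 0.0
        bias = float(0.5 * (hi + lo))
    return alpha, bias, converged, dual_obj


def svm_train(X: FeatureMatrix, C: float, kernel: KernelSpec) -> SVMModel:
    """Train a kernel SVM on labeled data by solving the dual problem.

    Raises :class:`SingleClassInput` when only one class is present; emits
    :class:`NoConvergenceWarning` (and flags the model) if the pair-update
    budget runs out before the KKT gap closes.
    """
    K = gram_matrix(kernel, X)
    alpha, bias, converged, dual_obj = svm_train_from_kernel(K, X.labels, C)
    sv = alpha > ALPHA_EPS
    return SVMModel(
        support_vectors=X.values[sv].copy(),
        alphas=alpha[sv].copy(),
        sv_labels=X.labels[sv].astype(float),
        bias=bias,
        C=float(C),
        kernel=kernel,
        feature_names=list(X.feature_names),
        converged=converged,
        dual_objective=dual_obj,
    )


def decision_values(m: SVMModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Decision scores ``f(x) = sum_i a_i y_i K(x_i, x) + b`` for each row."""
    V = X.values if isinstance(X, FeatureMatrix) else np.atleast_2d(
        np.asarray(X, dtype=float)
    )
    if V.shape[1] != m.support_vectors.shape[1]:
        raise DimensionMismatch("input dimension does not match the model")
    K = kernel_matrix(m.kernel, V, m.support_vectors)
    return K @ (m.alphas * m.sv_labels) + m.bias


def decision_value(m: SVMModel, x: np.ndarray) -> float:
    """Decision score of a single vector."""
    return float(decision_values(m, np.atleast_2d(np.asarray(x, dtype=float)))[0])


def svm_predict(m: SVMModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Predicted labels: sign of the decision value, exact zero mapped to +1."""
    f = decision_values(m, X)
    return np.where(f >= 0.0, 1, -1)


# --------------------------------------------------------------------------
# serialization

def model_to_json(m: SVMModel) -> str:
    """Serialize a model to JSON; floats round-trip exactly (shortest repr)."""
    doc = {
        "support_vectors": m.support_vectors.tolist(),
        "alphas": m.alphas.tolist(),
        "sv_labels": m.sv_labels.tolist(),
        "bias": m.bias,
        "C": m.C,
        "kernel": {
            "family": m.kernel.family,
            "phi": m.kernel.phi,
            "a": m.kernel.a,
            "b": m.kernel.b,
        },
        "feature_names": m.feature_names,
        "converged": m.converged,
        "dual_objective": m.dual_objective,
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def model_from_json(doc: str) -> SVMModel:
    """Inverse of :func:`model_to_json`."""
    d = json.loads(doc)
    kd = d["kernel"]
    return SVMModel(
        support_vectors=np.asarray(d["support_vectors"], dtype=float),
        alphas=np.asarray(d["alphas"], dtype=float),
        sv_labels=np.asarray(d["sv_labels"], dtype=float),
        bias=float(d["bias"]),
        C=float(d["C"]),
        kernel=KernelSpec(family=kd["family"], phi=kd["phi"], a=kd["a"], b=kd["b"]),
        feature_names=list(d["feature_names"]),
        converged=bool(d["converged"]),
        dual_objective=float(d["dual_objective"]),
    )
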