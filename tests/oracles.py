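"""Independent reference computations used to check the package's own paths.

These stay deliberately naive (generic QP, log-log tail regression) so they
share no code with the implementations they audit.
"""

import numpy as np
from scipy import optimize


def qp_dual_solve(K: np.ndarray, y: np.ndarray, C: float):
    """Solve the SVM dual with a generic constrained QP (SLSQP).

    Returns (alpha, dual_objective) for max sum(a) - 1/2 a'Qa subject to
    0 <= a <= C and a.y = 0. Intended for small n only.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    Q = (y[:, None] * y[None, :]) * K

    res = optimize.minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.zeros(n),
        jac=lambda a: Q @ a - 1.0,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    return res.x, -res.fun


def tail_index_loglog(samples: np.ndarray, upper_quantile: float = 0.99) -> float:
    """Power-law tail exponent of |samples| by log-log CCDF regression.

    Fits log P(|X| > s) ~ -lam * log s over the upper tail (between the
    ``upper_quantile`` point and the 10th-largest value, to avoid extreme
    order-statistic noise); returns the estimated lam.
    """
    x = np.sort(np.abs(np.asarray(samples, dtype=float)))
    n = x.size
    lo = int(upper_quantile * n)
    hi = n - 10
    xs = x[lo:hi]
    ccdf = 1.0 - (np.arange(lo, hi) + 1) / n
    slope, _ = np.polyfit(np.log(xs), np.log(ccdf), 1)
    return -float(slope)


def random_svm_problem(rng: np.random.Generator, n_max: int = 30):
    """A small random Gaussian-kernel dual problem with both classes present."""
    n = int(rng.integers(6, n_max + 1))
    X = rng.normal(size=(n, 3))
    y = np.where(rng.uniform(size=n) < 0.5, 1.0, -1.0)
    if abs(y.sum()) == n:
        y[0] = -y[0]
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-0.7 * d2)
    return X, y, K
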