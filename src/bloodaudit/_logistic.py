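"""L2-penalized logistic regression by Newton's method.

Minimizes  sum_i log(1 + exp(-y_i (x_i.w + b))) + ||w||^2 / (2C)
with the intercept unpenalized — the same objective as
sklearn.linear_model.LogisticRegression(C=C). Kept in-house because the
bias audit refits this model tens of thousands of times on tiny design
matrices, where a dedicated warm-started Newton solve is far cheaper
than a general-purpose estimator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fit_logistic", "decision_values"]


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    w0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Fit; returns theta = [w_1..w_d, b]. ``y`` must be 0/1."""
    n, d = X.shape
    Xb = np.hstack([X, np.ones((n, 1))])
    t = np.asarray(y, dtype=float)
    theta = np.zeros(d + 1) if w0 is None else w0.copy()
    lam = 1.0 / C
    pen = np.full(d + 1, lam)
    pen[-1] = 0.0  # intercept unpenalized
    for _ in range(max_iter):
        z = Xb @ theta
        p = 1.0 / (1.0 + np.exp(-z))
        grad = Xb.T @ (p - t) + pen * theta
        if np.abs(grad).max() < tol:
            break
        w = p * (1.0 - p)
        H = (Xb * w[:, None]).T @ Xb
        H[np.diag_indices_from(H)] += pen
        step = np.linalg.solve(H, grad)
        # dampen in the rare ill-conditioned case
        if not np.all(np.isfinite(step)):
            break
        theta = theta - step
    return theta


def decision_values(X: np.ndarray, theta: np.ndarray) -> np.ndarray:
    return X @ theta[:-1] + theta[-1]
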