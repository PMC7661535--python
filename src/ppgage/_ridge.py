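"""Direct cross-validated ridge solvers used by the ranking procedure.

Small-p problems make generic grid-search machinery the bottleneck, so the
linear ridge path is computed from one SVD per fold (exact for every
penalty simultaneously) and the logistic ridge by IRLS Newton iterations
with warm starts along the penalty path.  Intercepts are unpenalized.
"""

from __future__ import annotations

import numpy as np

__all__ = ["linear_ridge_cv", "logistic_ridge_cv"]


def _folds(n: int, k: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    return np.array_split(idx, k)


def _ridge_path_svd(X, y, alphas):
    """Centered ridge coefficients for every alpha from one SVD."""
    xm, ym = X.mean(axis=0), y.mean()
    U, s, Vt = np.linalg.svd(X - xm, full_matrices=False)
    Uty = U.T @ (y - ym)
    coefs = [Vt.T @ (s / (s**2 + a) * Uty) for a in alphas]
    return coefs, xm, ym


def linear_ridge_cv(X, y, alphas, folds: int = 10,
                    rng: np.random.Generator | None = None):
    """Linear ridge with the penalty tuned by k-fold CV mean squared error.

    Returns ``(coef, intercept, best_alpha)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = rng or np.random.default_rng(0)
    n = X.shape[0]
    sse = np.zeros(len(alphas))
    for hold in _folds(n, folds, rng):
        mask = np.ones(n, dtype=bool)
        mask[hold] = False
        coefs, xm, ym = _ridge_path_svd(X[mask], y[mask], alphas)
        Xc = X[hold] - xm
        for i, coef in enumerate(coefs):
            resid = y[hold] - (Xc @ coef + ym)
            sse[i] += resid @ resid
    best = int(np.argmin(sse))
    coefs, xm, ym = _ridge_path_svd(X, y, alphas)
    coef = coefs[best]
    return coef, ym - xm @ coef, float(alphas[best])


def _logistic_ridge_fit(X, y, alpha, w0=None, max_iter: int = 50,
                        tol: float = 1e-8):
    """Newton/IRLS for L2-penalized logistic regression (intercept free)."""
    n, p = X.shape
    Xb = np.column_stack((np.ones(n), X))
    w = np.zeros(p + 1) if w0 is None else w0.copy()
    pen = np.full(p + 1, alpha)
    pen[0] = 0.0
    for _ in range(max_iter):
        eta = np.clip(Xb @ w, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = Xb.T @ (mu - y) + pen * w
        W = mu * (1.0 - mu) + 1e-10
        H = (Xb * W[:, None]).T @ Xb + np.diag(pen)
        step = np.linalg.solve(H, grad)
        w -= step
        if np.max(np.abs(step)) < tol:
            break
    return w


def _deviance(X, y, w):
    eta = np.clip(np.column_stack((np.ones(len(X)), X)) @ w, -30, 30)
    # -2 log-likelihood, numerically stable log(1 + e^eta)
    return 2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta)


def logistic_ridge_cv(X, y, alphas, folds: int = 10,
                      rng: np.random.Generator | None = None):
    """Logistic ridge with the penalty tuned by k-fold CV deviance.

    Returns ``(coef, intercept, best_alpha)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = rng or np.random.default_rng(0)
    n = X.shape[0]
    order = np.argsort(alphas)[::-1]  # strong penalty first for warm starts
    dev = np.zeros(len(alphas))
    for hold in _folds(n, folds, rng):
        mask = np.ones(n, dtype=bool)
        mask[hold] = False
        w = None
        for i in order:
            w = _logistic_ridge_fit(X[mask], y[mask], alphas[i], w0=w)
            dev[i] += _deviance(X[hold], y[hold], w)
    best = int(np.argmin(dev))
    w = None
    for i in order:
        w = _logistic_ridge_fit(X, y, alphas[i], w0=w)
        if i == best:
            break
    return w[1:], w[0], float(alphas[best])
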