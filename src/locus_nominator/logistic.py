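"""Logistic regression via iteratively reweighted least squares.

A small dedicated engine rather than a general GLM: a genome-wide scan
refits the same covariate block against thousands of single-variant
design columns, so each fit is warm-started from the covariate-only
solution and runs a handful of damped Newton steps on a tiny normal
system.  Agreement with statsmodels' Logit is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class FitError(RuntimeError):
    pass


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int

    def wald_p(self) -> np.ndarray:
        z = self.beta / self.se
        return 2 * stats.norm.sf(np.abs(z))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    start: np.ndarray | None = None,
    max_iter: int = 40,
    tol: float = 1e-8,
) -> LogisticFit:
    """Newton-Raphson (IRLS) fit of P(y=1) = logistic(X @ beta).

    ``X`` must include an intercept column if one is wanted.  Step-halving
    guards against overshoot; quasi-separation is reported as
    ``converged=False`` rather than raised, because a GWAS scan must keep
    going past pathological variants.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k) if start is None else np.array(start, dtype=float)

    def nll(b):
        eta = X @ b
        # log(1 + exp(eta)) - y*eta, stable form
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    prev = nll(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as err:
            raise FitError(f"singular information matrix: {err}") from err
        # damped update
        alpha = 1.0
        for _ in range(20):
            cand = beta + alpha * step
            cur = nll(cand)
            if cur <= prev + 1e-12:
                break
            alpha *= 0.5
        else:
            cand, cur = beta, prev
        delta = np.max(np.abs(cand - beta))
        beta, improved = cand, prev - cur
        prev = cur
        if delta < tol or improved < tol * (abs(prev) + 1.0) * 1e-4:
            converged = delta < tol or improved >= 0
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as err:
        raise FitError(f"singular information matrix at solution: {err}") from err
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    # flag quasi-separation: runaway coefficients or vanishing curvature
    if np.any(np.abs(beta) > 30) or np.any(se > 1e3):
        converged = False
    return LogisticFit(beta=beta, se=se, loglik=-prev, converged=converged, n_iter=it)


def drop_collinear(X: np.ndarray, names: list[str], tol: float = 1e-8):
    """Remove columns that are (numerically) linear combinations of earlier ones."""
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped
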