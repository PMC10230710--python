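"""Shared least-squares helpers used by the QTL and mediation engines."""

from __future__ import annotations

import numpy as np
from scipy import stats


def add_intercept(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Return a design matrix [1 | covariates] with shape (n, 1 + k)."""
    ones = np.ones((n, 1))
    if covariates is None:
        return ones
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise ValueError(f"covariates have {cov.shape[0]} rows, expected {n}")
    return np.hstack([ones, cov])


def ols_t_test(y: np.ndarray, design: np.ndarray, term: int) -> tuple[float, float, float, int]:
    """OLS fit of y on `design`; t-test for the coefficient at column `term`.

    Returns (beta, se, two-sided p, df). Raises LinAlgError-free: callers
    handle rank deficiency by checking matrix rank beforehand.
    """
    n, k = design.shape
    df = n - k
    if df <= 0:
        raise ValueError("not enough samples for the requested design")
    gram = design.T @ design
    ginv = np.linalg.inv(gram)
    coef = ginv @ (design.T @ y)
    resid = y - design @ coef
    sigma2 = float(resid @ resid) / df
    # an exact fit (residuals at round-off level) makes the t-test
    # meaningless; fall through to the deterministic convention below
    if sigma2 < 1e-12 * (float(y @ y) / len(y) + 1e-300):
        sigma2 = 0.0
    se = float(np.sqrt(max(sigma2 * ginv[term, term], 0.0)))
    beta = float(coef[term])
    if se == 0.0:
        # response exactly in the design span: p -> 0 for a genuinely
        # nonzero coefficient, 1 for one that is zero up to round-off
        scale = np.abs(coef).max() + 1.0
        return beta, se, (0.0 if abs(beta) > 1e-8 * scale else 1.0), df
    tstat = beta / se
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return beta, se, float(p), df


def residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of `values` on [intercept | covariates].

    The covariate design must be full rank; residuals are orthogonal to
    every covariate column to numerical precision.
    """
    values = np.asarray(values, dtype=float)
    design = add_intercept(covariates, values.shape[0])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ coef


def projection_complement(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Annihilator matrix M = I - D (D'D)^-1 D' for D = [1 | covariates]."""
    design = add_intercept(covariates, n)
    q, _ = np.linalg.qr(design)
    return np.eye(n) - q @ q.T
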