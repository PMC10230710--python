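"""Regression-based mediation comparator with a permutation/GEV null.

The mediation statistic for a triplet is the conditional p-value of
the variant coefficient in Y ~ X + Z_Y + M_residualized: complete
mediation drives this p toward 1 (X carries no signal once the
mediator is in the model). The null distribution of "how large can the
conditional p get by chance" is built by conditioning on random
off-chromosome decoy mediators: each of n_perm permutations
sample-index-shuffles the decoy set, records the maximum conditional
p-value across decoys, and a generalized extreme value distribution is
fitted to the n_perm maxima. The family-wise-error-controlled
mediation p-value is the upper-tail GEV probability of the observed
conditional p, significant below 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from qtlmed._ols import add_intercept, ols_t_test, residualize

log = logging.getLogger(__name__)

__all__ = [
    "GEVFit",
    "RegressionMediationResult",
    "conditional_pvalue",
    "residualize",
    "permutation_gev_fwer",
]


@dataclass
class GEVFit:
    """Maximum-likelihood GEV fit to permutation maxima.

    shape follows the scipy ``genextreme`` convention (c = -xi).
    """

    location: float
    scale: float
    shape: float
    n_samples: int
    ks_statistic: float

    def cdf(self, x: float) -> float:
        return float(stats.genextreme.cdf(x, self.shape, loc=self.location, scale=self.scale))


@dataclass
class RegressionMediationResult:
    triplet_id: str
    p_conditional_observed: float
    fwer_p: float
    significant: bool
    gev: GEVFit | None = None
    used_empirical_fallback: bool = False


def conditional_pvalue(
    y: np.ndarray,
    x: np.ndarray,
    covariates_zy: np.ndarray | None,
    m_residualized: np.ndarray,
    test_term: str = "x",
) -> float:
    """Two-sided p of the X (or M) coefficient in Y ~ X + Z_Y + M_resid.

    ``test_term="m"`` instead reports the mediator coefficient's p — an
    alternative reading of the mediation statistic kept behind this
    flag.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    m = np.asarray(m_residualized, dtype=float)
    base = add_intercept(covariates_zy, y.shape[0])
    design = np.hstack([base, x[:, None], m[:, None]])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        log.warning("collinear design in conditional test; degenerate p = 1")
        return 1.0
    term = design.shape[1] - (2 if test_term == "x" else 1)
    _, _, p, _ = ols_t_test(y, design, term)
    return p


def _conditional_p_matrix(
    y_r: np.ndarray, x_r: np.ndarray, q: np.ndarray, decoys: np.ndarray, df: int
) -> np.ndarray:
    """Conditional p of X for every decoy column, vectorized.

    y_r, x_r are the outcome and dosage residualized on the base design
    whose orthonormal basis is q; decoys has shape (..., n, d) and is
    residualized here. Returns p with shape (..., d).
    """
    qt_d = np.einsum("nk,...nd->...kd", q, decoys, optimize=True)
    d_r = decoys - np.einsum("nk,...kd->...nd", q, qt_d, optimize=True)
    a = float(x_r @ x_r)
    b = np.einsum("n,...nd->...d", x_r, d_r, optimize=True)
    c = np.einsum("...nd,...nd->...d", d_r, d_r, optimize=True)
    u = float(x_r @ y_r)
    v = np.einsum("n,...nd->...d", y_r, d_r, optimize=True)
    syy = float(y_r @ y_r)
    det = a * c - b**2
    det = np.where(np.abs(det) < 1e-12, np.nan, det)
    beta_x = (c * u - b * v) / det
    beta_d = (a * v - b * u) / det
    ssr = np.clip(syy - (beta_x * u + beta_d * v), 0.0, None)
    s2 = ssr / df
    var_bx = s2 * c / det
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta_x / np.sqrt(var_bx)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.isnan(p), 1.0, p)


def permutation_gev_fwer(
    y: np.ndarray,
    x: np.ndarray,
    covariates_zy: np.ndarray | None,
    m_residualized: np.ndarray,
    decoy_mediators: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    triplet_id: str = "",
    alpha: float = 0.05,
) -> RegressionMediationResult:
    """FWER-controlled mediation p-value for one triplet.

    decoy_mediators: samples x decoys matrix of off-chromosome
    mediator phenotypes (already residualized by their own
    covariates). Each permutation shuffles the decoy rows, computes
    the conditional p of X given each decoy, and keeps the maximum;
    a GEV is fitted to the maxima and fwer_p = 1 - GEV_CDF(observed).
    Falls back to the empirical tail proportion if the GEV fit fails.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    decoys = np.asarray(decoy_mediators, dtype=float)
    if decoys.ndim == 1:
        decoys = decoys[:, None]
    n = y.shape[0]
    p_obs = conditional_pvalue(y, x, covariates_zy, m_residualized)

    base = add_intercept(covariates_zy, n)
    q, _ = np.linalg.qr(base)
    y_r = y - q @ (q.T @ y)
    x_r = x - q @ (q.T @ x)
    df = n - base.shape[1] - 2
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    p_null = _conditional_p_matrix(y_r, x_r, q, decoys[perms], df)
    maxima = p_null.max(axis=-1)

    gev = None
    fallback = False
    try:
        shape, loc, scale = stats.genextreme.fit(maxima)
        if not np.isfinite([shape, loc, scale]).all() or scale <= 0:
            raise ValueError("degenerate GEV fit")
        ks = stats.kstest(maxima, "genextreme", args=(shape, loc, scale)).statistic
        gev = GEVFit(float(loc), float(scale), float(shape), n_perm, float(ks))
        fwer_p = 1.0 - gev.cdf(p_obs)
    except Exception:  # noqa: BLE001 - MLE failure falls back to empirical tail
        log.warning("GEV fit failed for %s; using empirical tail", triplet_id)
        fallback = True
        fwer_p = float(np.mean(maxima >= p_obs))
    return RegressionMediationResult(
        triplet_id=triplet_id,
        p_conditional_observed=float(p_obs),
        fwer_p=float(fwer_p),
        significant=bool(fwer_p < alpha),
        gev=gev,
        used_empirical_fallback=fallback,
    )
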