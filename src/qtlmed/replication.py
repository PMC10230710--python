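"""Cross-dataset replication statistics.

Storey's pi1 = 1 - pi0 estimates the fraction of non-null associations
among replication p-values; sign concordance summarizes shared allelic
direction between two QTL effect tables; donor down-sampling equalizes
sample sizes between datasets before power comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Pi1Result:
    pi1: float
    pi0: float
    storey_lambda_grid: np.ndarray
    ci_lower: float
    ci_upper: float
    n_pairs: int


def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (truncated-power form with linearity
    constraints beyond the boundary knots); columns = len(knots) - 2 + 1.
    """
    k = np.asarray(knots, dtype=float)
    kmax = k[-1]

    def d(j: int) -> np.ndarray:
        num = np.clip(x - k[j], 0, None) ** 3 - np.clip(x - kmax, 0, None) ** 3
        return num / (kmax - k[j])

    cols = [x]
    for j in range(len(k) - 2):
        cols.append(d(j) - d(len(k) - 2))
    return np.column_stack(cols)


def _pi0_smoothed(p: np.ndarray, grid: np.ndarray, smoother: str) -> float:
    n = p.size
    pi0_lambda = np.array([(p > lam).sum() / (n * (1.0 - lam)) for lam in grid])
    if smoother == "mean":
        return float(np.clip(pi0_lambda.mean(), 0.0, 1.0))
    if len(grid) < 4:
        return float(np.clip(pi0_lambda[-1], 0.0, 1.0))
    # natural cubic spline with 3 df evaluated at the largest lambda
    interior = np.quantile(grid, [1 / 3, 2 / 3])
    knots = np.concatenate([[grid[0]], interior, [grid[-1]]])
    basis = np.column_stack([np.ones_like(grid), _natural_spline_basis(grid, knots)])
    coef, *_ = np.linalg.lstsq(basis, pi0_lambda, rcond=None)
    at_max = np.column_stack(
        [np.ones(1), _natural_spline_basis(np.array([grid[-1]]), knots)]
    )
    return float(np.clip(at_max @ coef, 0.0, 1.0)[0])


def storey_pi1(
    p_values: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
    smoother: str = "spline",
) -> Pi1Result:
    """Storey's pi1 with a percentile bootstrap confidence interval.

    pi0(lambda) = #{p > lambda} / (n (1 - lambda)) on the grid; the
    final pi0 is the natural-cubic-spline smoother (3 df) evaluated at
    the largest lambda, clamped to [0, 1] (``smoother="mean"`` uses the
    grid mean instead). The default grid is seq(0.2, 0.8, 0.1); trans
    replication conventionally uses seq(0.1, max(p), 0.05).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    grid = np.arange(0.2, 0.8001, 0.1) if lambda_grid is None else np.asarray(lambda_grid)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("lambda grid must lie strictly inside (0, 1)")
    grid = np.sort(grid)
    pi0 = _pi0_smoothed(p, grid, smoother)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        boots[b] = 1.0 - _pi0_smoothed(rng.choice(p, size=p.size, replace=True),
                                       grid, smoother)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    pi1 = 1.0 - pi0
    return Pi1Result(
        pi1=float(pi1), pi0=float(pi0), storey_lambda_grid=grid,
        ci_lower=float(min(lo, pi1)), ci_upper=float(max(hi, pi1)), n_pairs=int(p.size),
    )


def trans_lambda_grid(p_values: np.ndarray) -> np.ndarray:
    """seq(0.1, max(p), 0.05), the grid convention for trans replication."""
    upper = min(float(np.max(p_values)), 0.9999)
    if upper <= 0.1:
        return np.array([0.1])
    return np.arange(0.1, upper + 1e-12, 0.05)


def sign_concordance(triplets: pd.DataFrame) -> tuple[float, int]:
    """Fraction of triplets whose two QTL effects share a sign.

    Needs columns beta_xm and beta_xy; zero or non-finite betas are
    excluded and counted. Returns (fraction, n_excluded).
    """
    bxm = triplets["beta_xm"].to_numpy(dtype=float)
    bxy = triplets["beta_xy"].to_numpy(dtype=float)
    ok = np.isfinite(bxm) & np.isfinite(bxy) & (bxm != 0) & (bxy != 0)
    n_excluded = int((~ok).sum())
    if ok.sum() == 0:
        return float("nan"), n_excluded
    frac = float(np.mean(np.sign(bxm[ok]) == np.sign(bxy[ok])))
    return frac, n_excluded


def downsample_donors(
    matrices: dict[str, pd.DataFrame | np.ndarray],
    n_target: int,
    seed: int = 0,
) -> dict[str, pd.DataFrame | np.ndarray]:
    """Uniform donor subset applied consistently to every matrix.

    All matrices must share their first (sample) dimension; sampling is
    without replacement and deterministic under the seed.
    """
    sizes = {k: (v.shape[0]) for k, v in matrices.items()}
    n_avail = next(iter(sizes.values()))
    if any(s != n_avail for s in sizes.values()):
        raise ValueError("matrices disagree on sample count")
    if n_target > n_avail:
        raise ValueError(f"cannot sample {n_target} donors from {n_avail}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n_avail, size=n_target, replace=False))
    out: dict[str, pd.DataFrame | np.ndarray] = {}
    for key, mat in matrices.items():
        if isinstance(mat, pd.DataFrame):
            out[key] = mat.iloc[idx].reset_index(drop=True)
        else:
            out[key] = np.asarray(mat)[idx]
    return out
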