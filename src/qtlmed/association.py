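"""Fixed-effect linear-model QTL engine.

Covers cis caQTL/eQTL and trans scans with covariate adjustment, a
local effective-test correction based on the eigenvalue spectrum of the
cis genotype correlation matrix, hierarchical eGene FDR control, and
greedy windowed LD pruning. Samples are assumed unrelated, so the
variance model is ordinary least squares; all tests are two-sided
t-tests on the dosage coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from qtlmed._ols import add_intercept, ols_t_test

log = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000  # bp, inclusive, around the TSS
CROSSMAP_LOG2_MAX = 5.0  # pairs with symmetric log2 cross-mappability above this are dropped
TRANS_MAF_MIN = 0.025


@dataclass
class QTLResult:
    """One variant-phenotype association test."""

    variant_id: str
    feature_id: str
    beta: float
    se: float
    p_nominal: float
    n_samples: int
    p_local_adjusted: float | None = None
    q_value: float | None = None
    degenerate: bool = False


def fit_qtl(
    y: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray | None = None,
    extra_conditioning: np.ndarray | None = None,
    variant_id: str = "",
    feature_id: str = "",
) -> QTLResult:
    """Test association of phenotype ``y`` with dosage ``x``.

    Fits y ~ x + covariates (+ extra conditioning vectors) by least
    squares and reports the two-sided t-test on the dosage coefficient.
    A monomorphic variant or rank-deficient design yields a degenerate
    result with the p = 1 convention rather than a spurious p-value.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.shape[0]
    if x.shape[0] != n:
        raise ValueError("phenotype and dosage lengths differ")
    base = add_intercept(covariates, n)
    if extra_conditioning is not None:
        extra = np.asarray(extra_conditioning, dtype=float)
        if extra.ndim == 1:
            extra = extra[:, None]
        base = np.hstack([base, extra])
    design = np.hstack([base, x[:, None]])
    if n <= design.shape[1]:
        raise ValueError("n must exceed the number of regressors")
    if np.ptp(x) == 0 or np.linalg.matrix_rank(design) < design.shape[1]:
        return QTLResult(variant_id, feature_id, 0.0, 0.0, 1.0, n, degenerate=True)
    beta, se, p, _ = ols_t_test(y, design, term=design.shape[1] - 1)
    return QTLResult(variant_id, feature_id, beta, se, p, n)


def effective_tests(genotypes: np.ndarray, variance_explained: float = 0.99) -> int:
    """Effective number of independent tests in a cis window.

    Smallest k such that the top-k eigenvalues of the variant
    correlation matrix explain at least ``variance_explained`` of the
    total variance. Constant columns contribute one unit of variance
    with no correlation to anything else.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    m = g.shape[1]
    if m == 0:
        raise ValueError("at least one variant required")
    sd = g.std(axis=0, ddof=0)
    z = np.where(sd > 0, (g - g.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    corr = (z.T @ z) / g.shape[0]
    np.fill_diagonal(corr, 1.0)
    eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    eig = np.clip(eig, 0.0, None)
    frac = np.cumsum(eig) / eig.sum()
    k = int(np.searchsorted(frac, variance_explained - 1e-12) + 1)
    return max(1, min(k, m))


def bh_fdr(p_values: np.ndarray, level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, q, *_ = multipletests(p, alpha=level, method="fdr_bh")
    return q, reject


def hierarchical_egene_fdr(
    results: pd.DataFrame,
    m_eff: dict[str, int],
    level: float = 0.05,
) -> pd.DataFrame:
    """Two-stage eGene discovery.

    Nominal p-values are locally adjusted per gene by a Bonferroni-style
    effective-test multiplier (p_local = min(1, p * M_eff)); the top
    variant per gene enters a genome-wide BH correction, and genes with
    global q below ``level`` are flagged as eGenes.

    ``results`` needs columns variant_id, feature_id, p_nominal.
    """
    rows = []
    for gene, grp in results.groupby("feature_id"):
        if grp.empty:
            log.info("gene %s has no tests; skipped", gene)
            continue
        meff = m_eff.get(gene, 1)
        p_local = np.minimum(1.0, grp["p_nominal"].to_numpy() * meff)
        top = int(np.argmin(p_local))
        rows.append(
            {
                "feature_id": gene,
                "variant_id": grp["variant_id"].iloc[top],
                "p_nominal": grp["p_nominal"].iloc[top],
                "beta": grp["beta"].iloc[top] if "beta" in grp else np.nan,
                "p_local": p_local[top],
                "m_eff": meff,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table.assign(q_global=[], egene=[])
    q, sig = bh_fdr(table["p_local"].to_numpy(), level)
    table["q_global"] = q
    table["egene"] = sig
    return table


def ld_prune(
    genotypes: np.ndarray,
    window: int = 50,
    step: int = 5,
    r2_threshold: float = 0.5,
) -> np.ndarray:
    """Greedy windowed LD pruning over position-ordered variants.

    Within each ``window``-variant window, of any pair with squared
    correlation above ``r2_threshold`` the later variant is removed;
    the window then slides by ``step``. Returns retained column indices.
    """
    g = np.asarray(genotypes, dtype=float)
    m = g.shape[1]
    keep = np.ones(m, dtype=bool)
    start = 0
    while True:
        idx = [j for j in range(start, min(start + window, m)) if keep[j]]
        for a_pos, a in enumerate(idx):
            if not keep[a]:
                continue
            for b in idx[a_pos + 1 :]:
                if not keep[b]:
                    continue
                sa, sb = g[:, a].std(), g[:, b].std()
                if sa == 0 or sb == 0:
                    continue
                r = np.corrcoef(g[:, a], g[:, b])[0, 1]
                if r * r > r2_threshold:
                    keep[b] = False
        if start + window >= m:
            break
        start += step
    return np.flatnonzero(keep)


def trans_scan(
    genotypes: pd.DataFrame,
    variant_meta: pd.DataFrame,
    expression: pd.DataFrame,
    gene_meta: pd.DataFrame,
    covariates: np.ndarray | None = None,
    crossmap: pd.DataFrame | None = None,
    variant_gene_cis: dict[str, str] | None = None,
    maf_min: float = TRANS_MAF_MIN,
    fdr_level: float = 0.10,
    prune: bool = True,
) -> pd.DataFrame:
    """Distal-association scan of cis-QTL variants against all genes.

    Filters follow the trans-eQTL design: variants below the MAF floor
    are dropped, variants are LD-pruned (50/5/0.5), pseudogenes are
    excluded, pairs closer than 1 Mb to the TSS on the same chromosome
    are skipped, and upstream-downstream gene pairs with symmetric
    log2 cross-mappability strictly above 5 are discarded. Missing
    cross-mappability entries count as 0 (pair retained). BH flags at
    10% FDR.

    genotypes: samples x variants (columns = variant ids, dosage 0/1/2).
    variant_meta: variant_id, chrom, pos. gene_meta: gene_id, chrom,
    tss, is_pseudogene. crossmap: gene_a, gene_b, log2_crossmap.
    variant_gene_cis maps each variant to its upstream cis gene for the
    cross-mappability filter.
    """
    vmeta = variant_meta.set_index("variant_id")
    gmeta = gene_meta.set_index("gene_id")
    dosages = genotypes.to_numpy(dtype=float)
    n = dosages.shape[0]
    af = dosages.mean(axis=0) / 2.0
    maf = np.minimum(af, 1 - af)
    keep = maf > maf_min
    variant_ids = [v for v, k in zip(genotypes.columns, keep) if k]
    sub = genotypes[variant_ids]
    if prune and len(variant_ids) > 1:
        order = np.argsort([vmeta.loc[v, "pos"] for v in variant_ids])
        ordered = [variant_ids[i] for i in order]
        kept_idx = ld_prune(sub[ordered].to_numpy())
        variant_ids = [ordered[i] for i in kept_idx]

    cm_lookup: dict[tuple[str, str], float] = {}
    if crossmap is not None:
        for _, row in crossmap.iterrows():
            cm_lookup[(row["gene_a"], row["gene_b"])] = float(row["log2_crossmap"])

    def symmetric_crossmap(a: str, b: str) -> float:
        fwd = cm_lookup.get((a, b))
        rev = cm_lookup.get((b, a))
        if fwd is None and rev is None:
            return 0.0
        fwd = fwd if fwd is not None else 0.0
        rev = rev if rev is not None else 0.0
        return 0.5 * (fwd + rev)

    rows = []
    for vid in variant_ids:
        vchrom, vpos = vmeta.loc[vid, "chrom"], vmeta.loc[vid, "pos"]
        x = sub[vid].to_numpy(dtype=float)
        cis_gene = (variant_gene_cis or {}).get(vid)
        for gid in expression.columns:
            info = gmeta.loc[gid]
            if bool(info.get("is_pseudogene", False)):
                continue
            if info["chrom"] == vchrom and abs(int(info["tss"]) - int(vpos)) <= CIS_WINDOW:
                continue
            if cis_gene is not None:
                if cis_gene == gid:
                    continue
                if symmetric_crossmap(cis_gene, gid) > CROSSMAP_LOG2_MAX:
                    log.debug("dropping %s-%s: cross-mappability filter", vid, gid)
                    continue
            res = fit_qtl(expression[gid].to_numpy(dtype=float), x, covariates,
                          variant_id=vid, feature_id=gid)
            rows.append(
                {
                    "variant_id": vid,
                    "feature_id": gid,
                    "beta": res.beta,
                    "se": res.se,
                    "p_nominal": res.p_nominal,
                    "n_samples": n,
                    "degenerate": res.degenerate,
                }
            )
    cols = ["variant_id", "feature_id", "beta", "se", "p_nominal",
            "n_samples", "degenerate"]
    table = pd.DataFrame(rows, columns=cols)
    if table.empty:
        return table.assign(q_value=[], significant=[])
    q, sig = bh_fdr(table["p_nominal"].to_numpy(), fdr_level)
    table["q_value"] = q
    table["significant"] = sig
    return table


def cis_scan(
    genotypes: pd.DataFrame,
    variant_meta: pd.DataFrame,
    phenotypes: pd.DataFrame,
    feature_meta: pd.DataFrame,
    covariates: np.ndarray | None = None,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """All cis variant-feature tests within ``window`` bp of each feature.

    feature_meta needs feature_id, chrom, and either tss (genes) or
    start/end (peaks; the midpoint anchors the window).
    """
    vmeta = variant_meta.set_index("variant_id")
    rows = []
    for _, feat in feature_meta.iterrows():
        anchor = int(feat["tss"]) if "tss" in feat and not pd.isna(feat.get("tss")) else (
            int(feat["start"]) + int(feat["end"])
        ) // 2
        fid = feat["feature_id"]
        if fid not in phenotypes.columns:
            continue
        y = phenotypes[fid].to_numpy(dtype=float)
        for vid in genotypes.columns:
            if vmeta.loc[vid, "chrom"] != feat["chrom"]:
                continue
            if abs(int(vmeta.loc[vid, "pos"]) - anchor) > window:
                continue
            res = fit_qtl(y, genotypes[vid].to_numpy(dtype=float), covariates,
                          variant_id=vid, feature_id=fid)
            rows.append(
                {
                    "variant_id": vid,
                    "feature_id": fid,
                    "beta": res.beta,
                    "se": res.se,
                    "p_nominal": res.p_nominal,
                    "n_samples": res.n_samples,
                    "degenerate": res.degenerate,
                }
            )
    return pd.DataFrame(rows, columns=["variant_id", "feature_id", "beta", "se",
                                       "p_nominal", "n_samples", "degenerate"])
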