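"""LD-thresholded colocalization of QTL signals with GWAS loci.

A GWAS locus and a molecular QTL are called colocalized when (1) their
index variants are in high LD (r^2 > 0.8) and (2) the molecular
association attenuates below its discovery significance threshold when
the GWAS index variant is added to the QTL model as a covariate —
evidence that the two signals tag the same causal variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qtlmed.association import fit_qtl

log = logging.getLogger(__name__)

GWAS_SIGNIFICANCE = 5e-8
INDEX_PRUNE_R2 = 0.2
COLOC_LD_R2 = 0.8


@dataclass
class GWASIndexSet:
    trait: str
    index_variants: pd.DataFrame  # variant_id, p, pos
    pruning_r2: float = INDEX_PRUNE_R2
    significance: float = GWAS_SIGNIFICANCE


@dataclass
class ColocCall:
    qtl_variant: str
    gwas_variant: str
    ld_r2: float
    p_marginal: float
    p_conditional: float
    colocalized: bool
    fold_attenuation: float = field(default=float("nan"))


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared sample correlation of two dosage vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must share samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("LD undefined for a monomorphic variant")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def define_gwas_index(
    gwas: pd.DataFrame,
    genotypes: pd.DataFrame,
    trait: str = "",
    significance: float = GWAS_SIGNIFICANCE,
    prune_r2: float = INDEX_PRUNE_R2,
) -> GWASIndexSet:
    """Greedy LD-independent index selection among genome-wide hits.

    Candidates with p below ``significance`` are visited by ascending
    p; a candidate joins the index set only if its r^2 with every
    accepted index is below ``prune_r2``.
    gwas: columns variant_id, p (and optionally pos).
    """
    hits = gwas[gwas["p"] < significance].sort_values("p", kind="stable")
    accepted: list[dict] = []
    for _, row in hits.iterrows():
        vid = row["variant_id"]
        if vid not in genotypes.columns:
            continue
        g = genotypes[vid].to_numpy(dtype=float)
        if np.ptp(g) == 0:
            continue
        independent = all(
            ld_r2(g, genotypes[acc["variant_id"]].to_numpy(dtype=float)) < prune_r2
            for acc in accepted
        )
        if independent:
            accepted.append({"variant_id": vid, "p": float(row["p"]),
                             "pos": int(row.get("pos", -1))})
    return GWASIndexSet(trait, pd.DataFrame(accepted, columns=["variant_id", "p", "pos"]),
                        prune_r2, significance)


def test_coloc(
    qtl_variant: str,
    gwas_variant: str,
    genotypes: pd.DataFrame,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    discovery_threshold: float = 0.05,
) -> ColocCall:
    """Conditional-attenuation colocalization test for one locus pair.

    Refits the QTL model adding the GWAS index dosage as a covariate;
    colocalized when ld_r2 > 0.8 and the conditional p rises above the
    discovery significance threshold. A perfectly collinear pair
    (r^2 = 1) is colocalized by definition; the conditional fit is
    skipped.
    """
    gq = genotypes[qtl_variant].to_numpy(dtype=float)
    gg = genotypes[gwas_variant].to_numpy(dtype=float)
    r2 = ld_r2(gq, gg)
    marginal = fit_qtl(phenotype, gq, covariates, variant_id=qtl_variant)
    if np.isclose(r2, 1.0):
        log.info("GWAS index collinear with QTL variant %s; colocalized by definition",
                 qtl_variant)
        return ColocCall(qtl_variant, gwas_variant, r2, marginal.p_nominal, 1.0, True,
                         fold_attenuation=float("inf"))
    conditional = fit_qtl(phenotype, gq, covariates, extra_conditioning=gg,
                          variant_id=qtl_variant)
    p_cond = 1.0 if conditional.degenerate else conditional.p_nominal
    attenuated = p_cond > discovery_threshold
    fold = (np.log10(max(p_cond, 1e-300)) / np.log10(max(marginal.p_nominal, 1e-300))
            if marginal.p_nominal < 1 else float("nan"))
    return ColocCall(
        qtl_variant, gwas_variant, r2, marginal.p_nominal, p_cond,
        colocalized=bool(r2 > COLOC_LD_R2 and attenuated),
        fold_attenuation=float(fold),
    )
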