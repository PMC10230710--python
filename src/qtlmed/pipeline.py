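"""End-to-end orchestration: simulate -> QTL -> triplets -> mediation ->
error filter -> regression comparator, from a single seeded config.

Each planted triplet occupies its own locus: a variant inside a peak,
with a gene TSS nearby, so cis scans recover exactly the planted
associations in the high-PVE regime. Stage outputs are written as TSV
and checksummed into a JSON manifest; rerunning the same config
reproduces identical checksums.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from qtlmed import io as qio
from qtlmed.association import bh_fdr, cis_scan, hierarchical_egene_fdr, effective_tests
from qtlmed.bayes import MediationPriors, posterior_over_models
from qtlmed.error_model import estimate_icc, filter_triplets, simulate_flip_threshold
from qtlmed.regression import permutation_gev_fwer, residualize
from qtlmed.synthetic import GenomeLayout, SyntheticArchitecture, generate_triplet_data
from qtlmed.triplets import Triplet, build_forward_triplets, validate_triplets

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one end-to-end demo run."""

    seed: int = 0
    n_samples: int = 300
    n_triplets: int = 40
    forward_fraction: float = 0.5
    independence_fraction: float = 0.5
    pve_a: float = 0.5
    pve_b: float = 0.5
    pve_c_independence: float = 0.5
    maf: float = 0.5
    icc_m: float = 0.9
    icc_y: float = 0.95
    n_replicate_donors: int = 50
    n_replicates: int = 3
    caqtl_fdr: float = 0.05
    egene_fdr: float = 0.05
    run_error_model: bool = True
    run_regression: bool = True
    flip_grid_points: int = 10
    flip_reps: int = 2
    n_perm: int = 200
    n_decoys: int = 10
    out_dir: str = "pipeline_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**qio.load_config(path))


def _plant_loci(cfg: RunConfig, rng: np.random.Generator):
    """One locus per triplet: peak with an internal variant, gene TSS 10 kb away."""
    spacing = 3_000_000
    chrom_len = spacing * (cfg.n_triplets + 1)
    peaks, genes, variants = [], [], []
    for i in range(cfg.n_triplets):
        start = spacing * i + 1_000_000
        peaks.append({"peak_id": f"peak{i}", "chrom": "chr1",
                      "start": start, "end": start + 500})
        genes.append({"gene_id": f"gene{i}", "chrom": "chr1",
                      "tss": start + 10_000, "strand": "+",
                      "is_tf": False, "is_pseudogene": False})
        variants.append({"id": f"var{i}", "variant_id": f"var{i}", "chrom": "chr1",
                         "pos": start + int(rng.integers(0, 500)), "maf": cfg.maf})
    layout = GenomeLayout([("chr1", chrom_len)], pd.DataFrame(peaks), pd.DataFrame(genes))
    return layout, pd.DataFrame(variants)


def run_all(cfg: RunConfig) -> dict:
    """Execute every enabled stage; returns the output manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(cfg.seed)
    stage_seed = {name: int(master.integers(2**31)) for name in
                  ("simulate", "qtl", "mediate", "error", "regression")}
    rng = np.random.default_rng(stage_seed["simulate"])

    # --- simulate ---------------------------------------------------------
    layout, variant_meta = _plant_loci(cfg, rng)
    n_forward = round(cfg.n_triplets * cfg.forward_fraction)
    truth_rows, geno_cols, acc_cols, expr_cols = [], {}, {}, {}
    icc_m_true: dict[str, float] = {}
    icc_y_true: dict[str, float] = {}
    replicate_tables_m, replicate_tables_y = {}, {}
    for i in range(cfg.n_triplets):
        is_forward = i < n_forward
        arch = SyntheticArchitecture(
            true_model="complete mediation" if is_forward else "co-local/independence",
            pve_a=cfg.pve_a,
            pve_b=cfg.pve_b if is_forward else 0.0,
            pve_c=0.0 if is_forward else cfg.pve_c_independence,
            maf=cfg.maf, n_samples=cfg.n_samples,
            icc_m=cfg.icc_m, icc_y=cfg.icc_y,
            n_replicate_donors=cfg.n_replicate_donors,
            n_replicates=cfg.n_replicates,
        )
        data = generate_triplet_data(arch, seed=int(rng.integers(2**31)))
        geno_cols[f"var{i}"] = data.x
        acc_cols[f"peak{i}"] = data.m_observed
        expr_cols[f"gene{i}"] = data.y_observed
        icc_m_true[f"peak{i}"] = cfg.icc_m
        icc_y_true[f"gene{i}"] = cfg.icc_y
        replicate_tables_m[f"peak{i}"] = data.replicates_m
        replicate_tables_y[f"gene{i}"] = data.replicates_y
        truth_rows.append({"triplet_id": f"var{i}:peak{i}:gene{i}",
                           "true_model": arch.true_model})
    genotypes = pd.DataFrame(geno_cols)
    accessibility = pd.DataFrame(acc_cols)
    expression = pd.DataFrame(expr_cols)
    truth = pd.DataFrame(truth_rows)
    qio.write_tsv(out / "truth.tsv", truth)
    qio.write_bed(out / "peaks.bed", layout.peaks)
    qio.write_tsv(out / "genes.tsv", layout.genes)
    qio.write_vcf(out / "genotypes.vcf", genotypes, variant_meta)
    qio.write_phenotype_matrix(out / "accessibility.tsv", accessibility)
    qio.write_phenotype_matrix(out / "expression.tsv", expression)

    # --- QTL scans --------------------------------------------------------
    peak_meta = layout.peaks.rename(columns={"peak_id": "feature_id"})
    gene_meta = layout.genes.rename(columns={"gene_id": "feature_id"})
    ca_results = cis_scan(genotypes, variant_meta, accessibility, peak_meta)
    e_results = cis_scan(genotypes, variant_meta, expression, gene_meta)
    q, sig = bh_fdr(ca_results["p_nominal"].to_numpy(), cfg.caqtl_fdr)
    ca_results["q_value"], ca_results["significant"] = q, sig
    m_eff = {
        gid: effective_tests(genotypes.to_numpy())
        for gid in expression.columns
    }
    egenes = hierarchical_egene_fdr(e_results, m_eff, cfg.egene_fdr)
    qio.write_tsv(out / "caqtl.tsv", ca_results)
    qio.write_tsv(out / "eqtl.tsv", e_results)
    qio.write_tsv(out / "egenes.tsv", egenes)

    # --- triplets ---------------------------------------------------------
    ca_sig = ca_results[ca_results["significant"]]
    e_sig = egenes[egenes["egene"]][["variant_id", "feature_id", "beta"]]
    trips = build_forward_triplets(ca_sig, e_sig, variant_meta,
                                   layout.peaks, layout.genes)
    validate_triplets(trips, variant_meta, layout.peaks, layout.genes)

    # --- Bayesian mediation ----------------------------------------------
    priors = MediationPriors(model_prior_mode="complete")
    med_rows = []
    for t in trips:
        post = posterior_over_models(
            genotypes[t.x_variant_id].to_numpy(),
            accessibility[t.m_feature_id].to_numpy(),
            expression[t.y_feature_id].to_numpy(),
            priors=priors, triplet_id=t.triplet_id,
        )
        t.classification = post.classification
        med_rows.append({
            "triplet_id": t.triplet_id,
            "m_feature_id": t.m_feature_id,
            "y_feature_id": t.y_feature_id,
            "classification": post.classification,
            "posterior_forward_sum": post.posterior_forward_sum,
            "posterior_reactive_sum": post.posterior_reactive_sum,
            **{f"p_{k}": v for k, v in post.posterior.items()},
        })
    mediation = pd.DataFrame(med_rows)
    qio.write_tsv(out / "mediation.tsv", mediation)

    # --- error-model filter ----------------------------------------------
    if cfg.run_error_model and not mediation.empty:
        icc_m_est = {
            fid: estimate_icc(tab, fid).icc
            for fid, tab in replicate_tables_m.items() if len(tab)
        }
        icc_y_est = {
            fid: estimate_icc(tab, fid).icc
            for fid, tab in replicate_tables_y.items() if len(tab)
        }
        grid = np.linspace(0.05, 1.0, cfg.flip_grid_points)
        thresholds = {}
        for _, row in mediation[mediation["classification"] == "reactive"].iterrows():
            thresholds[row["triplet_id"]] = simulate_flip_threshold(
                cfg.pve_a, cfg.pve_b, "reactive_truth",
                n_samples=cfg.n_samples, icc_grid=grid, n_reps=cfg.flip_reps,
                seed=stage_seed["error"], triplet_id=row["triplet_id"],
            )
        retained, excluded = filter_triplets(mediation, icc_m_est, icc_y_est, thresholds)
        qio.write_tsv(out / "mediation_filtered.tsv", retained)
        qio.write_tsv(out / "exclusions.tsv", excluded)
        final = retained
    else:
        final = mediation.assign(provenance="unfiltered")
        qio.write_tsv(out / "mediation_filtered.tsv", final)

    # --- regression comparator -------------------------------------------
    if cfg.run_regression and trips:
        reg_rng = np.random.default_rng(stage_seed["regression"])
        reg_rows = []
        decoy_pool = accessibility.to_numpy()
        for t in trips:
            own = list(accessibility.columns).index(t.m_feature_id)
            decoy_idx = [j for j in range(decoy_pool.shape[1]) if j != own]
            chosen = reg_rng.choice(decoy_idx,
                                    size=min(cfg.n_decoys, len(decoy_idx)),
                                    replace=False)
            res = permutation_gev_fwer(
                expression[t.y_feature_id].to_numpy(),
                genotypes[t.x_variant_id].to_numpy(),
                None,
                residualize(accessibility[t.m_feature_id].to_numpy(), None),
                decoy_pool[:, chosen],
                n_perm=cfg.n_perm,
                seed=int(reg_rng.integers(2**31)),
                triplet_id=t.triplet_id,
            )
            reg_rows.append({
                "triplet_id": res.triplet_id,
                "p_conditional_observed": res.p_conditional_observed,
                "fwer_p": res.fwer_p,
                "significant": res.significant,
            })
        qio.write_tsv(out / "regression_mediation.tsv", pd.DataFrame(reg_rows))

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config": asdict(cfg),
        "stage_seeds": stage_seed,
        "n_triplets_built": len(trips),
        "outputs": {
            p.name: qio.sha256_file(p)
            for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.bed"))
            + sorted(out.glob("*.vcf"))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
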