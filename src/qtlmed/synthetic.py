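"""Synthetic genotype / phenotype / annotation generator with planted causal architectures.

Every downstream stage of the pipeline is validated against data from
this module: Hardy-Weinberg genotypes at a chosen minor allele
frequency (optionally with block LD), X-M-Y triplets with exact
variance partitioning among genetic, mediated, direct, covariate, and
noise components, technical-replicate tables with a controlled
intraclass correlation, random peak sequences with planted motif
consensus instances, and GWAS summary statistics colocalized with a
planted causal variant.

The defaults mirror the study conditions the pipeline is meant to
emulate: variant MAF 0.5 and 75 donors (a realistic cell-line QTL cohort)
unless configured otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qtlmed.association import fit_qtl

BASES = np.array(list("ACGT"))

DAG_LABELS = (
    "no-effects", "x->m only", "m->y only", "x->y only",
    "complete mediation", "co-local/independence", "y-with-m no-x->m",
    "partial mediation", "y->m only", "complete reactive",
    "x->m + y->m", "partial reactive",
)


@dataclass
class GenomeLayout:
    """Chromosome lengths plus peak and gene annotation tables.

    peaks: columns peak_id, chrom, start, end (0-based half-open).
    genes: columns gene_id, chrom, tss, strand, is_tf, is_pseudogene.
    """

    chromosomes: list[tuple[str, int]]
    peaks: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if not self.peaks.empty:
            if (self.peaks["start"] >= self.peaks["end"]).any():
                raise ValueError("peak start must be < end")
            if self.peaks["peak_id"].duplicated().any():
                raise ValueError("peak ids must be unique")
            for _, p in self.peaks.iterrows():
                if p["end"] > lengths[p["chrom"]] or p["start"] < 0:
                    raise ValueError(f"peak {p['peak_id']} outside chromosome")
        if not self.genes.empty:
            if self.genes["gene_id"].duplicated().any():
                raise ValueError("gene ids must be unique")
            for _, g in self.genes.iterrows():
                if not (0 <= g["tss"] < lengths[g["chrom"]]):
                    raise ValueError(f"gene {g['gene_id']} TSS outside chromosome")


@dataclass
class SyntheticArchitecture:
    """Specification of one planted X-M-Y triplet.

    pve_a: fraction of M variance explained by X (for reactive-truth
    models, of Y variance — the roles mirror). pve_b: fraction of the
    downstream phenotype's variance explained by the mediator.
    pve_c: fraction of the downstream phenotype's variance explained
    directly by X. icc_m / icc_y: intraclass correlations of the
    observed phenotypes (1 = no measurement error). pve_cov: variance
    fraction from covariates, applied to both phenotypes.
    """

    true_model: str = "complete mediation"
    pve_a: float = 0.5
    pve_b: float = 0.5
    pve_c: float = 0.0
    maf: float = 0.5
    n_samples: int = 75
    icc_m: float = 1.0
    icc_y: float = 1.0
    n_replicate_donors: int = 0
    n_replicates: int = 3
    pve_cov: float = 0.0
    fix_effect_signs: bool = True

    def __post_init__(self) -> None:
        if self.true_model not in DAG_LABELS:
            raise ValueError(f"unknown causal model {self.true_model!r}")
        for v in (self.pve_a, self.pve_b, self.pve_c, self.pve_cov):
            if not 0 <= v < 1:
                raise ValueError("PVE values must lie in [0, 1)")
        if self.pve_a + self.pve_cov >= 1 or self.pve_b + self.pve_c + self.pve_cov >= 1:
            raise ValueError("per-phenotype PVE sums must be < 1")
        for icc in (self.icc_m, self.icc_y):
            if not 0 < icc <= 1:
                raise ValueError("ICC must lie in (0, 1]")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


@dataclass
class TripletData:
    """Output container of generate_triplet_data."""

    x: np.ndarray  # dosage 0/1/2
    m_true: np.ndarray
    y_true: np.ndarray
    m_observed: np.ndarray
    y_observed: np.ndarray
    covariates: np.ndarray | None
    replicates_m: pd.DataFrame = field(default_factory=pd.DataFrame)
    replicates_y: pd.DataFrame = field(default_factory=pd.DataFrame)


def generate_genotypes(
    n_samples: int,
    variants: pd.DataFrame,
    ld_block_r2: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Hardy-Weinberg dosages (0/1/2) for a variant table.

    variants: columns id, chrom, pos, maf (and optionally block,
    identifying LD blocks). Within a block, each allele of a variant
    copies the corresponding allele of the previous variant with
    probability sqrt(ld_block_r2), giving adjacent-pair dosage r^2
    near the target.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    mafs = variants["maf"].to_numpy(dtype=float)
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    blocks = variants["block"].to_numpy() if "block" in variants else np.arange(len(variants))
    copy_p = np.sqrt(ld_block_r2) if ld_block_r2 is not None else 0.0
    alleles = np.zeros((n_samples, 2, len(variants)), dtype=np.int8)
    for j, maf in enumerate(mafs):
        fresh = rng.random((n_samples, 2)) < maf
        if j > 0 and blocks[j] == blocks[j - 1] and copy_p > 0:
            copy = rng.random((n_samples, 2)) < copy_p
            alleles[:, :, j] = np.where(copy, alleles[:, :, j - 1], fresh)
        else:
            alleles[:, :, j] = fresh
    dosage = alleles.sum(axis=1)
    return pd.DataFrame(dosage, columns=variants["id"].tolist())


def _scaled_effect(source: np.ndarray, pve: float, rng: np.random.Generator,
                   fix_sign: bool) -> np.ndarray:
    """Component with variance exactly ``pve`` relative to unit total.

    The source is standardized to unit variance, then scaled so the
    component's variance fraction equals pve by construction.
    """
    if pve == 0:
        return np.zeros_like(source, dtype=float)
    s = np.asarray(source, dtype=float)
    sd = s.std(ddof=0)
    if sd == 0:
        return np.zeros_like(s)
    sign = 1.0 if fix_sign else (1.0 if rng.random() < 0.5 else -1.0)
    return sign * np.sqrt(pve) * (s - s.mean()) / sd


def generate_triplet_data(
    arch: SyntheticArchitecture,
    covariates: np.ndarray | None = None,
    seed: int = 0,
) -> TripletData:
    """Simulate one triplet under the planted causal model.

    Structural components are scaled so their empirical variance
    fractions equal the planted PVEs; residual noise tops each
    phenotype up to (approximately) unit variance. Measurement error
    on the observed phenotypes is Gaussian with variance
    Var(true) * (1 - icc) / icc so the intraclass correlation equals
    the target. Replicate tables hold n_replicate_donors donors with
    n_replicates draws each sharing the donor's true value.
    """
    rng = np.random.default_rng(seed)
    n = arch.n_samples
    x = rng.binomial(2, arch.maf, size=n).astype(float)
    while np.ptp(x) == 0:  # avoid a monomorphic draw at small n
        x = rng.binomial(2, arch.maf, size=n).astype(float)
    x_to_m, med, x_to_y = {
        label: cfg
        for label, cfg in zip(DAG_LABELS, (
            (False, "none", False), (True, "none", False), (False, "m_to_y", False),
            (False, "none", True), (True, "m_to_y", False), (True, "none", True),
            (False, "m_to_y", True), (True, "m_to_y", True), (False, "y_to_m", False),
            (False, "y_to_m", True), (True, "y_to_m", False), (True, "y_to_m", True),
        ))
    }[arch.true_model]

    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        cov_m = _scaled_effect(covariates.sum(axis=1), arch.pve_cov, rng, arch.fix_effect_signs)
        cov_y = _scaled_effect(covariates.sum(axis=1), arch.pve_cov, rng, arch.fix_effect_signs)
    else:
        cov_m = cov_y = np.zeros(n)

    def upstream(parent_pves: list[tuple[np.ndarray, float]], cov_term: np.ndarray) -> np.ndarray:
        total_pve = sum(p for _, p in parent_pves) + (float(np.var(cov_term) > 0) and arch.pve_cov)
        noise_var = max(1.0 - total_pve, 1e-12)
        out = rng.normal(0.0, np.sqrt(noise_var), size=n) + cov_term
        for src, pve in parent_pves:
            out = out + _scaled_effect(src, pve, rng, arch.fix_effect_signs)
        return out

    if med == "y_to_m":  # reactive-type: Y is upstream of M
        y_parents = [(x, arch.pve_a)] if (x_to_y or arch.true_model in
                                          ("complete reactive", "partial reactive")) else []
        y_true = upstream(y_parents, cov_y)
        m_parents = [(y_true, arch.pve_b)]
        if x_to_m:
            m_parents.append((x, arch.pve_c))
        m_true = upstream(m_parents, cov_m)
    else:
        m_parents = [(x, arch.pve_a)] if x_to_m else []
        m_true = upstream(m_parents, cov_m)
        y_parents = []
        if med == "m_to_y":
            y_parents.append((m_true, arch.pve_b))
        if x_to_y:
            y_parents.append((x, arch.pve_c))
        y_true = upstream(y_parents, cov_y)

    def observe(true: np.ndarray, icc: float) -> tuple[np.ndarray, float]:
        err_var = float(np.var(true)) * (1.0 - icc) / icc
        if err_var == 0:
            return true.copy(), 0.0
        return true + rng.normal(0.0, np.sqrt(err_var), size=n), err_var

    m_obs, err_m = observe(m_true, arch.icc_m)
    y_obs, err_y = observe(y_true, arch.icc_y)

    def replicate_table(true: np.ndarray, err_var: float, icc: float) -> pd.DataFrame:
        if arch.n_replicate_donors == 0:
            return pd.DataFrame(columns=["donor", "replicate", "value"])
        donors = rng.choice(n, size=min(arch.n_replicate_donors, n), replace=False)
        if err_var == 0 and icc < 1:
            err_var = float(np.var(true)) * (1.0 - icc) / icc
        rows = []
        for d in donors:
            for r in range(arch.n_replicates):
                noise = rng.normal(0.0, np.sqrt(err_var)) if err_var > 0 else 0.0
                rows.append({"donor": int(d), "replicate": r, "value": true[d] + noise})
        return pd.DataFrame(rows)

    return TripletData(
        x=x, m_true=m_true, y_true=y_true, m_observed=m_obs, y_observed=y_obs,
        covariates=covariates,
        replicates_m=replicate_table(m_true, err_m, arch.icc_m),
        replicates_y=replicate_table(y_true, err_y, arch.icc_y),
    )


def generate_motif_instances(
    pwm: np.ndarray,
    peaks: pd.DataFrame,
    planted_fraction: float,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random peak sequences with the PWM consensus planted in a fraction.

    pwm: 4 x width weight matrix (rows A, C, G, T). Returns
    (peak_id -> sequence, truth table with peak_id and offset).
    Exactly round(planted_fraction * n_peaks) peaks carry an exact
    consensus insertion at a recorded 0-based offset; all other bases
    are i.i.d. uniform.
    """
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must lie in [0, 1]")
    width = pwm.shape[1]
    lengths = (peaks["end"] - peaks["start"]).to_numpy()
    if width > lengths.min():
        raise ValueError("PWM wider than the shortest peak")
    rng = np.random.default_rng(seed)
    consensus = "".join(BASES[np.argmax(pwm, axis=0)])
    n_plant = round(planted_fraction * len(peaks))
    planted = rng.choice(len(peaks), size=n_plant, replace=False)
    sequences: dict[str, str] = {}
    truth_rows = []
    for i, (_, peak) in enumerate(peaks.iterrows()):
        length = int(peak["end"] - peak["start"])
        seq = rng.choice(BASES, size=length)
        if i in planted:
            offset = int(rng.integers(0, length - width + 1))
            seq[offset : offset + width] = list(consensus)
            truth_rows.append({"peak_id": peak["peak_id"], "offset": offset})
        sequences[peak["peak_id"]] = "".join(seq)
    truth = pd.DataFrame(truth_rows, columns=["peak_id", "offset"])
    return sequences, truth


def generate_gwas_stats(
    genotypes: pd.DataFrame,
    causal_variant: str,
    trait_pve: float,
    n_gwas: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Marginal GWAS summary statistics for a trait with one causal variant.

    A GWAS cohort of n_gwas individuals is drawn by resampling rows of
    the genotype panel (preserving LD); the trait is the causal
    variant's standardized dosage scaled to ``trait_pve`` plus Gaussian
    noise. Per-variant marginal regression yields (beta, se, p).
    """
    if causal_variant not in genotypes.columns:
        raise KeyError(f"unknown causal variant {causal_variant!r}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, genotypes.shape[0], size=n_gwas)
    panel = genotypes.to_numpy(dtype=float)[idx]
    cols = list(genotypes.columns)
    g_causal = panel[:, cols.index(causal_variant)]
    trait = rng.normal(0.0, np.sqrt(max(1.0 - trait_pve, 1e-12)), size=n_gwas)
    trait = trait + _scaled_effect(g_causal, trait_pve, rng, fix_sign=True)
    rows = []
    for j, vid in enumerate(cols):
        res = fit_qtl(trait, panel[:, j], variant_id=vid, feature_id="trait")
        rows.append({"variant_id": vid, "beta": res.beta, "se": res.se,
                     "p": res.p_nominal, "n": n_gwas})
    return pd.DataFrame(rows)


def make_layout(
    n_peaks: int = 20,
    n_genes: int = 10,
    chrom_length: int = 10_000_000,
    n_chromosomes: int = 2,
    peak_length: int = 500,
    tf_fraction: float = 0.3,
    seed: int = 0,
) -> GenomeLayout:
    """Random genome layout with evenly spread peaks and genes."""
    rng = np.random.default_rng(seed)
    chroms = [(f"chr{i + 1}", chrom_length) for i in range(n_chromosomes)]
    peak_rows, gene_rows = [], []
    for i in range(n_peaks):
        chrom = chroms[i % n_chromosomes][0]
        start = int(rng.integers(0, chrom_length - peak_length))
        peak_rows.append({"peak_id": f"peak{i}", "chrom": chrom,
                          "start": start, "end": start + peak_length})
    for i in range(n_genes):
        chrom = chroms[i % n_chromosomes][0]
        gene_rows.append({
            "gene_id": f"gene{i}", "chrom": chrom,
            "tss": int(rng.integers(0, chrom_length)),
            "strand": "+" if rng.random() < 0.5 else "-",
            "is_tf": bool(rng.random() < tf_fraction),
            "is_pseudogene": False,
        })
    return GenomeLayout(chroms, pd.DataFrame(peak_rows), pd.DataFrame(gene_rows))
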