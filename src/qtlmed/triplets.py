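"""Candidate X-M-Y triplet construction and annotation.

Three eligibility classes feed the mediation engine:

* forward  — the variant sits inside a chromatin-accessible peak it
  regulates (caQTL at 5% FDR) and is also an eQTL for a gene whose TSS
  lies within 1 Mb (M = peak accessibility, Y = expression);
* reactive — the variant cis-regulates a transcription-factor gene and
  is a trans-caQTL for a distal peak carrying that TF's binding motif
  (80% relative-score match), with variants inside the target peak
  excluded since those indicate cis action;
* trans    — the variant is a cis-eSNP of an upstream gene and a
  trans-eQTL (>1 Mb or another chromosome) of a downstream gene
  (M = upstream expression, Y = downstream expression).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

MOTIF_MIN_RELATIVE_SCORE = 0.8
PROMOTER_WINDOW = 2_000  # bp either side of the TSS
CIS_WINDOW = 1_000_000

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWM:
    """Position weight matrix: 4 x width, rows A, C, G, T.

    ``matrix`` may hold counts, probabilities, or log-odds; scanning
    converts counts/probabilities to log-odds against a uniform
    background with a pseudocount.
    """

    matrix: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("PWM must be 4 x width with width >= 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.matrix, axis=0))

    def log_odds(self, pseudocount: float = 0.1) -> np.ndarray:
        m = self.matrix
        if np.any(m < 0):  # already log-odds
            return m
        col_sums = m.sum(axis=0)
        probs = (m + pseudocount) / (col_sums + 4 * pseudocount)
        return np.log2(probs / 0.25)


def read_jaspar(path: str) -> list[PWM]:
    """Parse a JASPAR-format PFM file into PWM objects (Biopython)."""
    from Bio import motifs

    out = []
    with open(path) as fh:
        for motif in motifs.parse(fh, "jaspar"):
            mat = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
            out.append(PWM(mat, name=motif.name or motif.matrix_id))
    return out


@dataclass
class Triplet:
    x_variant_id: str
    m_feature_id: str
    y_feature_id: str
    eligibility: str  # forward | reactive | trans
    beta_xm: float = float("nan")
    beta_xy: float = float("nan")
    direction_shared: bool | None = None
    r2_ym: float = float("nan")
    tss_distance: int = -1
    in_promoter: bool = False
    asca: bool | None = None
    motif_disruption: bool | None = None
    classification: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def triplet_id(self) -> str:
        return f"{self.x_variant_id}:{self.m_feature_id}:{self.y_feature_id}"


def scan_pwm(
    sequence: str,
    pwm: PWM,
    min_relative_score: float = MOTIF_MIN_RELATIVE_SCORE,
    both_strands: bool = True,
) -> pd.DataFrame:
    """All motif hits with min-max relative score above the threshold.

    relative score = (score - min possible) / (max possible - min
    possible) using the log-odds matrix; both strands are scanned by
    scoring the reverse complement. Ambiguous bases contribute the
    column minimum. Offsets are 0-based on the forward strand.
    """
    lo = pwm.log_odds()
    w = pwm.width
    col_min, col_max = lo.min(axis=0), lo.max(axis=0)
    denom = float((col_max - col_min).sum())
    seq = sequence.upper()
    n = len(seq)
    hits = []

    def score_strand(s: str, strand: str) -> None:
        if any(b not in _BASE_INDEX for b in set(s)):
            log.info("ambiguous bases scored at the column minimum")
        idx = np.array([_BASE_INDEX.get(b, -1) for b in s])
        for off in range(len(s) - w + 1):
            window = idx[off : off + w]
            score = float(
                sum(lo[b, i] if b >= 0 else col_min[i] for i, b in enumerate(window))
            )
            rel = (score - col_min.sum()) / denom if denom > 0 else 1.0
            if rel >= min_relative_score:
                fwd_off = off if strand == "+" else len(s) - w - off
                hits.append({"offset": fwd_off, "strand": strand,
                             "relative_score": rel})

    score_strand(seq, "+")
    if both_strands:
        score_strand(seq.translate(_COMPLEMENT)[::-1], "-")
    return pd.DataFrame(hits, columns=["offset", "strand", "relative_score"])


def _inside_peak(pos: int, start: int, end: int) -> bool:
    """Half-open interval membership, the BED convention."""
    return start <= pos < end


def build_forward_triplets(
    caqtl: pd.DataFrame,
    eqtl: pd.DataFrame,
    variant_meta: pd.DataFrame,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
) -> list[Triplet]:
    """Forward-eligible triplets from significant ca/eQTL pairs.

    caqtl: significant variant-peak rows (variant_id, feature_id,
    beta); eqtl: significant variant-gene rows. A triplet requires the
    same variant in both tables, the variant inside the peak interval
    (half-open), and the variant within 1 Mb of the gene TSS.
    """
    vmeta = variant_meta.set_index("variant_id")
    pmeta = peaks.set_index("peak_id")
    gmeta = genes.set_index("gene_id")
    out = []
    ca_by_variant = caqtl.groupby("variant_id")
    for vid, egrp in eqtl.groupby("variant_id"):
        if vid not in ca_by_variant.groups or vid not in vmeta.index:
            continue
        pos = int(vmeta.loc[vid, "pos"])
        chrom = vmeta.loc[vid, "chrom"]
        for _, ca in ca_by_variant.get_group(vid).iterrows():
            peak = pmeta.loc[ca["feature_id"]]
            if peak["chrom"] != chrom or not _inside_peak(pos, int(peak["start"]),
                                                          int(peak["end"])):
                continue
            for _, eq in egrp.iterrows():
                gene = gmeta.loc[eq["feature_id"]]
                dist = abs(int(gene["tss"]) - pos)
                if gene["chrom"] != chrom or dist > CIS_WINDOW:
                    continue
                out.append(Triplet(
                    x_variant_id=vid,
                    m_feature_id=ca["feature_id"],
                    y_feature_id=eq["feature_id"],
                    eligibility="forward",
                    beta_xm=float(ca["beta"]),
                    beta_xy=float(eq["beta"]),
                    direction_shared=bool(np.sign(ca["beta"]) == np.sign(eq["beta"])),
                    tss_distance=dist,
                    in_promoter=dist <= PROMOTER_WINDOW,
                ))
    return out


def build_reactive_triplets(
    tf_egenes: pd.DataFrame,
    pwms: dict[str, PWM],
    peak_sequences: dict[str, str],
    trans_caqtl: pd.DataFrame,
    variant_meta: pd.DataFrame,
    peaks: pd.DataFrame,
) -> list[Triplet]:
    """Reactive-eligible triplets: TF eGene variant -> motif-bearing peak.

    tf_egenes: significant TF-gene rows (variant_id, feature_id, beta)
    from the TF-restricted hierarchical procedure; trans_caqtl:
    significant trans variant-peak rows at 5% FDR. The peak must carry
    a motif hit of the TF; variants inside the target peak are
    excluded (cis action).
    """
    vmeta = variant_meta.set_index("variant_id")
    pmeta = peaks.set_index("peak_id")
    motif_cache: dict[tuple[str, str], bool] = {}

    def has_motif(tf: str, peak_id: str) -> bool:
        key = (tf, peak_id)
        if key not in motif_cache:
            pwm = pwms.get(tf)
            if pwm is None:
                motif_cache[key] = False
            else:
                hits = scan_pwm(peak_sequences.get(peak_id, ""), pwm)
                motif_cache[key] = not hits.empty
        return motif_cache[key]

    out = []
    for _, eg in tf_egenes.iterrows():
        tf_gene = eg["feature_id"]
        vid = eg["variant_id"]
        if tf_gene not in pwms:
            log.info("TF %s has no PWM; skipped", tf_gene)
            continue
        matches = trans_caqtl[trans_caqtl["variant_id"] == vid]
        for _, ca in matches.iterrows():
            peak_id = ca["feature_id"]
            peak = pmeta.loc[peak_id]
            pos = int(vmeta.loc[vid, "pos"])
            if vmeta.loc[vid, "chrom"] == peak["chrom"] and _inside_peak(
                pos, int(peak["start"]), int(peak["end"])
            ):
                log.info("variant %s inside target peak %s; excluded from reactive",
                         vid, peak_id)
                continue
            if not has_motif(tf_gene, peak_id):
                continue
            out.append(Triplet(
                x_variant_id=vid,
                m_feature_id=tf_gene,  # reactive mediator analog: TF expression
                y_feature_id=peak_id,
                eligibility="reactive",
                beta_xm=float(eg["beta"]),
                beta_xy=float(ca["beta"]),
                direction_shared=bool(np.sign(eg["beta"]) == np.sign(ca["beta"])),
            ))
    return out


def build_trans_triplets(
    cis_pairs: pd.DataFrame,
    trans_results: pd.DataFrame,
    crossmap: pd.DataFrame | None = None,
    crossmap_log2_max: float = 5.0,
) -> list[Triplet]:
    """Trans-eligible triplets: cis eSNP -> upstream gene -> distal gene.

    cis_pairs: variant_id, feature_id (upstream gene), beta;
    trans_results: significant trans rows (variant_id, feature_id =
    downstream gene, beta). Self-pairs are rejected; pairs with
    symmetric log2 cross-mappability strictly above the cutoff are
    dropped.
    """
    cm: dict[tuple[str, str], float] = {}
    if crossmap is not None:
        for _, row in crossmap.iterrows():
            cm[(row["gene_a"], row["gene_b"])] = float(row["log2_crossmap"])

    def symmetric(a: str, b: str) -> float:
        return 0.5 * (cm.get((a, b), 0.0) + cm.get((b, a), 0.0))

    out = []
    for _, cis in cis_pairs.iterrows():
        vid, upstream = cis["variant_id"], cis["feature_id"]
        for _, tr in trans_results[trans_results["variant_id"] == vid].iterrows():
            downstream = tr["feature_id"]
            if downstream == upstream:
                continue
            if symmetric(upstream, downstream) > crossmap_log2_max:
                log.info("pair %s-%s dropped: cross-mappability", upstream, downstream)
                continue
            out.append(Triplet(
                x_variant_id=vid,
                m_feature_id=upstream,
                y_feature_id=downstream,
                eligibility="trans",
                beta_xm=float(cis["beta"]),
                beta_xy=float(tr["beta"]),
                direction_shared=bool(np.sign(cis["beta"]) == np.sign(tr["beta"])),
            ))
    return out


def validate_triplets(
    triplets: list[Triplet],
    variant_meta: pd.DataFrame,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
) -> None:
    """Re-check every eligibility invariant; raises on violation."""
    vmeta = variant_meta.set_index("variant_id")
    pmeta = peaks.set_index("peak_id")
    gmeta = genes.set_index("gene_id")
    for t in triplets:
        pos = int(vmeta.loc[t.x_variant_id, "pos"])
        chrom = vmeta.loc[t.x_variant_id, "chrom"]
        if t.eligibility == "forward":
            peak = pmeta.loc[t.m_feature_id]
            if peak["chrom"] != chrom or not _inside_peak(pos, int(peak["start"]),
                                                          int(peak["end"])):
                raise AssertionError(f"{t.triplet_id}: variant not inside mediator peak")
            gene = gmeta.loc[t.y_feature_id]
            if gene["chrom"] != chrom or abs(int(gene["tss"]) - pos) > CIS_WINDOW:
                raise AssertionError(f"{t.triplet_id}: gene TSS beyond the cis window")
        elif t.eligibility == "reactive":
            peak = pmeta.loc[t.y_feature_id]
            if peak["chrom"] == chrom and _inside_peak(pos, int(peak["start"]),
                                                       int(peak["end"])):
                raise AssertionError(f"{t.triplet_id}: reactive variant inside target peak")
        elif t.eligibility == "trans":
            if t.m_feature_id == t.y_feature_id:
                raise AssertionError(f"{t.triplet_id}: self-pair")
        else:
            raise AssertionError(f"{t.triplet_id}: unknown eligibility {t.eligibility}")


def annotate_and_compare(
    triplets: pd.DataFrame,
    positive_class: str = "forward",
    negative_class: str = "independence",
) -> pd.DataFrame:
    """Predictive-feature comparison between two classification groups.

    Unpaired two-sided t-tests for the continuous features (r2_ym and
    |TSS distance|) and chi-square tests for the binary flags
    (promoter membership, motif disruption, ASCA). Comparisons with a
    class below 2 members are skipped with a log entry.
    """
    a = triplets[triplets["classification"] == positive_class]
    b = triplets[triplets["classification"] == negative_class]
    rows = []
    if len(a) < 2 or len(b) < 2:
        log.info("a comparison class has < 2 members; all comparisons skipped")
        return pd.DataFrame(rows, columns=["feature", "test", "statistic", "p"])
    for feature in ("r2_ym", "tss_distance"):
        if feature not in triplets:
            continue
        va = a[feature].to_numpy(dtype=float)
        vb = b[feature].to_numpy(dtype=float)
        if feature == "tss_distance":
            va, vb = np.abs(va), np.abs(vb)
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        if len(va) < 2 or len(vb) < 2:
            log.info("feature %s: too few finite values; skipped", feature)
            continue
        stat, p = stats.ttest_ind(va, vb, equal_var=False)
        rows.append({"feature": feature, "test": "t", "statistic": float(stat),
                     "p": float(p)})
    for flag in ("in_promoter", "motif_disruption", "asca"):
        if flag not in triplets:
            continue
        fa = a[flag].dropna().astype(bool)
        fb = b[flag].dropna().astype(bool)
        if len(fa) < 2 or len(fb) < 2:
            continue
        table = np.array([[fa.sum(), (~fa).sum()], [fb.sum(), (~fb).sum()]])
        if (table.sum(axis=0) == 0).any():
            continue
        stat, p, *_ = stats.chi2_contingency(table, correction=False)
        rows.append({"feature": flag, "test": "chi2", "statistic": float(stat),
                     "p": float(p)})
    return pd.DataFrame(rows, columns=["feature", "test", "statistic", "p"])
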