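"""Plain-text readers and writers for the pipeline's artifact formats.

Coordinates are 0-based half-open internally; BED is emitted natively
and 1-based formats (VCF) are converted on write.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


def write_vcf(path: str | Path, genotypes: pd.DataFrame, variant_meta: pd.DataFrame) -> None:
    """Minimal VCF 4.2 with GT and DS fields; positions converted to 1-based."""
    vmeta = variant_meta.set_index("id" if "id" in variant_meta else "variant_id")
    samples = [f"S{i}" for i in range(genotypes.shape[0])]
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        chroms = sorted(vmeta["chrom"].unique())
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for vid in genotypes.columns:
            row = vmeta.loc[vid]
            dosages = genotypes[vid].to_numpy()
            fields = [f"{gt_codes[int(d)]}:{float(d):g}" for d in dosages]
            fh.write(f"{row['chrom']}\t{int(row['pos']) + 1}\t{vid}\tA\tG\t.\tPASS\t.\t"
                     f"GT:DS\t" + "\t".join(fields) + "\n")


def write_bed(path: str | Path, peaks: pd.DataFrame) -> None:
    peaks[["chrom", "start", "end", "peak_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "peak_id"])
    return df[["peak_id", "chrom", "start", "end"]]


def write_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phenotype_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    """Feature x sample orientation, feature ids in the first column."""
    matrix.T.rename_axis("feature_id").to_csv(path, sep="\t", float_format="%.6g")


def read_phenotype_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).T


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "seed" not in cfg:
        raise ValueError("config must carry a top-level seed")
    return cfg


def save_config(path: str | Path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
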