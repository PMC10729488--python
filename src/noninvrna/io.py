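"""Plain-text readers and writers for the pipeline's tables.

Counts travel as gene-by-sample TSV (gene id first column) or
MatrixMarket triplets with gene/sample index files; genotypes as a
minimal VCF (GT genotypes) or a dosage TSV; gene lists one id per line.
Floating-point TSVs are rounded to 10 decimals on write so file digests
are stable across runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .simulate import GenotypeTable

__all__ = [
    "write_counts_tsv",
    "read_counts_tsv",
    "write_counts_mtx",
    "read_counts_mtx",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_vcf",
    "read_vcf",
    "read_gene_list",
    "write_gene_list",
    "write_table",
    "sha256_file",
]

FLOAT_DECIMALS = 10


def write_table(df: pd.DataFrame, path, index: bool = True) -> Path:
    """TSV writer with floats rounded to 10 decimals for digest stability."""
    path = Path(path)
    df.round(FLOAT_DECIMALS).to_csv(path, sep="\t", index=index)
    return path


def write_counts_tsv(counts: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = counts.copy()
    out.index.name = "gene_id"
    return write_table(out, path)


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_mtx(counts: pd.DataFrame, prefix) -> tuple:
    """MatrixMarket triplet plus gene and sample index files."""
    prefix = Path(prefix)
    mtx = prefix.with_suffix(".mtx")
    sio.mmwrite(mtx, sparse.coo_matrix(counts.to_numpy()))
    genes = prefix.parent / (prefix.name + ".genes.txt")
    samples = prefix.parent / (prefix.name + ".samples.txt")
    genes.write_text("\n".join(counts.index) + "\n")
    samples.write_text("\n".join(counts.columns) + "\n")
    return mtx, genes, samples


def read_counts_mtx(mtx_path, genes_path, samples_path) -> pd.DataFrame:
    m = sio.mmread(mtx_path).toarray()
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    return pd.DataFrame(m, index=genes, columns=samples)


def write_dosage_tsv(geno: GenotypeTable, path) -> Path:
    path = Path(path)
    out = geno.variants[["chrom", "pos", "ref", "alt", "maf"]].join(geno.dosage)
    out.index.name = "variant"
    out.to_csv(path, sep="\t")
    return path


def read_dosage_tsv(path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"chrom": str})
    meta_cols = ["chrom", "pos", "ref", "alt", "maf"]
    variants = df[meta_cols].copy()
    variants.insert(0, "variant", variants.index)
    dosage = df.drop(columns=meta_cols)
    return GenotypeTable(dosage=dosage, variants=variants)


def write_vcf(geno: GenotypeTable, path) -> Path:
    """Minimal unphased GT-only VCF (dosage 0/1/2 -> 0/0, 0/1, 1/1)."""
    path = Path(path)
    donors = list(geno.dosage.columns)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(geno.variants["chrom"].astype(str))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(donors) + "\n")
        for vid, row in geno.variants.iterrows():
            gts = "\t".join(gt_map[int(d)] for d in geno.dosage.loc[vid])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return path


def read_vcf(path) -> GenotypeTable:
    """Read GT genotypes into a dosage table (alternate-allele counts)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    donors = list(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        alt = ",".join(rec.ALT)
        vid = rec.ID or f"var_{rec.CHROM}_{rec.POS}"
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dos = np.array([[0, 1, -1, 2][t] for t in rec.gt_types], dtype=float)
        rows.append(dos)
        freq = np.nanmean(np.where(dos < 0, np.nan, dos)) / 2.0
        meta.append(
            {
                "variant": vid,
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": alt,
                "maf": float(min(freq, 1 - freq)),
            }
        )
    variants = pd.DataFrame(meta).set_index("variant", drop=False)
    dosage = pd.DataFrame(np.array(rows), index=variants.index, columns=donors)
    return GenotypeTable(dosage=dosage, variants=variants)


def read_gene_list(path) -> list:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(genes, path) -> Path:
    path = Path(path)
    path.write_text("\n".join(genes) + "\n")
    return path


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path
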