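"""Readers and writers for every on-disk format the pipeline touches.

Coordinate conventions (see FORMATS.md in the repository root):

* internally everything is 0-based, half-open;
* ``fragments.bed`` is emitted natively in BED coordinates (0-based half-open);
* ``genes.tsv`` is a GTF-like table emitted 1-based inclusive, converted at
  this I/O boundary;
* SNP positions in ``snps_<phenotype>.tsv`` and VCF POS are 1-based.

All tables are plain tab-separated text so fixtures and pipeline outputs stay
human-readable and diffable.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end"]
FRAGMENT_COLUMNS = ["chrom", "start", "end", "frag_id"]
SNP_COLUMNS = ["rsid", "chrom", "pos", "assoc_p", "phenotype"]
CONTACT_COLUMNS = ["frag_a", "frag_b", "count"]
EQTL_COLUMNS = ["rsid", "gene_id", "tissue", "nominal_p"]
DGI_COLUMNS = ["gene_id", "drug", "source"]
TRUTH_COLUMNS = ["role", "group", "id_a", "id_b"]


class FormatError(ValueError):
    """A file does not conform to its documented format."""


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing} (found {list(df.columns)})")
    return df


# --------------------------------------------------------------------- genes
def write_genes(genes: pd.DataFrame, path: str | Path) -> None:
    """Write the gene model 1-based inclusive (GTF-like dialect)."""
    out = genes[GENE_COLUMNS].copy()
    out["start"] = out["start"].astype(int) + 1  # 0-based half-open -> 1-based inclusive
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, GENE_COLUMNS)
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    bad = df[df["start"] >= df["end"]]
    if not bad.empty:
        raise FormatError(f"{path}: gene {bad.iloc[0]['gene_id']} has start >= end")
    return df


# ----------------------------------------------------------------- fragments
def write_fragments(fragments: pd.DataFrame, path: str | Path) -> None:
    """BED: chrom, start, end, frag_id (native 0-based half-open)."""
    fragments[FRAGMENT_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_fragments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLUMNS, dtype=str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


# ---------------------------------------------------------------------- SNPs
def write_snps(snps: pd.DataFrame, path: str | Path) -> None:
    out = snps[SNP_COLUMNS].copy()
    out["pos"] = out["pos"].astype(int) + 1  # 1-based on disk
    out.to_csv(path, sep="\t", index=False)


def read_snps(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, SNP_COLUMNS)
    df["pos"] = df["pos"].astype(int) - 1
    df["assoc_p"] = df["assoc_p"].astype(float)
    return df


# ------------------------------------------------------------------ contacts
def write_contacts(contacts: pd.DataFrame, path: str | Path) -> None:
    contacts[CONTACT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_contacts(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, CONTACT_COLUMNS)
    df["count"] = df["count"].astype(int)
    return df


# ------------------------------------------------------------- eQTL table
def write_eqtl_table(assoc: pd.DataFrame, path: str | Path) -> None:
    assoc[EQTL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, EQTL_COLUMNS)
    df["nominal_p"] = df["nominal_p"].astype(float)
    return df


# ----------------------------------------------------------------------- GMT
def write_gmt(pathways: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            desc = (descriptions or {}).get(name, "synthetic pathway")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT records need name, description, >=1 gene")
            out[parts[0]] = set(parts[2:])
    return out


# ----------------------------------------------------------------------- DGI
def write_dgi(dgi: pd.DataFrame, path: str | Path) -> None:
    dgi[DGI_COLUMNS].to_csv(path, sep="\t", index=False)


def read_dgi(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, DGI_COLUMNS)


# ----------------------------------------------------------------------- VCF
def write_phased_vcf(snps: pd.DataFrame, haplotypes: np.ndarray, path: str | Path,
                     contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a minimal phased VCF 4.2.

    ``haplotypes`` is an (n_haplotypes, n_snps) 0/1 matrix whose columns are
    ordered like the rows of ``snps``; consecutive haplotype pairs become one
    diploid sample with a phased GT.
    """
    n_hap, n_snp = haplotypes.shape
    if n_snp != len(snps):
        raise FormatError(f"haplotype matrix has {n_snp} sites but {len(snps)} SNPs given")
    if n_hap % 2:
        raise FormatError("need an even number of haplotypes to form diploid samples")
    samples = [f"S{i:04d}" for i in range(n_hap // 2)]
    order = np.lexsort((snps["pos"].to_numpy(), snps["chrom"].to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=spatialqtl-simulate\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in order:
            row = snps.iloc[j]
            col = haplotypes[:, j]
            gts = "\t".join(f"{col[2 * s]}|{col[2 * s + 1]}" for s in range(n_hap // 2))
            fh.write(f"{row['chrom']}\t{int(row['pos']) + 1}\t{row['rsid']}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_phased_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a phased VCF into an (n_haplotypes, n_sites) 0/1 matrix.

    Returns the matrix and a site table (rsid, chrom, pos 0-based) whose row
    order matches the matrix columns.  Unphased genotypes raise FormatError.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    cols: list[np.ndarray] = []
    sites: list[tuple[str, str, int]] = []
    for var in vcf:
        gts = np.asarray(var.genotypes, dtype=int)
        if gts.shape[1] < 3 or not np.all(gts[:, 2] == 1):
            raise FormatError(f"{path}: site {var.ID} is not fully phased")
        cols.append(gts[:, :2].reshape(-1))
        sites.append((var.ID, var.CHROM, var.POS - 1))
    if not cols:
        raise FormatError(f"{path}: no VCF records")
    mat = np.stack(cols, axis=1).astype(np.uint8)
    table = pd.DataFrame(sites, columns=["rsid", "chrom", "pos"])
    return mat, table


# --------------------------------------------------------------------- truth
def write_truth(rows: pd.DataFrame, path: str | Path) -> None:
    rows[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, TRUTH_COLUMNS).fillna("")


# -------------------------------------------------------------- gene lists
def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
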