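"""Druggability annotation of eGenes/pathways and LD (r^2) screening of eQTLs.

r^2 is computed exactly from phased haplotypes:

    D = p_AB - p_A * p_B
    r^2 = D^2 / (p_A (1 - p_A) p_B (1 - p_B))

with all frequencies taken over the haplotype sample.  A monomorphic locus
has an undefined r^2 and is reported as missing with a warning.  The LD
screen examines every cross-phenotype pair of eQTL SNPs on the same
chromosome and reports pairs above the threshold (default r^2 > 0.8); it
annotates potentially LD-driven shared eGenes, it never filters them.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Collection, Mapping

import numpy as np
import pandas as pd


class LDError(ValueError):
    """Missing or unusable SNP in the haplotype panel."""


# ----------------------------------------------------------------- druggable
def annotate_druggable(
    egene_sets: Mapping[str, Collection[str]], dgi: pd.DataFrame
) -> tuple[dict[str, set[str]], float]:
    """Per-phenotype druggable eGenes and the global druggable fraction.

    A gene is druggable when it has >=1 drug-gene interaction row; the global
    fraction is over the union of all phenotypes' eGenes.
    """
    druggable_universe = set(dgi["gene_id"])
    per_phen = {p: set(genes) & druggable_universe for p, genes in egene_sets.items()}
    union: set[str] = set().union(*(set(g) for g in egene_sets.values())) if egene_sets else set()
    fraction = len(union & druggable_universe) / len(union) if union else 0.0
    return per_phen, fraction


def druggable_pathways(
    enriched_sets: Mapping[str, Collection[str]],
    pathways: Mapping[str, Collection[str]],
    druggable_egenes: Mapping[str, Collection[str]],
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Druggable pathways per phenotype, plus pairwise overlap records.

    A pathway is druggable for phenotype P iff it is enriched for P and
    contains >=1 of P's druggable eGenes.  Overlap rows flag the case of a
    shared druggable pathway with zero shared druggable eGenes (phenotypes
    can share a treatable pathway without sharing a target gene).
    """
    per_phen: dict[str, set[str]] = {}
    for phen, enriched in enriched_sets.items():
        dg = set(druggable_egenes.get(phen, ()))
        per_phen[phen] = {
            pw for pw in enriched if set(pathways.get(pw, ())) & dg
        }
    rows = []
    for a, b in combinations(sorted(per_phen), 2):
        shared_pw = per_phen[a] & per_phen[b]
        shared_genes = set(druggable_egenes.get(a, ())) & set(druggable_egenes.get(b, ()))
        for pw in sorted(shared_pw):
            rows.append({
                "combination": f"{a}+{b}",
                "pathway_id": pw,
                "n_shared_druggable_egenes": len(shared_genes),
                "shared_pathway_without_shared_gene": len(shared_genes) == 0,
            })
    overlap = pd.DataFrame(
        rows,
        columns=[
            "combination", "pathway_id",
            "n_shared_druggable_egenes", "shared_pathway_without_shared_gene",
        ],
    )
    return per_phen, overlap


# ------------------------------------------------------------------------ LD
class HaplotypePanel:
    """Phased 0/1 haplotypes with per-SNP chromosome lookup."""

    def __init__(self, matrix: np.ndarray, sites: pd.DataFrame):
        self.matrix = np.asarray(matrix, dtype=np.uint8)
        self.sites = sites.reset_index(drop=True)
        self.col = {rsid: i for i, rsid in enumerate(self.sites["rsid"])}
        self.chrom = dict(zip(self.sites["rsid"], self.sites["chrom"]))

    @classmethod
    def from_vcf(cls, path) -> "HaplotypePanel":
        from .formats import read_phased_vcf

        matrix, sites = read_phased_vcf(path)
        return cls(matrix, sites)

    def alleles(self, rsid: str) -> np.ndarray:
        if rsid not in self.col:
            raise LDError(f"SNP {rsid!r} absent from the haplotype panel")
        return self.matrix[:, self.col[rsid]]


def r2_from_haplotypes(a: np.ndarray, b: np.ndarray) -> float:
    """r^2 between two phased allele vectors; NaN (with warning) if monomorphic."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("allele vectors must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need >=2 haplotypes to estimate LD")
    p_a, p_b = a.mean(), b.mean()
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0.0:
        warnings.warn("monomorphic SNP: r^2 undefined, reported as missing", stacklevel=2)
        return float("nan")
    d = (a * b).mean() - p_a * p_b
    return float(d * d / denom)


def ld_r2(panel: HaplotypePanel, rsid_a: str, rsid_b: str) -> float:
    if rsid_a == rsid_b:
        raise LDError("r^2 requires two distinct SNPs")
    return r2_from_haplotypes(panel.alleles(rsid_a), panel.alleles(rsid_b))


def _pairwise_r2_matrix(ha: np.ndarray, hb: np.ndarray) -> np.ndarray:
    """r^2 between every column of ``ha`` and every column of ``hb``."""
    ha = ha.astype(np.float64)
    hb = hb.astype(np.float64)
    n = ha.shape[0]
    pa = ha.mean(axis=0)
    pb = hb.mean(axis=0)
    pab = ha.T @ hb / n
    d = pab - np.outer(pa, pb)
    denom = np.outer(pa * (1 - pa), pb * (1 - pb))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, d * d / denom, np.nan)


def screen_ld_confounding(
    eqtl_snps: Mapping[str, Collection[str]],
    panel: HaplotypePanel,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Cross-phenotype eQTL SNP pairs on the same chromosome with r^2 > threshold.

    SNPs on different chromosomes are never tested.  SNPs missing from the
    panel raise; monomorphic SNPs yield missing r^2 and cannot exceed the
    threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    rows = []
    phens = sorted(eqtl_snps)
    for pa, pb in combinations(phens, 2):
        snps_a = sorted(set(eqtl_snps[pa]))
        snps_b = sorted(set(eqtl_snps[pb]))
        for rs in (*snps_a, *snps_b):
            if rs not in panel.col:
                raise LDError(f"eQTL SNP {rs!r} absent from the haplotype panel")
        by_chrom_a: dict[str, list[str]] = {}
        for rs in snps_a:
            by_chrom_a.setdefault(panel.chrom[rs], []).append(rs)
        by_chrom_b: dict[str, list[str]] = {}
        for rs in snps_b:
            by_chrom_b.setdefault(panel.chrom[rs], []).append(rs)
        for chrom in sorted(set(by_chrom_a) & set(by_chrom_b)):
            la, lb = by_chrom_a[chrom], by_chrom_b[chrom]
            cols_a = panel.matrix[:, [panel.col[r] for r in la]]
            cols_b = panel.matrix[:, [panel.col[r] for r in lb]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r2 = _pairwise_r2_matrix(cols_a, cols_b)
            hit_i, hit_j = np.where(r2 > threshold)
            for i, j in zip(hit_i, hit_j):
                if la[i] == lb[j]:
                    continue  # same SNP driving two phenotypes is not an LD pair
                rows.append({
                    "rsid_a": la[i], "rsid_b": lb[j],
                    "phenotype_a": pa, "phenotype_b": pb,
                    "chrom": chrom, "r2": float(r2[i, j]),
                })
    return pd.DataFrame(
        rows, columns=["rsid_a", "rsid_b", "phenotype_a", "phenotype_b", "chrom", "r2"]
    )
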