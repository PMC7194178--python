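"""eQTL stage: join spatial pairs to the association table, BH-correct, and
derive per-phenotype eGene sets with cis/trans classification.

The multiple-testing scope is one joint Benjamini-Hochberg correction across
all (SNP, gene, tissue) triples tested for a given phenotype and Hi-C source
(the conservative reading of a CoDeS3D-style run); ``bh_scope="per_tissue"``
switches to a separate correction within each tissue for sensitivity
analysis.

cis/trans follows the 1 Mb convention: a call is cis when SNP and gene are on
the same chromosome and the SNP lies within ``window`` bp of the gene
(boundary inclusive), trans otherwise or when inter-chromosomal.  Distance is
anchored at the nearest gene-body edge by default (``anchor="tss"`` measures
to the annotated start instead; gene models here carry no strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_i = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j), clipped to 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def query_associations(
    pairs: pd.DataFrame, assoc: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Association rows whose (rsid, gene_id) appears in ``pairs``.

    Returns ``(tested, untested)``: ``tested`` holds every matching
    association row (one per tissue); ``untested`` lists spatial pairs with no
    row in the association table at all.
    """
    key_pairs = pairs[["rsid", "gene_id"]].drop_duplicates()
    tested = assoc.merge(key_pairs, on=["rsid", "gene_id"], how="inner")
    seen = set(zip(tested["rsid"], tested["gene_id"]))
    untested = key_pairs[
        [((r, g) not in seen) for r, g in zip(key_pairs["rsid"], key_pairs["gene_id"])]
    ].reset_index(drop=True)
    return tested.reset_index(drop=True), untested


def classify_cis_trans(
    snp_chrom, snp_pos, gene_chrom, gene_start, gene_end,
    window: int = 1_000_000, anchor: str = "edge",
):
    """Vectorised cis/trans classification.

    Returns ``(cis_trans, distance)`` arrays; distance is NaN for
    inter-chromosomal (trans) calls and 0 for SNPs inside the gene body.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    snp_chrom = np.asarray(snp_chrom, dtype=object)
    gene_chrom = np.asarray(gene_chrom, dtype=object)
    pos = np.asarray(snp_pos, dtype=np.int64)
    start = np.asarray(gene_start, dtype=np.int64)
    end = np.asarray(gene_end, dtype=np.int64)

    same = snp_chrom == gene_chrom
    if anchor == "tss":
        dist = np.abs(pos - start).astype(float)
    elif anchor == "edge":
        dist = np.zeros(pos.shape, dtype=float)
        left = pos < start
        right = pos >= end
        dist[left] = (start - pos)[left]
        # gap to the last base of the gene body (end is half-open)
        dist[right] = (pos - end + 1)[right]
    else:
        raise ValueError(f"anchor must be 'edge' or 'tss', got {anchor!r}")
    dist = np.where(same, dist, np.nan)
    cis = same & (dist <= window)
    label = np.where(cis, "cis", "trans")
    return label, dist


def process_calls(
    tested: pd.DataFrame,
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    alpha: float = 0.05,
    window: int = 1_000_000,
    anchor: str = "edge",
    bh_scope: str = "joint",
) -> pd.DataFrame:
    """Attach q-values, significance flags and cis/trans labels to tested triples."""
    calls = tested.merge(
        snps[["rsid", "chrom", "pos"]].rename(columns={"chrom": "snp_chrom"}),
        on="rsid", how="left",
    ).merge(
        genes[["gene_id", "chrom", "start", "end"]].rename(columns={"chrom": "gene_chrom"}),
        on="gene_id", how="left",
    )
    if calls["snp_chrom"].isna().any() or calls["gene_chrom"].isna().any():
        missing = calls[calls["snp_chrom"].isna() | calls["gene_chrom"].isna()]
        raise ValueError(
            f"tested triples reference unknown SNPs/genes, e.g. "
            f"{missing.iloc[0]['rsid']}/{missing.iloc[0]['gene_id']}"
        )
    calls = calls.reset_index(drop=True)
    if calls.empty:
        calls["q"] = pd.Series(dtype=float)
        calls["significant"] = pd.Series(dtype=bool)
        calls["cis_trans"] = pd.Series(dtype=object)
        calls["distance"] = pd.Series(dtype=float)
        return calls
    if bh_scope == "joint":
        calls["q"] = bh_adjust(calls["nominal_p"].to_numpy())
    elif bh_scope == "per_tissue":
        calls["q"] = np.nan
        for _, idx in calls.groupby("tissue").groups.items():
            calls.loc[idx, "q"] = bh_adjust(calls.loc[idx, "nominal_p"].to_numpy())
    else:
        raise ValueError(f"bh_scope must be 'joint' or 'per_tissue', got {bh_scope!r}")
    calls["significant"] = calls["q"] < alpha
    label, dist = classify_cis_trans(
        calls["snp_chrom"], calls["pos"], calls["gene_chrom"],
        calls["start"], calls["end"], window=window, anchor=anchor,
    )
    calls["cis_trans"] = label
    calls["distance"] = dist
    return calls


@dataclass
class EGeneSet:
    """Per-phenotype, per-Hi-C-source eGene and eQTL-SNP sets."""

    phenotype: str
    hic_source: str
    egenes: set[str] = field(default_factory=set)
    eqtl_snps: set[str] = field(default_factory=set)


def collect_egenes(
    calls: pd.DataFrame, phenotype: str, hic_source: str, alpha: float = 0.05
) -> EGeneSet:
    """Genes with >=1 call at q < alpha, and the SNPs driving them."""
    sig = calls[calls["q"] < alpha]
    return EGeneSet(
        phenotype=phenotype,
        hic_source=hic_source,
        egenes=set(sig["gene_id"]),
        eqtl_snps=set(sig["rsid"]),
    )


def summarize_proportions(
    egenesets: list[EGeneSet],
    snp_counts: dict[str, int],
    calls_by_run: dict[tuple[str, str], pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Per (phenotype, source) summary: SNP counts, eQTL fraction, cis/trans split."""
    rows = []
    for es in egenesets:
        n_snps = snp_counts[es.phenotype]
        n_eqtl = len(es.eqtl_snps)
        row = {
            "phenotype": es.phenotype,
            "hic_source": es.hic_source,
            "n_snps": n_snps,
            "n_eqtl_snps": n_eqtl,
            "eqtl_fraction": n_eqtl / n_snps if n_snps else 0.0,
            "n_egenes": len(es.egenes),
        }
        if calls_by_run is not None:
            calls = calls_by_run.get((es.phenotype, es.hic_source))
            if calls is not None:
                sig = calls[calls["significant"]]
                row["n_cis"] = int((sig["cis_trans"] == "cis").sum())
                row["n_trans"] = int((sig["cis_trans"] == "trans").sum())
        rows.append(row)
    return pd.DataFrame(rows)


def partition_by_dataset(snp_sets_by_source: dict[str, set[str]]) -> dict[str, int]:
    """Split eQTL SNPs into source-exclusive and multi-source counts.

    For two sources this is the classic (A-only, B-only, both) partition; the
    counts always sum to the size of the union.
    """
    if len(snp_sets_by_source) < 2:
        raise ValueError(
            "partition_by_dataset needs >=2 Hi-C sources; run the pipeline on both datasets"
        )
    union: set[str] = set().union(*snp_sets_by_source.values())
    out: dict[str, int] = {}
    multi = 0
    for snp in union:
        hits = [src for src, snps in snp_sets_by_source.items() if snp in snps]
        if len(hits) == 1:
            out[f"{hits[0]}_only"] = out.get(f"{hits[0]}_only", 0) + 1
        else:
            multi += 1
    for src in snp_sets_by_source:
        out.setdefault(f"{src}_only", 0)
    out["both" if len(snp_sets_by_source) == 2 else "multiple"] = multi
    out["union"] = len(union)
    return out
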