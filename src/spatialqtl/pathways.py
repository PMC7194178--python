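"""Pathway over-representation analysis (ORA) of eGene sets, cross-phenotype
pathway overlap with its own bootstrap null, and classification of shared
pathways by what drives the sharing.

ORA is the standard one-sided hypergeometric test: for a pathway with K
annotated genes in a universe of N, and an eGene set contributing n universe
genes of which k fall in the pathway, p = P(X >= k), X ~ Hypergeom(N, K, n).
The universe defaults to the genes annotated to at least one pathway in the
collection (intersected with the gene model) — the conservative
annotation-restricted choice; BH correction runs across pathways within one
phenotype.

A pathway shared between phenotypes is classified by its member eGenes:
``condition_specific`` when no member gene belongs to more than one
phenotype's eGene set, ``shared_egenes`` when every member hit is via a gene
common to >=2 phenotypes, ``mixed`` otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Collection, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .config import canon_combo, combo_label
from .overlap import OverlapResult, bootstrap_overlap, compute_intersections


@dataclass
class SharedPathwayRecord:
    pathway_id: str
    combination: tuple[str, ...]
    driver_class: str  # shared_egenes | condition_specific | mixed
    egene_breakdown: dict[str, set[str]]


def default_universe(pathways: Mapping[str, Collection[str]],
                     gene_model: Collection[str] | None = None) -> set[str]:
    """Genes annotated to >=1 pathway, optionally intersected with the gene model."""
    universe: set[str] = set()
    for genes in pathways.values():
        universe |= set(genes)
    if gene_model is not None:
        universe &= set(gene_model)
    return universe


def ora_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric ORA p-value: P(X >= k), X ~ Hypergeom(N, K, n)."""
    if K <= 0:
        return 1.0
    return min(float(hypergeom.sf(k - 1, N, K, n)), 1.0)


def ora_enrich(
    egenes: Collection[str],
    pathways: Mapping[str, Collection[str]],
    universe: Collection[str],
    alpha: float = 0.05,
    phenotype: str = "",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``egenes`` in each pathway.

    Genes outside the universe are dropped with a warning (both from the
    query set and from pathway annotations).  Returns one row per pathway
    with k, K, n, N, p, BH q and the enrichment flag at q < alpha.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    query = set(egenes)
    outside = query - uni
    if outside:
        warnings.warn(
            f"{len(outside)} eGene(s) outside the universe dropped from ORA "
            f"(e.g. {sorted(outside)[:3]})",
            stacklevel=2,
        )
    query &= uni
    N = len(uni)
    n = len(query)
    rows = []
    for pw_id, genes in pathways.items():
        pw = set(genes) & uni
        K = len(pw)
        k = len(pw & query)
        rows.append({
            "pathway_id": pw_id, "phenotype": phenotype,
            "k": k, "K": K, "n": n, "N": N, "p": ora_pvalue(k, K, n, N),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        out["enriched"] = pd.Series(dtype=bool)
        return out
    from .eqtl import bh_adjust

    out["q"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = out["q"] < alpha
    return out


def pathway_overlaps(enriched_sets: Mapping[str, Collection[str]]) -> pd.DataFrame:
    """Inclusive intersections of enriched-pathway ID sets (same semantics as eGenes)."""
    return compute_intersections(enriched_sets)


def classify_shared_pathway(
    pathway_id: str,
    pathway_genes: Collection[str],
    combination: Collection[str],
    egene_sets: Mapping[str, Collection[str]],
    enriched_sets: Mapping[str, Collection[str]],
) -> SharedPathwayRecord:
    """Classify one pathway shared by a phenotype combination.

    Requires the pathway to be enriched for every member of the combination.
    """
    combo = canon_combo(combination)
    for phen in combo:
        if pathway_id not in set(enriched_sets.get(phen, ())):
            raise ValueError(
                f"pathway {pathway_id!r} is not enriched for {phen!r}; "
                f"classification is defined only for pathways shared by the whole combination"
            )
    pw = set(pathway_genes)
    hits = {phen: pw & set(egene_sets[phen]) for phen in combo}
    all_hits: set[str] = set().union(*hits.values())
    if not all_hits:
        raise ValueError(f"pathway {pathway_id!r} has no eGene hits in {combo_label(combo)}")
    shared_genes = {g for g in all_hits if sum(g in h for h in hits.values()) >= 2}
    if not shared_genes:
        driver = "condition_specific"
    elif shared_genes == all_hits:
        driver = "shared_egenes"
    else:
        driver = "mixed"
    return SharedPathwayRecord(
        pathway_id=pathway_id,
        combination=combo,
        driver_class=driver,
        egene_breakdown=hits,
    )


def classify_all_shared(
    overlaps: pd.DataFrame,
    pathways: Mapping[str, Collection[str]],
    egene_sets: Mapping[str, Collection[str]],
    enriched_sets: Mapping[str, Collection[str]],
) -> pd.DataFrame:
    """Classify every pathway in every non-empty combination overlap."""
    rows = []
    for rec in overlaps.itertuples():
        combo = tuple(rec.combination.split("+"))
        for pw_id in sorted(filter(None, rec.members.split(";"))):
            record = classify_shared_pathway(
                pw_id, pathways[pw_id], combo, egene_sets, enriched_sets
            )
            rows.append({
                "pathway_id": pw_id,
                "combination": rec.combination,
                "driver_class": record.driver_class,
                "egene_breakdown": "|".join(
                    f"{p}:{','.join(sorted(g))}" for p, g in record.egene_breakdown.items()
                ),
            })
    return pd.DataFrame(rows, columns=["pathway_id", "combination", "driver_class", "egene_breakdown"])


def bootstrap_pathway_overlap(
    enriched_sizes: Mapping[str, int],
    pathway_background: Collection[str],
    observed: int,
    n_boot: int = 10_000,
    seed: int = 0,
    background_label: str = "all_pathways",
) -> OverlapResult:
    """Bootstrap null over pathway IDs — identical machinery to the gene case."""
    return bootstrap_overlap(
        enriched_sizes, pathway_background, observed,
        n_boot=n_boot, seed=seed, background_label=background_label,
    )
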