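"""SNP/gene-to-fragment assignment and Hi-C-supported spatial pair calling.

This stage reproduces the spatial half of a CoDeS3D-style analysis: every SNP
is placed in the restriction fragment containing it, every gene is mapped to
all fragments its body overlaps, and a (SNP, gene) pair is called *spatial*
for a Hi-C dataset when that dataset records a contact between the SNP's
fragment and any fragment of the gene.

A SNP whose own fragment overlaps a gene is treated as spatially connected to
that gene without requiring a contact row (proximity ligation cannot report
within-fragment contacts, and dropping such pairs would discard promoter
SNPs); the ``self_contact`` flag disables this rule.  Adjacent fragments are
*not* automatically in contact, and contact counts are ignored — support is
presence/absence only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class SpatialError(ValueError):
    """Inconsistent spatial inputs (non-tiling fragments, unknown IDs...)."""


def filter_snps_by_significance(snps: pd.DataFrame, alpha: float = 5e-6) -> pd.DataFrame:
    """Keep SNPs with association p <= alpha (boundary inclusive), order preserved."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    kept = snps[snps["assoc_p"] <= alpha].copy()
    if kept.empty and not snps.empty:
        warnings.warn(f"no SNPs pass the significance threshold {alpha}", stacklevel=2)
    return kept


@dataclass
class FragmentIndex:
    """Per-chromosome sorted view of a tiling restriction-fragment map."""

    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    ids: dict[str, np.ndarray]
    all_ids: set[str]

    @classmethod
    def from_frame(cls, fragments: pd.DataFrame) -> "FragmentIndex":
        starts: dict[str, np.ndarray] = {}
        ends: dict[str, np.ndarray] = {}
        ids: dict[str, np.ndarray] = {}
        for chrom, grp in fragments.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            s = grp["start"].to_numpy(dtype=np.int64)
            e = grp["end"].to_numpy(dtype=np.int64)
            if np.any(s >= e):
                raise SpatialError(f"fragment with start >= end on {chrom}")
            if np.any(s[1:] != e[:-1]):
                raise SpatialError(f"fragments on {chrom} do not tile (gap or overlap)")
            starts[chrom] = s
            ends[chrom] = e
            ids[chrom] = grp["frag_id"].to_numpy(dtype=object)
        return cls(starts, ends, ids, set(fragments["frag_id"]))

    def locate(self, chrom: str, pos: int, what: str = "position") -> str:
        """Fragment containing ``pos`` (0-based; half-open boundary -> right fragment)."""
        if chrom not in self.starts:
            raise SpatialError(f"{what} on chromosome {chrom!r} absent from the fragment map")
        s = self.starts[chrom]
        i = int(np.searchsorted(s, pos, side="right")) - 1
        if i < 0 or pos >= self.ends[chrom][i]:
            raise SpatialError(f"{what} {chrom}:{pos} outside the fragment map")
        return self.ids[chrom][i]

    def overlapping(self, chrom: str, start: int, end: int, what: str = "interval") -> list[str]:
        """All fragments overlapping the half-open interval [start, end)."""
        if chrom not in self.starts:
            raise SpatialError(f"{what} on chromosome {chrom!r} absent from the fragment map")
        s, e = self.starts[chrom], self.ends[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        if lo >= hi:
            raise SpatialError(f"{what} {chrom}:{start}-{end} outside the fragment map")
        return list(self.ids[chrom][lo:hi])


def assign_snps_to_fragments(snps: pd.DataFrame, index: FragmentIndex) -> pd.DataFrame:
    """One row per SNP: rsid -> the fragment containing its position."""
    rows = [
        (r.rsid, index.locate(r.chrom, int(r.pos), what=f"SNP {r.rsid}"))
        for r in snps.itertuples()
    ]
    return pd.DataFrame(rows, columns=["rsid", "frag_id"])


def assign_genes_to_fragments(genes: pd.DataFrame, index: FragmentIndex) -> pd.DataFrame:
    """One row per (gene, overlapping fragment)."""
    rows = [
        (r.gene_id, f)
        for r in genes.itertuples()
        for f in index.overlapping(r.chrom, int(r.start), int(r.end), what=f"gene {r.gene_id}")
    ]
    return pd.DataFrame(rows, columns=["gene_id", "frag_id"])


def canonical_pair(frag_a: str, frag_b: str) -> tuple[str, str]:
    """Orientation-free contact key: (min, max) by fragment ID."""
    return (frag_a, frag_b) if frag_a <= frag_b else (frag_b, frag_a)


def _contact_adjacency(
    contacts: pd.DataFrame, known: set[str] | None, label: str
) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for a, b in zip(contacts["frag_a"], contacts["frag_b"]):
        if known is not None:
            for f in (a, b):
                if f not in known:
                    raise SpatialError(
                        f"contact file {label!r} references unknown fragment {f!r}"
                    )
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def call_spatial_pairs(
    snp_frags: pd.DataFrame,
    gene_frags: pd.DataFrame,
    contacts: dict[str, pd.DataFrame],
    fragment_ids: set[str] | None = None,
    self_contact: bool = True,
) -> pd.DataFrame:
    """Call SNP-gene pairs supported by >=1 Hi-C dataset.

    Returns one row per supported pair with ``datasets`` a comma-joined sorted
    list of supporting dataset labels.  Output is invariant to contact row
    order and fragment-pair orientation, and pairs with empty support are
    absent.  Passing ``fragment_ids`` (the full fragment map) enables
    rejection of contact rows referencing unknown fragments.
    """
    known = fragment_ids
    genes_by_frag: dict[str, set[str]] = {}
    for g, f in zip(gene_frags["gene_id"], gene_frags["frag_id"]):
        genes_by_frag.setdefault(f, set()).add(g)

    adjacency = {
        label: _contact_adjacency(df, known, label) for label, df in contacts.items()
    }
    labels = list(contacts)

    support: dict[tuple[str, str], set[str]] = {}
    for rsid, frag in zip(snp_frags["rsid"], snp_frags["frag_id"]):
        self_genes = genes_by_frag.get(frag, set()) if self_contact else set()
        for label in labels:
            partners = adjacency[label].get(frag, set())
            genes = set(self_genes)
            for partner in partners:
                genes |= genes_by_frag.get(partner, set())
            for gene in genes:
                support.setdefault((rsid, gene), set()).add(label)

    rows = [
        (rsid, gene, ",".join(sorted(datasets)))
        for (rsid, gene), datasets in support.items()
    ]
    out = pd.DataFrame(rows, columns=["rsid", "gene_id", "datasets"])
    return out.sort_values(["rsid", "gene_id"]).reset_index(drop=True)


def pairs_for_dataset(pairs: pd.DataFrame, label: str) -> pd.DataFrame:
    """Subset of spatial pairs supported by one dataset label."""
    mask = pairs["datasets"].str.split(",").apply(lambda ds: label in ds)
    return pairs[mask].reset_index(drop=True)
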