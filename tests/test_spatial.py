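"""Spatial stage: fragment assignment boundaries, pair calling versus an
exhaustive triple-enumeration oracle, and invariance properties."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spatialqtl.spatial import (
    FragmentIndex,
    SpatialError,
    assign_genes_to_fragments,
    assign_snps_to_fragments,
    call_spatial_pairs,
    canonical_pair,
    filter_snps_by_significance,
)

from conftest import make_contacts, make_genes, make_snps


# ------------------------------------------------------------ SNP filtering
def test_significance_filter_is_boundary_inclusive():
    snps = make_snps([
        ("rs1", "chr1", 10, 1e-7, "A"),
        ("rs2", "chr1", 20, 5e-6, "A"),
        ("rs3", "chr1", 30, 6e-6, "A"),
    ])
    kept = filter_snps_by_significance(snps, alpha=5e-6)
    assert list(kept["rsid"]) == ["rs1", "rs2"]


def test_significance_filter_alpha_one_is_identity():
    snps = make_snps([("rs1", "chr1", 10, 0.9, "A"), ("rs2", "chr1", 20, 1.0, "A")])
    assert len(filter_snps_by_significance(snps, alpha=1.0)) == 2


def test_significance_filter_warns_on_empty_result():
    snps = make_snps([("rs1", "chr1", 10, 0.5, "A")])
    with pytest.warns(UserWarning, match="threshold"):
        kept = filter_snps_by_significance(snps, alpha=5e-6)
    assert kept.empty


# ------------------------------------------------------- fragment assignment
def test_snp_on_fragment_boundary_goes_to_right_fragment(toy_fragments):
    index = FragmentIndex.from_frame(toy_fragments)
    snps = make_snps([("rs1", "chr1", 4000, 1e-8, "A")])
    assert assign_snps_to_fragments(snps, index)["frag_id"].iloc[0] == "F2"


def test_gene_maps_to_all_overlapping_fragments(toy_fragments):
    index = FragmentIndex.from_frame(toy_fragments)
    genes = make_genes([("g1", "G1", "chr1", 3900, 8100)])
    frags = assign_genes_to_fragments(genes, index)
    assert sorted(frags["frag_id"]) == ["F1", "F2", "F3"]


def test_snp_on_unknown_chromosome_raises(toy_fragments):
    index = FragmentIndex.from_frame(toy_fragments)
    snps = make_snps([("rs9", "chrX", 100, 1e-8, "A")])
    with pytest.raises(SpatialError, match="rs9"):
        assign_snps_to_fragments(snps, index)


def test_position_outside_fragment_map_raises(toy_fragments):
    index = FragmentIndex.from_frame(toy_fragments)
    snps = make_snps([("rs9", "chr1", 20_000, 1e-8, "A")])
    with pytest.raises(SpatialError, match="rs9"):
        assign_snps_to_fragments(snps, index)


def test_non_tiling_fragment_map_is_rejected():
    frags = pd.DataFrame(
        [("chr1", 0, 4000, "F1"), ("chr1", 5000, 9000, "F2")],
        columns=["chrom", "start", "end", "frag_id"],
    )
    with pytest.raises(SpatialError, match="tile"):
        FragmentIndex.from_frame(frags)


# ------------------------------------------------------------- pair calling
def _toy_setup(toy_fragments):
    index = FragmentIndex.from_frame(toy_fragments)
    snps = make_snps([("rs1", "chr1", 100, 1e-8, "A")])  # fragment F1
    genes = make_genes([("g1", "G1", "chr1", 16_500, 18_000)])  # fragment F5
    return index, snps, genes


def test_contact_supported_pair(toy_fragments):
    index, snps, genes = _toy_setup(toy_fragments)
    pairs = call_spatial_pairs(
        assign_snps_to_fragments(snps, index),
        assign_genes_to_fragments(genes, index),
        {"cellline": make_contacts([("F1", "F5")])},
    )
    assert len(pairs) == 1
    assert pairs.iloc[0]["datasets"] == "cellline"


def test_self_fragment_rule_supports_pair_without_contacts(toy_fragments):
    index = FragmentIndex.from_frame(toy_fragments)
    snps = make_snps([("rs1", "chr1", 4100, 1e-8, "A")])
    genes = make_genes([("g1", "G1", "chr1", 4000, 6000)])  # same fragment F2
    pairs = call_spatial_pairs(
        assign_snps_to_fragments(snps, index),
        assign_genes_to_fragments(genes, index),
        {"cellline": make_contacts([])},
    )
    assert len(pairs) == 1 and pairs.iloc[0]["gene_id"] == "g1"
    off = call_spatial_pairs(
        assign_snps_to_fragments(snps, index),
        assign_genes_to_fragments(genes, index),
        {"cellline": make_contacts([])},
        self_contact=False,
    )
    assert off.empty


def test_pair_in_both_datasets_yields_one_row_with_both_labels(toy_fragments):
    index, snps, genes = _toy_setup(toy_fragments)
    pairs = call_spatial_pairs(
        assign_snps_to_fragments(snps, index),
        assign_genes_to_fragments(genes, index),
        {"cellline": make_contacts([("F1", "F5")]),
         "muscle": make_contacts([("F5", "F1")])},  # flipped orientation
    )
    assert len(pairs) == 1
    assert pairs.iloc[0]["datasets"] == "cellline,muscle"


def test_unknown_fragment_in_contact_file_raises(toy_fragments):
    index, snps, genes = _toy_setup(toy_fragments)
    with pytest.raises(SpatialError, match="F99"):
        call_spatial_pairs(
            assign_snps_to_fragments(snps, index),
            assign_genes_to_fragments(genes, index),
            {"cellline": make_contacts([("F1", "F99")])},
            fragment_ids={"F1", "F2", "F3", "F4", "F5"},
        )


# -------------------------------------------------- oracle + property tests
def brute_force_pairs(snps, genes, fragments, contacts, self_contact=True):
    """Direct triple enumeration of the spatial-support definition."""
    index = FragmentIndex.from_frame(fragments)
    snp_frag = {r.rsid: index.locate(r.chrom, int(r.pos)) for r in snps.itertuples()}
    gene_frags = {
        r.gene_id: set(index.overlapping(r.chrom, int(r.start), int(r.end)))
        for r in genes.itertuples()
    }
    contact_sets = {
        label: {canonical_pair(a, b) for a, b in zip(df["frag_a"], df["frag_b"])}
        for label, df in contacts.items()
    }
    support = {}
    for rs in snps["rsid"]:
        for gene in genes["gene_id"]:
            for label in contacts:
                hit = any(
                    canonical_pair(snp_frag[rs], g) in contact_sets[label]
                    for g in gene_frags[gene]
                )
                if self_contact and snp_frag[rs] in gene_frags[gene]:
                    hit = True
                if hit:
                    support.setdefault((rs, gene), set()).add(label)
    return {k: frozenset(v) for k, v in support.items()}


def random_instance(rng, n_snps=20, n_genes=20, n_frags=30, n_contacts=40):
    frag_len = 1000
    frags = pd.DataFrame(
        [("chr1", i * frag_len, (i + 1) * frag_len, f"F{i}") for i in range(n_frags)],
        columns=["chrom", "start", "end", "frag_id"],
    )
    L = n_frags * frag_len
    snps = make_snps([
        (f"rs{i}", "chr1", int(rng.integers(L)), 1e-8, "A") for i in range(n_snps)
    ])
    genes = make_genes([])
    rows = []
    for i in range(n_genes):
        start = int(rng.integers(L - 1))
        end = min(L, start + 1 + int(rng.integers(3 * frag_len)))
        rows.append((f"g{i}", f"G{i}", "chr1", start, end))
    genes = make_genes(rows)
    contacts = {}
    for label in ("cellline", "muscle"):
        pairs = set()
        for _ in range(n_contacts):
            a, b = rng.integers(n_frags, size=2)
            pairs.add(canonical_pair(f"F{a}", f"F{b}"))
        contacts[label] = make_contacts(sorted(pairs))
    return snps, genes, frags, contacts


def as_support_dict(pairs_df):
    return {
        (r.rsid, r.gene_id): frozenset(r.datasets.split(","))
        for r in pairs_df.itertuples()
    }


@pytest.mark.parametrize("instance_seed", range(20))
def test_pair_calling_matches_triple_enumeration_oracle(instance_seed):
    rng = np.random.default_rng(5000 + instance_seed)
    snps, genes, frags, contacts = random_instance(rng)
    index = FragmentIndex.from_frame(frags)
    got = as_support_dict(call_spatial_pairs(
        assign_snps_to_fragments(snps, index),
        assign_genes_to_fragments(genes, index),
        contacts,
        fragment_ids=set(frags["frag_id"]),
    ))
    want = brute_force_pairs(snps, genes, frags, contacts)
    assert got == want


def test_output_invariant_to_contact_row_order_and_orientation():
    rng = np.random.default_rng(99)
    snps, genes, frags, contacts = random_instance(rng)
    index = FragmentIndex.from_frame(frags)
    args = (assign_snps_to_fragments(snps, index), assign_genes_to_fragments(genes, index))
    base = call_spatial_pairs(*args, contacts)
    shuffled = {
        label: df.sample(frac=1, random_state=1)
        .rename(columns={"frag_a": "frag_b", "frag_b": "frag_a"})
        .reset_index(drop=True)
        for label, df in contacts.items()
    }
    again = call_spatial_pairs(*args, shuffled)
    pd.testing.assert_frame_equal(base, again)


def test_adding_contacts_never_removes_pairs():
    rng = np.random.default_rng(123)
    snps, genes, frags, contacts = random_instance(rng)
    index = FragmentIndex.from_frame(frags)
    args = (assign_snps_to_fragments(snps, index), assign_genes_to_fragments(genes, index))
    base = as_support_dict(call_spatial_pairs(*args, contacts))
    more = {
        label: pd.concat([df, make_contacts([("F0", "F29"), ("F3", "F17")])])
        for label, df in contacts.items()
    }
    bigger = as_support_dict(call_spatial_pairs(*args, more))
    for pair, datasets in base.items():
        assert datasets <= bigger[pair]
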