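"""BH step-up correctness against a brute-force oracle (and statsmodels as a
second route), cis/trans classification, eGene collection and the
per-dataset eQTL partition."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatialqtl.eqtl import (
    EGeneSet,
    bh_adjust,
    classify_cis_trans,
    collect_egenes,
    partition_by_dataset,
    process_calls,
    query_associations,
    summarize_proportions,
)

from conftest import make_genes, make_snps


# ------------------------------------------------------------------------ BH
def bh_oracle(p):
    """Literal step-up definition: q_i = min_{p_(j) >= p_i} p_(j) * m / rank(j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        cands = [p[j] * m / ranks[j] for j in range(m) if p[j] >= p[i]]
        q[i] = min(1.0, min(cands))
    return q


def test_bh_hand_computed_example():
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-15
    )


def test_bh_single_p_is_identity():
    assert bh_adjust([0.3])[0] == pytest.approx(0.3)


def test_bh_rejects_out_of_range_p():
    for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.1]):
        with pytest.raises(ValueError):
            bh_adjust(bad)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1e-12, max_value=1.0, exclude_min=False), min_size=1, max_size=60))
def test_bh_matches_oracle_and_statsmodels(pvals):
    from statsmodels.stats.multitest import multipletests

    q = bh_adjust(pvals)
    np.testing.assert_allclose(q, bh_oracle(pvals), atol=1e-12)
    _, q_sm, _, _ = multipletests(pvals, method="fdr_bh")
    np.testing.assert_allclose(q, q_sm, atol=1e-12)


def test_bh_invariant_to_input_order():
    rng = np.random.default_rng(1)
    p = rng.uniform(1e-6, 1, size=200)
    perm = rng.permutation(200)
    q = bh_adjust(p)
    q_perm = bh_adjust(p[perm])
    np.testing.assert_allclose(q[perm], q_perm, atol=1e-15)


# --------------------------------------------------------------- cis / trans
@pytest.mark.parametrize(
    "snp_chrom,pos,gene_chrom,start,end,expect,dist",
    [
        ("chr1", 1_000_000, "chr1", 1_400_000, 1_600_000, "cis", 400_000.0),
        ("chr1", 100, "chr2", 1_000, 2_000, "trans", np.nan),
        ("chr1", 0, "chr1", 1_000_000, 1_100_000, "cis", 1_000_000.0),  # exactly 1 Mb
        ("chr1", 0, "chr1", 1_000_001, 1_100_000, "trans", 1_000_001.0),
        ("chr1", 1_500, "chr1", 1_000, 2_000, "cis", 0.0),  # inside gene body
    ],
)
def test_cis_trans_examples(snp_chrom, pos, gene_chrom, start, end, expect, dist):
    label, d = classify_cis_trans([snp_chrom], [pos], [gene_chrom], [start], [end])
    assert label[0] == expect
    if np.isnan(dist):
        assert np.isnan(d[0])
    else:
        assert d[0] == dist


def test_cis_trans_rejects_nonpositive_window():
    with pytest.raises(ValueError):
        classify_cis_trans(["chr1"], [0], ["chr1"], [10], [20], window=0)


# -------------------------------------------------------- query_associations
def _assoc(rows):
    return pd.DataFrame(rows, columns=["rsid", "gene_id", "tissue", "nominal_p"])


def test_query_returns_all_tissues_and_reports_untested():
    pairs = pd.DataFrame(
        [("rs1", "g1", "cellline"), ("rs2", "g2", "cellline")],
        columns=["rsid", "gene_id", "datasets"],
    )
    assoc = _assoc([
        ("rs1", "g1", "T1", 0.01), ("rs1", "g1", "T2", 0.2), ("rs1", "g1", "T3", 0.5),
        ("rs9", "g9", "T1", 0.9),
    ])
    tested, untested = query_associations(pairs, assoc)
    assert len(tested) == 3
    assert list(untested.itertuples(index=False)) == [("rs2", "g2")]


def test_query_with_empty_pairs_is_empty():
    tested, untested = query_associations(
        pd.DataFrame(columns=["rsid", "gene_id", "datasets"]),
        _assoc([("rs1", "g1", "T1", 0.5)]),
    )
    assert tested.empty and untested.empty


# ------------------------------------------------------------ eGene sets
def _calls_fixture():
    snps = make_snps([
        ("rs1", "chr1", 100, 1e-8, "A"),
        ("rs2", "chr1", 5_000, 1e-8, "A"),
    ])
    genes = make_genes([
        ("g1", "G1", "chr1", 1_000, 2_000),
        ("g2", "G2", "chr1", 2_000_000, 2_100_000),
    ])
    tested = _assoc([
        ("rs1", "g1", "T1", 1e-6),
        ("rs1", "g1", "T2", 0.8),
        ("rs2", "g2", "T1", 0.7),
        ("rs2", "g2", "T2", 0.9),
    ])
    return tested, snps, genes


def test_gene_significant_in_one_tissue_is_an_egene():
    tested, snps, genes = _calls_fixture()
    calls = process_calls(tested, snps, genes, alpha=0.05)
    es = collect_egenes(calls, "A", "combined", alpha=0.05)
    assert es.egenes == {"g1"}
    assert es.eqtl_snps == {"rs1"}


def test_no_significant_calls_gives_empty_set_not_error():
    tested, snps, genes = _calls_fixture()
    tested["nominal_p"] = [0.5, 0.8, 0.7, 0.9]
    calls = process_calls(tested, snps, genes, alpha=0.05)
    es = collect_egenes(calls, "A", "combined", alpha=0.05)
    assert es.egenes == set() and es.eqtl_snps == set()


def test_collect_egenes_monotone_in_alpha():
    rng = np.random.default_rng(7)
    snps = make_snps([(f"rs{i}", "chr1", 100 * i, 1e-8, "A") for i in range(30)])
    genes = make_genes([(f"g{i}", f"G{i}", "chr1", 10_000 * i, 10_000 * i + 500) for i in range(30)])
    tested = _assoc([
        (f"rs{i}", f"g{rng.integers(30)}", f"T{t}", float(rng.uniform(1e-6, 1)))
        for i in range(30) for t in range(3)
    ])
    calls = process_calls(tested, snps, genes)
    prev: set[str] = set()
    for alpha in (0.01, 0.05, 0.2, 0.8):
        cur = collect_egenes(calls, "A", "x", alpha=alpha).egenes
        assert prev <= cur
        prev = cur


def test_cis_trans_is_total_partition_of_significant_calls():
    tested, snps, genes = _calls_fixture()
    calls = process_calls(tested, snps, genes)
    sig = calls[calls["significant"]]
    assert set(sig["cis_trans"]) <= {"cis", "trans"}
    assert len(sig) == (sig["cis_trans"] == "cis").sum() + (sig["cis_trans"] == "trans").sum()


def test_summary_fraction():
    es = EGeneSet("A", "cellline", egenes={"g1"}, eqtl_snps={f"rs{i}" for i in range(8)})
    summary = summarize_proportions([es], {"A": 10})
    row = summary.iloc[0]
    assert row["n_eqtl_snps"] == 8 and row["eqtl_fraction"] == pytest.approx(0.8)
    assert 0.0 <= row["eqtl_fraction"] <= 1.0


# -------------------------------------------------------------- partitioning
def test_partition_two_sources_example():
    out = partition_by_dataset({"A": {"s1", "s2"}, "B": {"s2", "s3"}})
    assert out["A_only"] == 1 and out["B_only"] == 1 and out["both"] == 1
    assert out["A_only"] + out["B_only"] + out["both"] == out["union"] == 3


def test_partition_empty_second_source():
    out = partition_by_dataset({"A": {"s1", "s2", "s3"}, "B": set()})
    assert (out["A_only"], out["B_only"], out["both"]) == (3, 0, 0)


def test_partition_disjoint_sources():
    out = partition_by_dataset({"A": {"s1"}, "B": {"s2"}})
    assert out["both"] == 0


def test_partition_requires_two_sources():
    with pytest.raises(ValueError, match="sources"):
        partition_by_dataset({"A": {"s1"}})
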