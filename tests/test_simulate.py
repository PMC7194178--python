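"""Generator contracts: tiling, referential integrity, planted structure,
distributional properties and byte-level determinism."""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from spatialqtl import formats
from spatialqtl.annotate import r2_from_haplotypes
from spatialqtl.config import SimConfig, SizingError, small_config
from spatialqtl.simulate import (
    generate_all,
    generate_genome,
    generate_phenotype_snps,
)
from spatialqtl.spatial import FragmentIndex, canonical_pair


def test_fragments_tile_each_chromosome_exactly(rng):
    cfg = SimConfig(n_chromosomes=1, chrom_length=10**6, fragment_mean_length=4000,
                    n_genes=10)
    genes, fragments = generate_genome(cfg, rng)
    assert fragments["end"].max() == 10**6
    assert int((fragments["end"] - fragments["start"]).sum()) == 10**6
    # roughly 1e6 / 4000 fragments for an exponential digest
    assert 150 <= len(fragments) <= 400
    FragmentIndex.from_frame(fragments)  # raises if not disjoint+tiling


def test_gene_records_are_valid_and_non_overlapping(rng):
    cfg = SimConfig(n_genes=50, n_chromosomes=2, chrom_length=10**6)
    genes, _ = generate_genome(cfg, rng)
    assert len(genes) == 50
    assert (genes["start"] < genes["end"]).all()
    for _, grp in genes.groupby("chrom"):
        grp = grp.sort_values("start")
        assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()


def test_genome_sizing_error_names_the_constraint(rng):
    cfg = SimConfig(n_chromosomes=1, chrom_length=10_000, n_genes=50,
                    gene_length_range=(1_000, 4_000))
    with pytest.raises(SizingError, match="chrom_length"):
        generate_genome(cfg, rng)


def test_snp_tables_have_requested_counts_disjoint_sets_and_thresholded_p(rng):
    cfg = SimConfig(phenotypes={"A": 179, "B": 18, "C": 285, "D": 135})
    snps = generate_phenotype_snps(cfg, rng)
    counts = snps["phenotype"].value_counts().to_dict()
    assert counts == {"A": 179, "B": 18, "C": 285, "D": 135}
    assert snps["rsid"].is_unique
    assert not snps.duplicated(subset=["chrom", "pos"]).any()
    assert (snps["assoc_p"] <= 5e-6).all()
    assert (snps["assoc_p"] > 0).all()


def test_identical_config_produces_byte_identical_files(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    generate_all(small_config(5), a)
    generate_all(small_config(5), b)
    names = sorted(p.name for p in a.iterdir())
    assert names == sorted(p.name for p in b.iterdir())
    match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
    assert mismatch == [] and errors == []


class TestPlantedStructure:
    def test_every_planted_edge_has_a_contact_in_some_dataset(self, small_sim):
        sim = small_sim
        index = FragmentIndex.from_frame(sim.fragments)
        snp_frag = {
            r.rsid: index.locate(r.chrom, int(r.pos)) for r in sim.snps.itertuples()
        }
        gene_frags = {
            r.gene_id: set(index.overlapping(r.chrom, int(r.start), int(r.end)))
            for r in sim.genes.itertuples()
        }
        contact_sets = {
            label: {canonical_pair(a, b) for a, b in zip(df["frag_a"], df["frag_b"])}
            for label, df in sim.contacts.items()
        }
        for phen, edges in sim.truth.edges.items():
            for rs, gene in edges:
                possible = {canonical_pair(snp_frag[rs], g) for g in gene_frags[gene]}
                assert any(
                    possible & pairs for pairs in contact_sets.values()
                ), f"planted edge ({rs}, {gene}) unsupported by any dataset"

    def test_zero_density_dataset_never_supports_that_phenotypes_edges(self, small_sim):
        sim = small_sim
        # 'muscle' is configured with zero density for MG
        index = FragmentIndex.from_frame(sim.fragments)
        snp_frag = {
            r.rsid: index.locate(r.chrom, int(r.pos)) for r in sim.snps.itertuples()
        }
        gene_frags = {
            r.gene_id: set(index.overlapping(r.chrom, int(r.start), int(r.end)))
            for r in sim.genes.itertuples()
        }
        muscle = {
            canonical_pair(a, b)
            for a, b in zip(sim.contacts["muscle"]["frag_a"], sim.contacts["muscle"]["frag_b"])
        }
        for rs, gene in sim.truth.edges["MG"]:
            possible = {canonical_pair(snp_frag[rs], g) for g in gene_frags[gene]}
            assert not (possible & muscle)

    def test_contacts_are_canonical_and_unique(self, small_sim):
        for df in small_sim.contacts.values():
            assert (df["frag_a"] <= df["frag_b"]).all()
            assert not df.duplicated(subset=["frag_a", "frag_b"]).any()

    def test_some_planted_pairs_are_dataset_specific(self, small_sim):
        sim = small_sim
        index = FragmentIndex.from_frame(sim.fragments)
        snp_frag = {
            r.rsid: index.locate(r.chrom, int(r.pos)) for r in sim.snps.itertuples()
        }
        gene_frags = {
            r.gene_id: set(index.overlapping(r.chrom, int(r.start), int(r.end)))
            for r in sim.genes.itertuples()
        }
        contact_sets = {
            label: {canonical_pair(a, b) for a, b in zip(df["frag_a"], df["frag_b"])}
            for label, df in sim.contacts.items()
        }
        supported_by = []
        for phen, edges in sim.truth.edges.items():
            for rs, gene in edges:
                possible = {canonical_pair(snp_frag[rs], g) for g in gene_frags[gene]}
                supported_by.append(
                    frozenset(l for l, pairs in contact_sets.items() if possible & pairs)
                )
        assert any(len(s) == 1 for s in supported_by), "no dataset-specific planted pair"

    def test_planted_edges_have_subsignificant_eqtl_p(self, small_sim):
        sim = small_sim
        min_p = sim.eqtl.groupby(["rsid", "gene_id"])["nominal_p"].min()
        for edges in sim.truth.edges.values():
            for rs, gene in edges:
                assert min_p[(rs, gene)] < 0.05

    def test_shared_egenes_subset_of_member_sets(self, small_sim):
        truth = small_sim.truth
        for combo, genes in truth.shared_egenes.items():
            for phen in combo:
                assert genes <= truth.egenes[phen]

    def test_planted_pathways_have_condition_specific_hits_from_all_members(self, small_sim):
        sim = small_sim
        for combo, pw_ids in sim.truth.cooccurring_pathways.items():
            for pw_id in pw_ids:
                members = set(sim.pathways[pw_id])
                hits = {p: members & sim.truth.egenes[p] for p in combo}
                assert all(hits.values()), "a member phenotype contributes no eGene"
                for a in combo:
                    for b in combo:
                        if a < b:
                            assert not (hits[a] & hits[b]), "shared gene in planted pathway"

    def test_gmt_referential_integrity_and_count(self, small_sim):
        sim = small_sim
        assert len(sim.pathways) == sim.config.n_pathways
        gene_ids = set(sim.genes["gene_id"])
        for members in sim.pathways.values():
            assert set(members) <= gene_ids

    def test_planted_ld_pairs_reach_high_r2(self, small_sim):
        sim = small_sim
        col = {rs: j for j, rs in enumerate(sim.snps["rsid"])}
        assert sim.truth.ld_pairs, "no planted LD pair"
        for pair in sim.truth.ld_pairs:
            r2 = r2_from_haplotypes(
                sim.haplotypes[:, col[pair["rsid_a"]]],
                sim.haplotypes[:, col[pair["rsid_b"]]],
            )
            assert r2 > 0.8


def test_decoy_pvalues_are_uniform():
    """KS check on >=1e4 decoy nominal p-values under the default (floor 0)."""
    cfg = small_config(29)
    cfg.n_decoy_pairs = 2_000  # 2000 pairs x 6 tissues = 12k decoy p-values
    sim = generate_all(cfg)
    planted = sim.truth.all_edges()
    mask = [
        (rs, g) not in planted
        for rs, g in zip(sim.eqtl["rsid"], sim.eqtl["gene_id"])
    ]
    decoy_p = sim.eqtl.loc[mask, "nominal_p"].to_numpy()
    assert len(decoy_p) >= 10_000
    assert kstest(decoy_p, "uniform").pvalue > 0.01


def test_cross_chromosome_snps_are_in_linkage_equilibrium():
    cfg = small_config(31)
    cfg.n_haplotypes = 1_000
    sim = generate_all(cfg)
    snps = sim.snps.reset_index(drop=True)
    by_chrom = snps.groupby("chrom").groups
    chroms = sorted(by_chrom)
    checked = 0
    for i in by_chrom[chroms[0]][:15]:
        for j in by_chrom[chroms[1]][:15]:
            r2 = r2_from_haplotypes(sim.haplotypes[:, i], sim.haplotypes[:, j])
            assert r2 < 0.2
            checked += 1
    assert checked > 0


def test_vcf_site_count_equals_snp_count(small_sim):
    sim = small_sim
    mat, sites = formats.read_phased_vcf(Path(sim.out_dir) / "haplotypes.vcf")
    assert len(sites) == len(sim.snps)
    assert mat.shape == (sim.config.n_haplotypes, len(sim.snps))


def test_druggable_fraction_scales_with_config():
    cfg = small_config(17)
    cfg.n_genes = 1_000
    cfg.n_chromosomes = 6
    cfg.chrom_length = 2_000_000
    sim = generate_all(cfg)
    druggable = sim.dgi["gene_id"].nunique()
    # binomial(1000, 0.13): allow +/- 4 sd
    sd = np.sqrt(1000 * 0.13 * 0.87)
    assert abs(druggable - 130) < 4 * sd
    assert set(sim.dgi["gene_id"]) <= set(sim.genes["gene_id"])


def test_zero_druggable_fraction_gives_empty_table():
    cfg = small_config(3)
    cfg.druggable_fraction = 0.0
    sim = generate_all(cfg)
    assert sim.dgi.empty


def test_zero_eqtl_fraction_phenotype_has_no_planted_egenes():
    cfg = small_config(3)
    cfg.planted_eqtl_fraction = {"GS": 0.6, "MG": 0.5, "MS": 0.6, "ALS": 0.0}
    cfg.planted_pathway_cooccurrence = {("GS", "MG", "MS"): 1}
    cfg.validate()
    sim = generate_all(cfg)
    assert sim.truth.egenes["ALS"] == set()


def test_truth_roundtrip_through_tsv(small_sim, tmp_path):
    from spatialqtl.simulate import TruthTable

    path = tmp_path / "truth.tsv"
    formats.write_truth(small_sim.truth.to_frame(), path)
    back = TruthTable.from_frame(formats.read_truth(path))
    assert back.egenes == small_sim.truth.egenes
    assert back.eqtl_snps == small_sim.truth.eqtl_snps
    assert back.shared_egenes == small_sim.truth.shared_egenes
    assert back.cooccurring_pathways == small_sim.truth.cooccurring_pathways
    got = {(p["rsid_a"], p["rsid_b"]) for p in back.ld_pairs}
    want = {(p["rsid_a"], p["rsid_b"]) for p in small_sim.truth.ld_pairs}
    assert got == want
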