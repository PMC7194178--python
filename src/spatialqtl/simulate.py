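"""Synthetic-data generator with planted ground truth.

Emits every input the pipeline consumes — gene models, a tiling
restriction-fragment map, per-phenotype GWAS SNP tables, per-dataset Hi-C
fragment-contact lists, a GTEx-like multi-tissue association table, a GMT
pathway collection, a drug-gene interaction table and phased haplotypes —
together with a truth file recording what was planted: the true eGenes per
phenotype, truly shared eGenes per combination, truly co-occurring pathways,
and high-LD cross-phenotype SNP pairs.

Planting guarantees (all verified by the test suite):

* every true (SNP, eGene) edge has >=1 Hi-C contact in >=1 dataset and a
  sub-0.05 nominal association p in >=1 tissue;
* phenotype SNP sets are pairwise disjoint;
* planted co-occurring pathways contain condition-specific true eGenes from
  every member phenotype and no gene shared between members, so their
  driver class is ``condition_specific`` by construction;
* planted LD pairs share a haplotype block and reach r^2 > 0.8 (exactly 1
  when the copy noise is zero).

Identical configuration (including seed) produces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats
from .config import Combo, ConfigError, SimConfig, SizingError, combo_label
from .spatial import FragmentIndex, assign_snps_to_fragments, call_spatial_pairs, canonical_pair

_RS_BASE = 100_000


@dataclass
class TruthTable:
    """Planted ground truth, round-trippable through truth.tsv."""

    egenes: dict[str, set[str]] = field(default_factory=dict)
    eqtl_snps: dict[str, set[str]] = field(default_factory=dict)
    edges: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    specific_egenes: dict[str, list[str]] = field(default_factory=dict)
    shared_egenes: dict[Combo, set[str]] = field(default_factory=dict)
    cooccurring_pathways: dict[Combo, set[str]] = field(default_factory=dict)
    ld_pairs: list[dict] = field(default_factory=list)

    def all_edges(self) -> set[tuple[str, str]]:
        return {e for edges in self.edges.values() for e in edges}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for phen in sorted(self.egenes):
            for g in sorted(self.egenes[phen]):
                rows.append(("egene", phen, g, ""))
        for phen in sorted(self.eqtl_snps):
            for rs in sorted(self.eqtl_snps[phen]):
                rows.append(("eqtl_snp", phen, rs, ""))
        for phen in sorted(self.edges):
            for rs, g in sorted(self.edges[phen]):
                rows.append(("edge", phen, rs, g))
        for combo in sorted(self.shared_egenes):
            for g in sorted(self.shared_egenes[combo]):
                rows.append(("shared_egene", combo_label(combo), g, ""))
        for combo in sorted(self.cooccurring_pathways):
            for pw in sorted(self.cooccurring_pathways[combo]):
                rows.append(("cooccur_pathway", combo_label(combo), pw, ""))
        for pair in self.ld_pairs:
            rows.append((
                "ld_pair",
                f"{pair['phenotype_a']}+{pair['phenotype_b']}",
                pair["rsid_a"],
                pair["rsid_b"],
            ))
        return pd.DataFrame(rows, columns=formats.TRUTH_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TruthTable":
        truth = cls()
        for rec in df.itertuples():
            if rec.role == "egene":
                truth.egenes.setdefault(rec.group, set()).add(rec.id_a)
            elif rec.role == "eqtl_snp":
                truth.eqtl_snps.setdefault(rec.group, set()).add(rec.id_a)
            elif rec.role == "edge":
                truth.edges.setdefault(rec.group, []).append((rec.id_a, rec.id_b))
            elif rec.role == "shared_egene":
                combo = tuple(rec.group.split("+"))
                truth.shared_egenes.setdefault(combo, set()).add(rec.id_a)
            elif rec.role == "cooccur_pathway":
                combo = tuple(rec.group.split("+"))
                truth.cooccurring_pathways.setdefault(combo, set()).add(rec.id_a)
            elif rec.role == "ld_pair":
                pa, pb = rec.group.split("+")
                truth.ld_pairs.append({
                    "rsid_a": rec.id_a, "rsid_b": rec.id_b,
                    "phenotype_a": pa, "phenotype_b": pb,
                })
        return truth


@dataclass
class SimOutput:
    config: SimConfig
    genes: pd.DataFrame
    fragments: pd.DataFrame
    snps: pd.DataFrame  # all phenotypes, with a phenotype column
    contacts: dict[str, pd.DataFrame]
    eqtl: pd.DataFrame
    pathways: dict[str, list[str]]
    dgi: pd.DataFrame
    haplotypes: np.ndarray  # (n_haplotypes, n_snps) aligned with snps row order
    truth: TruthTable
    out_dir: Path | None = None


# ------------------------------------------------------------------- genome
def generate_genome(cfg: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene model + tiling fragment map.

    Fragments tile each chromosome exactly (lengths roughly exponential
    around the configured mean, emulating a restriction digest); genes are
    placed without overlap, uniformly over the free space of each chromosome.
    """
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    L = cfg.chrom_length

    frag_rows = []
    counter = 0
    min_len = max(200, cfg.fragment_mean_length // 10)
    max_len = 6 * cfg.fragment_mean_length
    for chrom in chroms:
        pos = 0
        while pos < L:
            length = int(np.clip(rng.exponential(cfg.fragment_mean_length), min_len, max_len))
            length = min(length, L - pos)
            counter += 1
            frag_rows.append((chrom, pos, pos + length, f"F{counter:06d}"))
            pos += length
    fragments = pd.DataFrame(frag_rows, columns=formats.FRAGMENT_COLUMNS)

    lo, hi = cfg.gene_length_range
    base, extra = divmod(cfg.n_genes, cfg.n_chromosomes)
    gene_rows = []
    gid = 0
    for ci, chrom in enumerate(chroms):
        k = base + (1 if ci < extra else 0)
        if k == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=k)
        free = L - int(lengths.sum())
        if free < 0:
            raise SizingError(
                f"chrom_length {L} too small to host {k} genes totalling "
                f"{int(lengths.sum())} bp on {chrom}; reduce n_genes or gene lengths"
            )
        offsets = np.sort(rng.integers(0, free + 1, size=k))
        starts = offsets + np.concatenate(([0], np.cumsum(lengths)[:-1]))
        for j in range(k):
            gid += 1
            gene_rows.append((
                f"G{gid:05d}", f"GENE{gid}", chrom, int(starts[j]), int(starts[j] + lengths[j]),
            ))
    genes = pd.DataFrame(gene_rows, columns=formats.GENE_COLUMNS)
    return genes, fragments


# --------------------------------------------------------------------- SNPs
def generate_phenotype_snps(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-phenotype SNP tables: unique rsIDs, disjoint sets, p <= threshold."""
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    total = sum(cfg.phenotypes.values())
    if total > cfg.n_chromosomes * cfg.chrom_length:
        raise SizingError(
            f"{total} SNPs requested but the genome has only "
            f"{cfg.n_chromosomes * cfg.chrom_length} positions"
        )
    taken: set[tuple[str, int]] = set()
    rows = []
    idx = 0
    for phen, n in cfg.phenotypes.items():
        for _ in range(n):
            while True:
                chrom = chroms[int(rng.integers(cfg.n_chromosomes))]
                pos = int(rng.integers(cfg.chrom_length))
                if (chrom, pos) not in taken:
                    taken.add((chrom, pos))
                    break
            idx += 1
            p = cfg.gwas_p_threshold * 10 ** (-float(rng.uniform(0.0, 4.0)))
            rows.append((f"rs{_RS_BASE + idx}", chrom, pos, p, phen))
    return pd.DataFrame(rows, columns=formats.SNP_COLUMNS)


# -------------------------------------------------------------------- truth
def _gene_distance(pos: int, start: int, end: int) -> int:
    if start <= pos < end:
        return 0
    return start - pos if pos < start else pos - end + 1


def plant_truth(
    cfg: SimConfig,
    genes: pd.DataFrame,
    snps: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[TruthTable, pd.DataFrame]:
    """Choose true eQTL SNPs, plant SNP->eGene edges (shared first, then
    condition-specific, preferring cis targets), and co-locate planted LD
    pairs in one haplotype block (repositioning the second SNP).

    Returns the truth table and the (possibly repositioned) SNP table.
    """
    snps = snps.copy().reset_index(drop=True)
    truth = TruthTable()
    pos_of = dict(zip(snps["rsid"], snps["pos"]))
    chrom_of = dict(zip(snps["rsid"], snps["chrom"]))

    for phen in cfg.phenotypes:
        rsids = snps.loc[snps["phenotype"] == phen, "rsid"].tolist()
        n_eqtl = cfg.n_eqtl_snps(phen)
        chosen = sorted(map(str, rng.choice(rsids, size=n_eqtl, replace=False))) if n_eqtl else []
        truth.eqtl_snps[phen] = set(chosen)
        truth.edges[phen] = []

    eqtl_order = {phen: sorted(truth.eqtl_snps[phen]) for phen in cfg.phenotypes}

    # --- planted LD pairs: move partner SNPs into a shared haplotype block
    taken_positions = {(c, p) for c, p in zip(snps["chrom"], snps["pos"])}
    used_in_ld: set[str] = set()
    for combo in sorted(cfg.planted_ld_pairs):
        if len(combo) != 2:
            raise ConfigError(f"planted_ld_pairs entries must be phenotype pairs, got {combo}")
        pa, pb = combo
        for _ in range(cfg.planted_ld_pairs[combo]):
            cand_a = [r for r in eqtl_order[pa] if r not in used_in_ld]
            cand_b = [r for r in eqtl_order[pb] if r not in used_in_ld]
            if not cand_a or not cand_b:
                raise ConfigError(
                    f"not enough free eQTL SNPs to plant an LD pair for {combo_label(combo)}"
                )
            rs_a = cand_a[int(rng.integers(len(cand_a)))]
            rs_b = cand_b[int(rng.integers(len(cand_b)))]
            chrom = chrom_of[rs_a]
            block = pos_of[rs_a] // cfg.ld_block_length
            blk_lo = block * cfg.ld_block_length
            blk_hi = min(blk_lo + cfg.ld_block_length, cfg.chrom_length)
            while True:
                new_pos = int(rng.integers(blk_lo, blk_hi))
                if (chrom, new_pos) not in taken_positions:
                    break
            taken_positions.discard((chrom_of[rs_b], pos_of[rs_b]))
            taken_positions.add((chrom, new_pos))
            snps.loc[snps["rsid"] == rs_b, ["chrom", "pos"]] = [chrom, new_pos]
            chrom_of[rs_b], pos_of[rs_b] = chrom, new_pos
            used_in_ld.update((rs_a, rs_b))
            truth.ld_pairs.append({
                "rsid_a": rs_a, "rsid_b": rs_b, "phenotype_a": pa, "phenotype_b": pb,
            })

    # --- gene planting
    gene_pool = genes.set_index("gene_id")
    unused = sorted(gene_pool.index)
    unused_set = set(unused)
    genes_by_chrom: dict[str, pd.DataFrame] = {
        chrom: grp.sort_values("start") for chrom, grp in genes.groupby("chrom")
    }
    load: dict[str, int] = {rs: 0 for phen in cfg.phenotypes for rs in eqtl_order[phen]}

    def pick_snp_for_gene(phen: str, gene_id: str) -> str:
        row = gene_pool.loc[gene_id]
        candidates = [rs for rs in eqtl_order[phen] if load[rs] < cfg.genes_per_snp_cap]
        if not candidates:
            raise ConfigError(
                f"phenotype {phen!r} ran out of eQTL SNP capacity while planting eGenes"
            )
        scored = []
        for rs in candidates:
            if chrom_of[rs] == row["chrom"]:
                dist = _gene_distance(pos_of[rs], int(row["start"]), int(row["end"]))
                cis = 0 if dist <= cfg.cis_window else 1
            else:
                dist, cis = 10**12, 2
            scored.append((cis, load[rs], dist, rs))
        scored.sort()
        return scored[0][3]

    def pick_cis_gene(phen: str, rs: str) -> str | None:
        chrom = chrom_of[rs]
        if chrom not in genes_by_chrom:
            return None
        grp = genes_by_chrom[chrom]
        near = grp[
            (grp["start"] - cfg.cis_window <= pos_of[rs])
            & (grp["end"] + cfg.cis_window > pos_of[rs])
        ]
        options = [g for g in near["gene_id"] if g in unused_set]
        if not options:
            return None
        return options[int(rng.integers(len(options)))]

    for combo in sorted(cfg.planted_shared_egenes):
        count = cfg.planted_shared_egenes[combo]
        truth.shared_egenes[combo] = set()
        for _ in range(count):
            options = sorted(unused_set)
            if not options:
                raise SizingError("gene universe exhausted while planting shared eGenes")
            gene_id = options[int(rng.integers(len(options)))]
            unused_set.discard(gene_id)
            for phen in combo:
                rs = pick_snp_for_gene(phen, gene_id)
                truth.edges[phen].append((rs, gene_id))
                load[rs] += 1
            truth.shared_egenes[combo].add(gene_id)

    for phen in cfg.phenotypes:
        # every chosen eQTL SNP must regulate >=1 gene (shared planting prefers
        # cis SNPs and can stack, leaving some SNPs bare); min-load selection
        # below fills the bare SNPs first
        zero_load = sum(1 for rs in eqtl_order[phen] if load[rs] == 0)
        n_specific = max(cfg.n_specific_egenes(phen), zero_load)
        truth.specific_egenes[phen] = []
        for _ in range(n_specific):
            candidates = [rs for rs in eqtl_order[phen] if load[rs] < cfg.genes_per_snp_cap]
            if not candidates:
                raise ConfigError(
                    f"phenotype {phen!r} ran out of eQTL SNP capacity while planting eGenes"
                )
            rs = min(candidates, key=lambda r: (load[r], r))
            gene_id = None
            if rng.random() < cfg.cis_fraction:
                gene_id = pick_cis_gene(phen, rs)
            if gene_id is None:
                options = sorted(unused_set)
                if not options:
                    raise SizingError("gene universe exhausted while planting specific eGenes")
                gene_id = options[int(rng.integers(len(options)))]
            unused_set.discard(gene_id)
            truth.edges[phen].append((rs, gene_id))
            load[rs] += 1
            truth.specific_egenes[phen].append(gene_id)

    for phen in cfg.phenotypes:
        truth.egenes[phen] = {g for _, g in truth.edges[phen]}

    return truth, snps


def derive_ld_truth(cfg: SimConfig, snps: pd.DataFrame, truth: TruthTable) -> None:
    """Record every cross-phenotype pair of true eQTL SNPs sharing a haplotype
    block as a planted high-LD pair.

    The haplotype generator copies all SNPs of one (chromosome, block) window
    from the same founder, so explicitly planted pairs and accidental
    same-block co-locations are equally high-LD; the truth file lists both,
    which is exactly what the LD screen recovers under noise-free copying.
    """
    block = {
        rec.rsid: (rec.chrom, int(rec.pos) // cfg.ld_block_length)
        for rec in snps.itertuples()
    }
    pairs = []
    phens = sorted(truth.eqtl_snps)
    for i, pa in enumerate(phens):
        for pb in phens[i + 1:]:
            for ra in sorted(truth.eqtl_snps[pa]):
                for rb in sorted(truth.eqtl_snps[pb]):
                    if block[ra] == block[rb]:
                        pairs.append({
                            "rsid_a": ra, "rsid_b": rb,
                            "phenotype_a": pa, "phenotype_b": pb,
                        })
    truth.ld_pairs = pairs


# ------------------------------------------------------------------ contacts
def generate_contacts(
    cfg: SimConfig,
    genes: pd.DataFrame,
    fragments: pd.DataFrame,
    snps: pd.DataFrame,
    truth: TruthTable,
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Per-dataset fragment-contact lists.

    Every planted (SNP, eGene) edge is supported by >=1 dataset; dataset
    membership is Bernoulli with probability ``density`` (per-phenotype
    overridable), with a deterministic fallback to the densest eligible
    dataset so no planted edge is orphaned.  Background contacts are added at
    dataset-specific density and never collide with planted edges of
    phenotypes excluded from that dataset.
    """
    index = FragmentIndex.from_frame(fragments)
    snp_frag = dict(zip(
        snps["rsid"],
        assign_snps_to_fragments(snps, index)["frag_id"],
    ))
    gene_frags = {
        r.gene_id: index.overlapping(r.chrom, int(r.start), int(r.end), what=f"gene {r.gene_id}")
        for r in genes.itertuples()
    }
    phen_of = dict(zip(snps["rsid"], snps["phenotype"]))

    pairs: dict[str, set[tuple[str, str]]] = {d.label: set() for d in cfg.datasets}
    forbidden: dict[str, set[tuple[str, str]]] = {d.label: set() for d in cfg.datasets}

    all_edges = sorted(self_edges := truth.all_edges())
    for rs, gene in all_edges:
        phen = phen_of[rs]
        frags = gene_frags[gene]
        gfrag = frags[int(rng.integers(len(frags)))]
        pair = canonical_pair(snp_frag[rs], gfrag)
        members = [
            d for d in cfg.datasets if rng.random() < d.planted_inclusion_prob(phen)
        ]
        if not members:
            eligible = [d for d in cfg.datasets if d.planted_inclusion_prob(phen) > 0]
            members = [max(eligible, key=lambda d: d.planted_inclusion_prob(phen))]
        for d in members:
            pairs[d.label].add(pair)
        for d in cfg.datasets:
            if d.planted_inclusion_prob(phen) == 0:
                for g in gene_frags[gene]:
                    forbidden[d.label].add(canonical_pair(snp_frag[rs], g))

    frag_ids = fragments["frag_id"].to_numpy(dtype=object)
    genome_mb = cfg.n_chromosomes * cfg.chrom_length / 1e6
    out: dict[str, pd.DataFrame] = {}
    for d in cfg.datasets:
        n_bg = int(round(d.density * cfg.background_contacts_per_mb * genome_mb))
        bag = pairs[d.label]
        target = len(bag) + n_bg
        attempts = 0
        while len(bag) < target and attempts < 50 * max(n_bg, 1):
            attempts += 1
            i, j = rng.integers(len(frag_ids), size=2)
            if i == j:
                continue
            pair = canonical_pair(frag_ids[i], frag_ids[j])
            if pair in forbidden[d.label]:
                continue
            bag.add(pair)
        rows = sorted(bag)
        counts = rng.integers(1, 50, size=len(rows))
        out[d.label] = pd.DataFrame(
            {
                "frag_a": [a for a, _ in rows],
                "frag_b": [b for _, b in rows],
                "count": counts,
            }
        )
    return out


# ---------------------------------------------------------------- eQTL table
def generate_eqtl_table(
    cfg: SimConfig,
    genes: pd.DataFrame,
    fragments: pd.DataFrame,
    snps: pd.DataFrame,
    truth: TruthTable,
    contacts: dict[str, pd.DataFrame],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """GTEx-like association table over (variant, gene, tissue).

    Planted edges receive a strongly sub-significant nominal p in >=1 tissue;
    everything else — spatially plausible non-planted pairs (covered at
    ``assoc_coverage``) and random decoy pairs padding the BH denominator —
    draws p ~ Uniform(decoy_p_floor, 1).
    """
    tissues = [f"T{i + 1:02d}" for i in range(cfg.n_tissues)]
    index = FragmentIndex.from_frame(fragments)
    snp_frags = assign_snps_to_fragments(snps, index)
    from .spatial import assign_genes_to_fragments

    gene_frags = assign_genes_to_fragments(genes, index)
    plausible = call_spatial_pairs(snp_frags, gene_frags, contacts,
                                   fragment_ids=set(fragments["frag_id"]))
    planted = truth.all_edges()

    lo_e, hi_e = cfg.eqtl_sig_exponent_range
    floor = cfg.decoy_p_floor

    def uniform_block(n_pairs: int) -> np.ndarray:
        return floor + (1.0 - floor) * rng.random((n_pairs, cfg.n_tissues))

    rows_rs: list[str] = []
    rows_gene: list[str] = []
    rows_tissue: list[str] = []
    rows_p: list[float] = []

    for rs, gene in sorted(planted):
        n_sig = max(1, int(rng.binomial(cfg.n_tissues, cfg.sig_tissue_fraction)))
        sig_idx = set(rng.choice(cfg.n_tissues, size=n_sig, replace=False).tolist())
        for t_i, tissue in enumerate(tissues):
            if t_i in sig_idx:
                p = 10.0 ** (-float(rng.uniform(lo_e, hi_e)))
            else:
                p = floor + (1.0 - floor) * float(rng.random())
            rows_rs.append(rs)
            rows_gene.append(gene)
            rows_tissue.append(tissue)
            rows_p.append(p)

    covered = set(planted)
    extra_pairs: list[tuple[str, str]] = []
    for rec in plausible.itertuples():
        pair = (rec.rsid, rec.gene_id)
        if pair in covered:
            continue
        if rng.random() < cfg.assoc_coverage:
            extra_pairs.append(pair)
            covered.add(pair)

    all_rsids = snps["rsid"].tolist()
    gene_ids = genes["gene_id"].tolist()
    missing_genes = sorted(set(gene_ids) - {g for _, g in covered})
    for gene in missing_genes:
        rs = all_rsids[int(rng.integers(len(all_rsids)))]
        if (rs, gene) not in covered:
            extra_pairs.append((rs, gene))
            covered.add((rs, gene))
    n_decoy_left = max(0, cfg.resolved_decoy_pairs() - len(missing_genes))
    attempts = 0
    added = 0
    while added < n_decoy_left and attempts < 20 * max(n_decoy_left, 1):
        attempts += 1
        rs = all_rsids[int(rng.integers(len(all_rsids)))]
        gene = gene_ids[int(rng.integers(len(gene_ids)))]
        if (rs, gene) in covered:
            continue
        covered.add((rs, gene))
        extra_pairs.append((rs, gene))
        added += 1

    if extra_pairs:
        block = uniform_block(len(extra_pairs))
        for i, (rs, gene) in enumerate(extra_pairs):
            rows_rs.extend([rs] * cfg.n_tissues)
            rows_gene.extend([gene] * cfg.n_tissues)
            rows_tissue.extend(tissues)
            rows_p.extend(block[i].tolist())

    return pd.DataFrame(
        {"rsid": rows_rs, "gene_id": rows_gene, "tissue": rows_tissue, "nominal_p": rows_p}
    )


# ------------------------------------------------------------------ pathways
def generate_pathways(
    cfg: SimConfig,
    genes: pd.DataFrame,
    truth: TruthTable,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """GMT collection with planted co-occurring pathways.

    Planted pathways hold condition-specific true eGenes from every member
    phenotype (``pathway_hits_per_phenotype`` each, capped by availability)
    and no gene shared between members; if needed they are padded to the
    minimum size with genes that are not eGenes of any phenotype.
    """
    gene_ids = genes["gene_id"].tolist()
    lo, hi = cfg.pathway_size_range
    total_planted = sum(cfg.planted_pathway_cooccurrence.values())
    if total_planted > cfg.n_pathways:
        raise ConfigError(
            f"{total_planted} planted pathways exceed n_pathways={cfg.n_pathways}"
        )
    all_egenes: set[str] = set().union(*truth.egenes.values()) if truth.egenes else set()
    neutral = sorted(set(gene_ids) - all_egenes)

    planted_slots = sorted(
        rng.choice(cfg.n_pathways, size=total_planted, replace=False).tolist()
    )
    planted_members: list[list[str]] = []
    slot_combo: dict[int, Combo] = {}
    si = 0
    for combo in sorted(cfg.planted_pathway_cooccurrence):
        for _ in range(cfg.planted_pathway_cooccurrence[combo]):
            members: list[str] = []
            for phen in combo:
                pool = sorted(set(truth.specific_egenes.get(phen, [])) - set(members))
                if not pool:
                    raise ConfigError(
                        f"phenotype {phen!r} has no condition-specific eGenes to plant "
                        f"into a co-occurring pathway"
                    )
                n_hits = min(cfg.pathway_hits_per_phenotype, len(pool))
                picked = rng.choice(pool, size=n_hits, replace=False).tolist()
                members.extend(picked)
            if len(members) > hi:
                raise ConfigError(
                    f"planted pathway for {combo_label(combo)} needs {len(members)} genes, "
                    f"above pathway_size_range upper bound {hi}"
                )
            if len(members) < lo:
                pad = rng.choice(neutral, size=lo - len(members), replace=False).tolist()
                members.extend(pad)
            slot = planted_slots[si]
            slot_combo[slot] = combo
            planted_members.append(members)
            si += 1

    pathways: dict[str, list[str]] = {}
    planted_iter = iter(planted_members)
    planted_set = set(planted_slots)
    for i in range(cfg.n_pathways):
        pw_id = f"PW{i + 1:04d}"
        if i in planted_set:
            members = next(planted_iter)
            combo = slot_combo[i]
            truth.cooccurring_pathways.setdefault(combo, set()).add(pw_id)
        else:
            size = int(rng.integers(lo, hi + 1))
            members = rng.choice(gene_ids, size=size, replace=False).tolist()
        pathways[pw_id] = sorted(members)
    return pathways


# ---------------------------------------------------------------- drug table
def generate_drug_table(
    cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """DGIdb-like drug-gene interaction rows for a random ``druggable_fraction``
    of all genes (1-2 rows per druggable gene)."""
    mask = rng.random(len(genes)) < cfg.druggable_fraction
    rows = []
    drug_no = 0
    for gene_id, hit in zip(genes["gene_id"], mask):
        if not hit:
            continue
        n_rows = 1 + int(rng.random() < 0.3)
        for _ in range(n_rows):
            drug_no += 1
            source = ["dgidb_a", "dgidb_b", "dgidb_c"][int(rng.integers(3))]
            rows.append((gene_id, f"DRUG{drug_no:04d}", source))
    return pd.DataFrame(rows, columns=formats.DGI_COLUMNS)


# --------------------------------------------------------------- haplotypes
def generate_haplotypes(
    cfg: SimConfig, snps: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Phased haplotypes: one founder 0/1 vector per (chromosome, block of
    ``ld_block_length`` bp); each SNP copies its block founder with flip
    probability ``ld_noise``.  SNPs in different blocks are independent, so
    planted same-block pairs are the only high-LD pairs by construction.
    """
    n = cfg.n_haplotypes
    founders: dict[tuple[str, int], np.ndarray] = {}
    cols = np.empty((n, len(snps)), dtype=np.uint8)
    for j, rec in enumerate(snps.itertuples()):
        key = (rec.chrom, int(rec.pos) // cfg.ld_block_length)
        if key not in founders:
            while True:
                base = rng.integers(0, 2, size=n).astype(np.uint8)
                if 0 < base.sum() < n:
                    break
            founders[key] = base
        v = founders[key].copy()
        if cfg.ld_noise > 0:
            flips = rng.random(n) < cfg.ld_noise
            v ^= flips.astype(np.uint8)
        if v.sum() == 0 or v.sum() == n:
            v[0] ^= 1  # keep every site polymorphic
        cols[:, j] = v
    return cols


# -------------------------------------------------------------------- driver
def generate_all(cfg: SimConfig, out_dir: str | Path | None = None) -> SimOutput:
    """Run every generator stage in a fixed order and (optionally) write the
    full input bundle plus truth.tsv to ``out_dir``."""
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(8)
    rngs = [np.random.default_rng(s) for s in streams]

    genes, fragments = generate_genome(cfg, rngs[0])
    snps = generate_phenotype_snps(cfg, rngs[1])
    truth, snps = plant_truth(cfg, genes, snps, rngs[2])
    derive_ld_truth(cfg, snps, truth)
    contacts = generate_contacts(cfg, genes, fragments, snps, truth, rngs[3])
    eqtl = generate_eqtl_table(cfg, genes, fragments, snps, truth, contacts, rngs[4])
    pathways = generate_pathways(cfg, genes, truth, rngs[5])
    dgi = generate_drug_table(cfg, genes, rngs[6])
    haplotypes = generate_haplotypes(cfg, snps, rngs[7])

    out = SimOutput(
        config=cfg, genes=genes, fragments=fragments, snps=snps, contacts=contacts,
        eqtl=eqtl, pathways=pathways, dgi=dgi, haplotypes=haplotypes, truth=truth,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        formats.write_genes(genes, out_dir / "genes.tsv")
        formats.write_fragments(fragments, out_dir / "fragments.bed")
        for phen in cfg.phenotypes:
            formats.write_snps(
                snps[snps["phenotype"] == phen], out_dir / f"snps_{phen}.tsv"
            )
        for label, df in contacts.items():
            formats.write_contacts(df, out_dir / f"contacts_{label}.tsv")
        formats.write_eqtl_table(eqtl, out_dir / "eqtl_associations.tsv")
        formats.write_gmt(pathways, out_dir / "pathways.gmt")
        formats.write_dgi(dgi, out_dir / "dgi.tsv")
        contig_lengths = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chromosomes)}
        formats.write_phased_vcf(snps, haplotypes, out_dir / "haplotypes.vcf", contig_lengths)
        formats.write_truth(truth.to_frame(), out_dir / "truth.tsv")
        cfg.to_yaml(out_dir / "sim_config.yaml")
        out.out_dir = out_dir
    return out
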