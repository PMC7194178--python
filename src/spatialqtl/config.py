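"""Configuration objects for the simulator and the end-to-end pipeline.

Two dataclasses are defined here:

``SimConfig``
    Every knob of the synthetic-data generator, with defaults that encode the
    study conditions the pipeline is meant to emulate (four phenotypes with
    disjoint GWAS SNP sets, two Hi-C datasets of very different contact
    density, a GTEx-like multi-tissue association table, a KEGG-sized pathway
    collection, a DGIdb-like drug table and phased haplotypes with plantable
    LD blocks).

``RunConfig``
    Thresholds and paths for one pipeline run.  Defaults are the analysis
    constants used throughout: suggestive GWAS threshold 5e-6, eQTL FDR 0.05,
    cis window 1 Mb, 10,000 bootstrap draws, LD screen at r^2 > 0.8.

Phenotype combinations are canonicalised as alphabetically sorted tuples and
serialised as ``"A+B"`` labels in YAML and output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

Combo = tuple[str, ...]


class ConfigError(ValueError):
    """Invalid configuration value."""


class SizingError(ConfigError):
    """A requested object count does not fit in the configured genome."""


def canon_combo(labels: Sequence[str]) -> Combo:
    """Canonical (alphabetically sorted, duplicate-free) combination tuple."""
    combo = tuple(sorted(set(labels)))
    if len(combo) < 2:
        raise ConfigError(f"combination needs >=2 distinct phenotypes, got {labels!r}")
    return combo


def combo_label(combo: Sequence[str]) -> str:
    return "+".join(canon_combo(combo))


def _parse_combo_map(raw: Mapping) -> dict[Combo, int]:
    out: dict[Combo, int] = {}
    for key, val in raw.items():
        combo = canon_combo(key.split("+")) if isinstance(key, str) else canon_combo(key)
        out[combo] = int(val)
    return out


@dataclass
class DatasetSpec:
    """One Hi-C contact dataset.

    ``density`` scales both the background contact count and the probability
    that a planted SNP-gene pair is supported by this dataset.
    ``phenotype_density`` overrides that probability for named phenotypes
    (e.g. 0.0 reproduces the condition in which no MG pair is supported by
    the muscle dataset).
    """

    label: str
    density: float = 1.0
    phenotype_density: dict[str, float] = field(default_factory=dict)

    def planted_inclusion_prob(self, phenotype: str) -> float:
        return float(self.phenotype_density.get(phenotype, self.density))


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 6
    chrom_length: int = 3_000_000
    fragment_mean_length: int = 4_000
    n_genes: int = 3_000
    gene_length_range: tuple[int, int] = (1_000, 4_000)
    phenotypes: dict[str, int] = field(
        default_factory=lambda: {"GS": 179, "MG": 18, "MS": 285, "ALS": 135}
    )
    gwas_p_threshold: float = 5e-6
    planted_eqtl_fraction: dict[str, float] = field(
        default_factory=lambda: {"GS": 0.8, "MG": 0.8, "MS": 0.8, "ALS": 0.45}
    )
    planted_shared_egenes: dict[Combo, int] = field(
        default_factory=lambda: {
            ("GS", "MG"): 10,
            ("GS", "MS"): 25,
            ("ALS", "GS"): 5,
            ("MG", "MS"): 10,
            ("ALS", "MS"): 2,
            ("ALS", "MG"): 1,
        }
    )
    n_tissues: int = 48
    n_pathways: int = 536
    pathway_size_range: tuple[int, int] = (10, 80)
    planted_pathway_cooccurrence: dict[Combo, int] = field(
        default_factory=lambda: {("ALS", "GS", "MG", "MS"): 3}
    )
    pathway_hits_per_phenotype: int = 8
    druggable_fraction: float = 0.13
    n_haplotypes: int = 1_000
    ld_block_length: int = 20_000
    ld_noise: float = 0.01
    planted_ld_pairs: dict[Combo, int] = field(
        default_factory=lambda: {("MG", "MS"): 1}
    )
    datasets: list[DatasetSpec] = field(
        default_factory=lambda: [
            DatasetSpec("cellline", 0.85),
            DatasetSpec("muscle", 0.35, {"MG": 0.0}),
        ]
    )
    background_contacts_per_mb: float = 50.0
    genes_per_snp_cap: int = 4
    cis_fraction: float = 0.95
    cis_window: int = 1_000_000
    eqtl_sig_exponent_range: tuple[float, float] = (5.0, 12.0)
    sig_tissue_fraction: float = 0.25
    decoy_p_floor: float = 0.0
    assoc_coverage: float = 0.9
    n_decoy_pairs: int | None = None

    # ------------------------------------------------------------------ helpers
    def n_eqtl_snps(self, phenotype: str) -> int:
        frac = self.planted_eqtl_fraction.get(phenotype, 0.0)
        return int(round(frac * self.phenotypes[phenotype]))

    def shared_commitment(self, phenotype: str) -> int:
        return sum(
            count for combo, count in self.planted_shared_egenes.items() if phenotype in combo
        )

    def pathway_need(self, phenotype: str) -> int:
        if any(phenotype in combo for combo in self.planted_pathway_cooccurrence):
            return self.pathway_hits_per_phenotype
        return 0

    def n_specific_egenes(self, phenotype: str) -> int:
        n_eqtl = self.n_eqtl_snps(phenotype)
        if n_eqtl == 0:
            return 0
        return max(n_eqtl - self.shared_commitment(phenotype), self.pathway_need(phenotype))

    def planted_egene_count(self, phenotype: str) -> int:
        if self.n_eqtl_snps(phenotype) == 0:
            return 0
        return self.shared_commitment(phenotype) + self.n_specific_egenes(phenotype)

    def resolved_decoy_pairs(self) -> int:
        return 2 * self.n_genes if self.n_decoy_pairs is None else self.n_decoy_pairs

    # ----------------------------------------------------------------- validate
    def validate(self) -> None:
        positive = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
            "fragment_mean_length": self.fragment_mean_length,
            "n_genes": self.n_genes,
            "n_tissues": self.n_tissues,
            "n_pathways": self.n_pathways,
            "n_haplotypes": self.n_haplotypes,
            "ld_block_length": self.ld_block_length,
            "genes_per_snp_cap": self.genes_per_snp_cap,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        for name, value in {
            "gwas_p_threshold": self.gwas_p_threshold,
            "druggable_fraction": self.druggable_fraction,
            "ld_noise": self.ld_noise,
            "cis_fraction": self.cis_fraction,
            "sig_tissue_fraction": self.sig_tissue_fraction,
            "decoy_p_floor": self.decoy_p_floor,
            "assoc_coverage": self.assoc_coverage,
            **{f"planted_eqtl_fraction[{k}]": v for k, v in self.planted_eqtl_fraction.items()},
        }.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if not self.phenotypes:
            raise ConfigError("at least one phenotype is required")
        for phen, n in self.phenotypes.items():
            if n <= 0:
                raise ConfigError(f"phenotype {phen!r} needs a positive SNP count, got {n}")
        if self.n_haplotypes % 2:
            raise ConfigError("n_haplotypes must be even (haplotypes are paired into diploid samples)")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ConfigError(f"invalid gene_length_range {self.gene_length_range}")
        lo, hi = self.pathway_size_range
        if not 0 < lo <= hi:
            raise ConfigError(f"invalid pathway_size_range {self.pathway_size_range}")
        if hi > self.n_genes:
            raise SizingError(
                f"pathway_size_range upper bound {hi} exceeds the gene universe ({self.n_genes})"
            )
        if not self.datasets:
            raise ConfigError("at least one Hi-C dataset is required")
        labels = [d.label for d in self.datasets]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"duplicate dataset labels: {labels}")
        known = set(self.phenotypes)
        for combo_map, what in [
            (self.planted_shared_egenes, "planted_shared_egenes"),
            (self.planted_pathway_cooccurrence, "planted_pathway_cooccurrence"),
            (self.planted_ld_pairs, "planted_ld_pairs"),
        ]:
            for combo in combo_map:
                unknown = set(combo) - known
                if unknown:
                    raise ConfigError(f"{what} references unknown phenotypes {sorted(unknown)}")
        for combo in self.planted_pathway_cooccurrence:
            for phen in combo:
                if self.n_eqtl_snps(phen) == 0:
                    raise ConfigError(
                        f"planted pathway combination {combo_label(combo)} includes "
                        f"{phen!r}, which has a zero eQTL fraction and hence no eGenes"
                    )
        for combo, count in self.planted_shared_egenes.items():
            cap = min(self.planted_egene_count(p) for p in combo)
            if count > cap:
                raise ConfigError(
                    f"planted shared count {count} for {combo_label(combo)} exceeds the "
                    f"smallest planted eGene set ({cap})"
                )
        for phen in self.phenotypes:
            n_eqtl = self.n_eqtl_snps(phen)
            demand = self.planted_egene_count(phen)
            if n_eqtl == 0 and self.shared_commitment(phen) > 0:
                raise ConfigError(
                    f"phenotype {phen!r} has planted shared eGenes but a zero eQTL fraction"
                )
            if n_eqtl and demand > n_eqtl * self.genes_per_snp_cap:
                raise ConfigError(
                    f"phenotype {phen!r} needs {demand} planted eGenes but only "
                    f"{n_eqtl} eQTL SNPs x cap {self.genes_per_snp_cap} are available"
                )
            if n_eqtl and not any(d.planted_inclusion_prob(phen) > 0 for d in self.datasets):
                raise ConfigError(
                    f"phenotype {phen!r} has no Hi-C dataset with positive density; "
                    "planted pairs would be unsupported"
                )

    # -------------------------------------------------------------------- yaml
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("planted_shared_egenes", "planted_pathway_cooccurrence", "planted_ld_pairs"):
            d[key] = {combo_label(c): v for c, v in getattr(self, key).items()}
        d["gene_length_range"] = list(self.gene_length_range)
        d["pathway_size_range"] = list(self.pathway_size_range)
        d["eqtl_sig_exponent_range"] = list(self.eqtl_sig_exponent_range)
        return d

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimConfig":
        d = dict(raw)
        for key in ("planted_shared_egenes", "planted_pathway_cooccurrence", "planted_ld_pairs"):
            if key in d:
                d[key] = _parse_combo_map(d[key])
        for key in ("gene_length_range", "pathway_size_range", "eqtl_sig_exponent_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "datasets" in d:
            d["datasets"] = [
                ds if isinstance(ds, DatasetSpec) else DatasetSpec(**ds) for ds in d["datasets"]
            ]
        cfg = cls(**d)
        cfg.planted_shared_egenes = {canon_combo(c): v for c, v in cfg.planted_shared_egenes.items()}
        cfg.planted_pathway_cooccurrence = {
            canon_combo(c): v for c, v in cfg.planted_pathway_cooccurrence.items()
        }
        cfg.planted_ld_pairs = {canon_combo(c): v for c, v in cfg.planted_ld_pairs.items()}
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def default_config(seed: int = 0) -> SimConfig:
    """The generator's default study conditions."""
    cfg = SimConfig(seed=seed)
    cfg.planted_shared_egenes = {canon_combo(c): v for c, v in cfg.planted_shared_egenes.items()}
    cfg.planted_pathway_cooccurrence = {
        canon_combo(c): v for c, v in cfg.planted_pathway_cooccurrence.items()
    }
    cfg.planted_ld_pairs = {canon_combo(c): v for c, v in cfg.planted_ld_pairs.items()}
    cfg.validate()
    return cfg


def noise_free_config(seed: int = 0) -> SimConfig:
    """Noise-free planted configuration.

    Decoy association p-values are floored at 0.1 so no decoy can reach BH
    q < 0.05 (a decoy's q is bounded below by its own p), making planted-truth
    recovery exact; LD block copying is noiseless so planted pairs reach
    r^2 = 1.  Scale is reduced (fewer SNPs, genes and tissues) relative to the
    defaults; the planted structure is otherwise the same.
    """
    cfg = SimConfig(
        seed=seed,
        phenotypes={"GS": 70, "MG": 18, "MS": 90, "ALS": 40},
        planted_eqtl_fraction={"GS": 0.8, "MG": 0.8, "MS": 0.8, "ALS": 0.45},
        planted_shared_egenes={
            canon_combo(c): v
            for c, v in {
                ("GS", "MG"): 8,
                ("GS", "MS"): 15,
                ("GS", "ALS"): 10,
                ("MG", "MS"): 8,
                ("MS", "ALS"): 10,
            }.items()
        },
        planted_pathway_cooccurrence={canon_combo(("GS", "MG", "MS", "ALS")): 1},
        n_tissues=12,
        pathway_size_range=(10, 60),
        n_haplotypes=400,
        ld_noise=0.0,
        decoy_p_floor=0.1,
        eqtl_sig_exponent_range=(6.0, 10.0),
    )
    cfg.planted_ld_pairs = {canon_combo(c): v for c, v in cfg.planted_ld_pairs.items()}
    cfg.validate()
    return cfg


def small_config(seed: int = 0) -> SimConfig:
    """A fast, scaled-down configuration for smoke tests and determinism checks."""
    cfg = SimConfig(
        seed=seed,
        n_chromosomes=3,
        chrom_length=1_500_000,
        n_genes=400,
        gene_length_range=(1_000, 4_000),
        phenotypes={"GS": 25, "MG": 8, "MS": 30, "ALS": 15},
        planted_eqtl_fraction={"GS": 0.6, "MG": 0.5, "MS": 0.6, "ALS": 0.4},
        planted_shared_egenes={
            canon_combo(c): v
            for c, v in {("GS", "MS"): 6, ("GS", "MG"): 3, ("MG", "MS"): 3}.items()
        },
        planted_pathway_cooccurrence={canon_combo(("GS", "MG", "MS", "ALS")): 1},
        pathway_hits_per_phenotype=4,
        n_tissues=6,
        n_pathways=80,
        pathway_size_range=(5, 20),
        n_haplotypes=200,
        planted_ld_pairs={canon_combo(("MG", "MS")): 1},
        background_contacts_per_mb=30.0,
    )
    cfg.validate()
    return cfg


@dataclass
class RunConfig:
    """Thresholds and switches for one end-to-end pipeline run."""

    seed: int = 0
    alpha_fdr: float = 0.05
    gwas_alpha: float = 5e-6
    cis_window: int = 1_000_000
    n_boot: int = 10_000
    ld_threshold: float = 0.8
    self_contact: bool = True
    cis_anchor: str = "edge"  # or "tss"
    bh_scope: str = "joint"  # or "per_tissue"
    exclusive_intersections: bool = False

    def validate(self) -> None:
        if not 0.0 < self.alpha_fdr <= 1.0:
            raise ConfigError(f"alpha_fdr must be in (0, 1], got {self.alpha_fdr}")
        if not 0.0 < self.gwas_alpha <= 1.0:
            raise ConfigError(f"gwas_alpha must be in (0, 1], got {self.gwas_alpha}")
        if not 0.0 < self.ld_threshold <= 1.0:
            raise ConfigError(f"ld_threshold must be in (0, 1], got {self.ld_threshold}")
        if self.cis_window <= 0:
            raise ConfigError(f"cis_window must be positive, got {self.cis_window}")
        if self.n_boot < 1:
            raise ConfigError(f"n_boot must be >=1, got {self.n_boot}")
        if self.cis_anchor not in ("edge", "tss"):
            raise ConfigError(f"cis_anchor must be 'edge' or 'tss', got {self.cis_anchor!r}")
        if self.bh_scope not in ("joint", "per_tissue"):
            raise ConfigError(f"bh_scope must be 'joint' or 'per_tissue', got {self.bh_scope!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        cfg = cls(**dict(raw))
        cfg.validate()
        return cfg
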