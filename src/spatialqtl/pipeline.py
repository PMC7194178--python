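"""End-to-end orchestration: simulate -> map -> eqtl -> overlap -> pathways ->
annotate, with input validation, a machine-readable run report and a
MANIFEST recording completeness.

Every stochastic stage derives its randomness from the single run seed, so
rerunning with an identical configuration reproduces every output file
byte-for-byte.  The report contains no timestamps for the same reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotate, eqtl, formats, overlap, pathways as pw
from .config import RunConfig, SimConfig
from .simulate import TruthTable, generate_all
from .spatial import (
    FragmentIndex,
    assign_genes_to_fragments,
    assign_snps_to_fragments,
    call_spatial_pairs,
    filter_snps_by_significance,
    pairs_for_dataset,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class LoadedInputs:
    genes: pd.DataFrame
    fragments: pd.DataFrame
    snps: pd.DataFrame
    contacts: dict[str, pd.DataFrame]
    eqtl: pd.DataFrame
    pathways: dict[str, set[str]]
    dgi: pd.DataFrame
    vcf_path: Path
    truth: TruthTable | None = None


@dataclass
class ValidationReport:
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"warnings": self.warnings, "errors": self.errors}


def load_inputs(input_dir: str | Path) -> LoadedInputs:
    input_dir = Path(input_dir)
    required = ["genes.tsv", "fragments.bed", "eqtl_associations.tsv",
                "pathways.gmt", "dgi.tsv", "haplotypes.vcf"]
    for name in required:
        if not (input_dir / name).exists():
            raise FileNotFoundError(f"missing input file {input_dir / name}")
    snp_paths = sorted(input_dir.glob("snps_*.tsv"))
    if not snp_paths:
        raise FileNotFoundError(f"no snps_<phenotype>.tsv files in {input_dir}")
    contact_paths = sorted(input_dir.glob("contacts_*.tsv"))
    if not contact_paths:
        raise FileNotFoundError(f"no contacts_<dataset>.tsv files in {input_dir}")
    snps = pd.concat([formats.read_snps(p) for p in snp_paths], ignore_index=True)
    contacts = {
        p.stem.removeprefix("contacts_"): formats.read_contacts(p) for p in contact_paths
    }
    truth = None
    if (input_dir / "truth.tsv").exists():
        truth = TruthTable.from_frame(formats.read_truth(input_dir / "truth.tsv"))
    return LoadedInputs(
        genes=formats.read_genes(input_dir / "genes.tsv"),
        fragments=formats.read_fragments(input_dir / "fragments.bed"),
        snps=snps,
        contacts=contacts,
        eqtl=formats.read_eqtl_table(input_dir / "eqtl_associations.tsv"),
        pathways=formats.read_gmt(input_dir / "pathways.gmt"),
        dgi=formats.read_dgi(input_dir / "dgi.tsv"),
        vcf_path=input_dir / "haplotypes.vcf",
        truth=truth,
    )


def validate_inputs(inputs: LoadedInputs) -> ValidationReport:
    """Referential-integrity checks across the input bundle.

    Errors are fatal (malformed coordinates, unknown fragment IDs); unknown
    gene/SNP references in annotation tables are warnings and the offending
    records are dropped downstream.
    """
    rep = ValidationReport()
    genes, frags, snps = inputs.genes, inputs.fragments, inputs.snps

    chrom_end = frags.groupby("chrom")["end"].max().to_dict()
    try:
        FragmentIndex.from_frame(frags)
    except Exception as exc:  # noqa: BLE001 - report, do not crash mid-validation
        rep.errors.append(str(exc))

    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        rep.errors.append(f"duplicate gene_id {dup!r} in gene model")
    for rec in genes.itertuples():
        end = chrom_end.get(rec.chrom)
        if end is None:
            rep.errors.append(f"gene {rec.gene_id} on chromosome {rec.chrom!r} absent from fragment map")
        elif rec.end > end:
            rep.errors.append(f"gene {rec.gene_id} extends past the end of {rec.chrom} ({rec.end} > {end})")

    if snps["rsid"].duplicated().any():
        dup = snps.loc[snps["rsid"].duplicated(), "rsid"].iloc[0]
        rep.errors.append(f"duplicate rsid {dup!r} across SNP tables")
    for rec in snps.itertuples():
        end = chrom_end.get(rec.chrom)
        if end is None:
            rep.errors.append(f"SNP {rec.rsid} on chromosome {rec.chrom!r} absent from fragment map")
        elif not 0 <= rec.pos < end:
            rep.errors.append(f"SNP {rec.rsid} at {rec.chrom}:{rec.pos} beyond chromosome end {end}")
        if not 0.0 < rec.assoc_p <= 1.0:
            rep.errors.append(f"SNP {rec.rsid} has association p outside (0, 1]: {rec.assoc_p}")

    frag_ids = set(frags["frag_id"])
    for label, df in inputs.contacts.items():
        unknown = (set(df["frag_a"]) | set(df["frag_b"])) - frag_ids
        if unknown:
            rep.errors.append(
                f"contacts {label!r} reference unknown fragments, e.g. {sorted(unknown)[:3]}"
            )

    gene_ids = set(genes["gene_id"])
    rsids = set(snps["rsid"])
    bad_g = set(inputs.eqtl["gene_id"]) - gene_ids
    if bad_g:
        rep.warnings.append(f"eQTL table references {len(bad_g)} unknown gene(s); rows dropped")
    bad_r = set(inputs.eqtl["rsid"]) - rsids
    if bad_r:
        rep.warnings.append(f"eQTL table references {len(bad_r)} unknown SNP(s); rows dropped")
    bad_p = inputs.eqtl[~inputs.eqtl["nominal_p"].between(0, 1, inclusive="right")]
    if not bad_p.empty:
        rep.errors.append(
            f"eQTL table has {len(bad_p)} nominal p-value(s) outside (0, 1]"
        )
    for pw_id, members in inputs.pathways.items():
        unknown = set(members) - gene_ids
        if unknown:
            rep.warnings.append(
                f"pathway {pw_id} references {len(unknown)} unknown gene(s); dropped"
            )
    bad_dgi = set(inputs.dgi["gene_id"]) - gene_ids
    if bad_dgi:
        rep.warnings.append(f"drug table references {len(bad_dgi)} unknown gene(s); rows dropped")
    return rep


def _clean_inputs(inputs: LoadedInputs) -> None:
    """Drop records flagged as warnings by validate_inputs (unknown references)."""
    gene_ids = set(inputs.genes["gene_id"])
    rsids = set(inputs.snps["rsid"])
    inputs.eqtl = inputs.eqtl[
        inputs.eqtl["gene_id"].isin(gene_ids) & inputs.eqtl["rsid"].isin(rsids)
    ].reset_index(drop=True)
    inputs.pathways = {
        pw_id: set(members) & gene_ids for pw_id, members in inputs.pathways.items()
    }
    inputs.pathways = {k: v for k, v in inputs.pathways.items() if v}
    inputs.dgi = inputs.dgi[inputs.dgi["gene_id"].isin(gene_ids)].reset_index(drop=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj)] if isinstance(obj, set) else [
            _jsonable(v) for v in obj
        ]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def run_all(
    out_dir: str | Path,
    run_cfg: RunConfig,
    input_dir: str | Path | None = None,
    sim_cfg: SimConfig | None = None,
) -> dict:
    """Run the full pipeline and return the report dict (also written to
    ``out_dir/report.json``).

    Either ``input_dir`` points at an existing input bundle, or ``sim_cfg``
    is given and the bundle is simulated into ``out_dir/sim`` first.  On a
    stage failure a MANIFEST marking incompleteness is written and a
    PipelineError naming the stage is raised.
    """
    run_cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"complete": False, "failed_stage": None, "files": []}
    report: dict = {
        "version": __version__,
        "seed": run_cfg.seed,
        "config": run_cfg.to_dict(),
        "stages": {},
    }

    def emit(name: str) -> Path:
        path = out_dir / name
        manifest["files"].append(name)
        return path

    stage = "simulate"
    try:
        if sim_cfg is not None:
            sim_out = generate_all(sim_cfg, out_dir / "sim")
            input_dir = out_dir / "sim"
            report["stages"]["simulate"] = {
                "out_dir": "sim",  # relative to the run directory, keeps reports reproducible
                "n_genes": len(sim_out.genes),
                "n_fragments": len(sim_out.fragments),
                "n_snps": len(sim_out.snps),
                "sim_seed": sim_cfg.seed,
            }
        elif input_dir is None:
            raise PipelineError("run_all needs either input_dir or sim_cfg")

        stage = "load"
        inputs = load_inputs(input_dir)

        stage = "validate"
        vrep = validate_inputs(inputs)
        with open(emit("validation.json"), "w") as fh:
            json.dump(vrep.to_dict(), fh, indent=2, sort_keys=True)
        if vrep.errors:
            raise PipelineError(
                f"input validation failed with {len(vrep.errors)} error(s); "
                f"first: {vrep.errors[0]}"
            )
        _clean_inputs(inputs)
        report["stages"]["validate"] = vrep.to_dict()

        stage = "map"
        phenotypes = list(dict.fromkeys(inputs.snps["phenotype"]))
        snps_kept = filter_snps_by_significance(inputs.snps, run_cfg.gwas_alpha)
        index = FragmentIndex.from_frame(inputs.fragments)
        snp_frags = assign_snps_to_fragments(snps_kept, index)
        gene_frags = assign_genes_to_fragments(inputs.genes, index)
        pairs = call_spatial_pairs(
            snp_frags, gene_frags, inputs.contacts,
            fragment_ids=set(inputs.fragments["frag_id"]),
            self_contact=run_cfg.self_contact,
        )
        pairs.to_csv(emit("spatial_pairs.tsv"), sep="\t", index=False)
        report["stages"]["map"] = {
            "n_snps_post_threshold": len(snps_kept),
            "n_spatial_pairs": len(pairs),
            "n_spatial_genes": int(pairs["gene_id"].nunique()),
            "per_dataset": {
                label: int(len(pairs_for_dataset(pairs, label)))
                for label in inputs.contacts
            },
        }

        stage = "eqtl"
        sources = list(inputs.contacts) + ["combined"]
        phen_of = dict(zip(inputs.snps["rsid"], inputs.snps["phenotype"]))
        snp_counts = snps_kept["phenotype"].value_counts().to_dict()
        egenesets: dict[tuple[str, str], eqtl.EGeneSet] = {}
        calls_by_run: dict[tuple[str, str], pd.DataFrame] = {}
        untested_frames = []
        for source in sources:
            src_pairs = pairs if source == "combined" else pairs_for_dataset(pairs, source)
            calls_frames = []
            for phen in phenotypes:
                ppairs = src_pairs[src_pairs["rsid"].map(phen_of) == phen]
                tested, untested = eqtl.query_associations(ppairs, inputs.eqtl)
                if not untested.empty:
                    untested = untested.assign(phenotype=phen, hic_source=source)
                    untested_frames.append(untested)
                calls = eqtl.process_calls(
                    tested, snps_kept, inputs.genes,
                    alpha=run_cfg.alpha_fdr, window=run_cfg.cis_window,
                    anchor=run_cfg.cis_anchor, bh_scope=run_cfg.bh_scope,
                )
                calls_by_run[(phen, source)] = calls
                egenesets[(phen, source)] = eqtl.collect_egenes(
                    calls, phen, source, run_cfg.alpha_fdr
                )
                calls_frames.append(calls.assign(phenotype=phen))
                formats.write_gene_list(
                    egenesets[(phen, source)].egenes,
                    emit(f"egenes_{phen}_{source}.txt"),
                )
            all_calls = pd.concat(calls_frames, ignore_index=True)
            all_calls.to_csv(emit(f"eqtl_calls_{source}.tsv"), sep="\t", index=False)
        if untested_frames:
            pd.concat(untested_frames, ignore_index=True).to_csv(
                emit("untested_pairs.tsv"), sep="\t", index=False
            )
        summary = eqtl.summarize_proportions(
            [egenesets[k] for k in sorted(egenesets)],
            snp_counts, calls_by_run,
        )
        summary.to_csv(emit("summary.tsv"), sep="\t", index=False)
        report["stages"]["eqtl"] = {
            "summary": summary.to_dict(orient="records"),
        }
        if len(inputs.contacts) >= 2:
            partition = {
                phen: eqtl.partition_by_dataset(
                    {src: egenesets[(phen, src)].eqtl_snps for src in inputs.contacts}
                )
                for phen in phenotypes
            }
            report["stages"]["eqtl"]["eqtl_snp_partition"] = partition

        stage = "overlap"
        combined_sets = {
            phen: egenesets[(phen, "combined")].egenes for phen in phenotypes
        }
        backgrounds = {
            "all_egenes": set(inputs.eqtl["gene_id"]),
            "spatial_genes": set(pairs["gene_id"]),
        }
        for label, bg in backgrounds.items():
            formats.write_gene_list(bg, emit(f"background_{label}.txt"))
        overlaps = overlap.run_both_backgrounds(
            combined_sets, backgrounds,
            n_boot=run_cfg.n_boot, seed=run_cfg.seed, alpha=run_cfg.alpha_fdr,
        )
        inter = overlap.compute_intersections(
            combined_sets, exclusive=run_cfg.exclusive_intersections
        )
        inter.to_csv(emit("egene_intersections.tsv"), sep="\t", index=False)
        overlaps.to_csv(emit("overlaps.tsv"), sep="\t", index=False)
        report["stages"]["overlap"] = {
            "set_sizes": {p: len(s) for p, s in combined_sets.items()},
            "background_sizes": {k: len(v) for k, v in backgrounds.items()},
            "results": overlaps.drop(columns=["null_mean"]).to_dict(orient="records"),
        }

        stage = "pathways"
        universe = pw.default_universe(inputs.pathways, inputs.genes["gene_id"])
        enriched_sets: dict[str, set[str]] = {}
        for phen in phenotypes:
            enr = pw.ora_enrich(
                combined_sets[phen], inputs.pathways, universe,
                alpha=run_cfg.alpha_fdr, phenotype=phen,
            )
            enr.to_csv(emit(f"enrichment_{phen}.tsv"), sep="\t", index=False)
            enriched_sets[phen] = set(enr.loc[enr["enriched"], "pathway_id"])
        pw_overlaps = pw.pathway_overlaps(enriched_sets)
        pw_overlaps.to_csv(emit("pathway_overlaps.tsv"), sep="\t", index=False)
        classes = pw.classify_all_shared(
            pw_overlaps, inputs.pathways, combined_sets, enriched_sets
        )
        classes.to_csv(emit("shared_pathway_classes.tsv"), sep="\t", index=False)
        pw_backgrounds = {
            "all_pathways": set(inputs.pathways),
            "egene_pathways": {
                pid for pid, members in inputs.pathways.items()
                if any(members & combined_sets[p] for p in phenotypes)
            },
        }
        pw_boot = overlap.run_both_backgrounds(
            enriched_sets, pw_backgrounds,
            n_boot=run_cfg.n_boot, seed=run_cfg.seed, alpha=run_cfg.alpha_fdr,
        )
        pw_boot.to_csv(emit("pathway_overlap_bootstrap.tsv"), sep="\t", index=False)
        report["stages"]["pathways"] = {
            "n_enriched": {p: len(s) for p, s in enriched_sets.items()},
            "driver_classes": classes["driver_class"].value_counts().to_dict(),
            "bootstrap": pw_boot.drop(columns=["null_mean"]).to_dict(orient="records"),
        }

        stage = "annotate"
        druggable, fraction = annotate.annotate_druggable(combined_sets, inputs.dgi)
        rows = [
            {"phenotype": p, "gene_id": g}
            for p in phenotypes for g in sorted(druggable[p])
        ]
        pd.DataFrame(rows, columns=["phenotype", "gene_id"]).to_csv(
            emit("druggable_egenes.tsv"), sep="\t", index=False
        )
        dpw, dpw_overlap = annotate.druggable_pathways(
            enriched_sets, inputs.pathways, druggable
        )
        dpw_rows = [
            {"phenotype": p, "pathway_id": pid}
            for p in phenotypes for pid in sorted(dpw[p])
        ]
        pd.DataFrame(dpw_rows, columns=["phenotype", "pathway_id"]).to_csv(
            emit("druggable_pathways.tsv"), sep="\t", index=False
        )
        dpw_overlap.to_csv(emit("druggable_pathway_overlaps.tsv"), sep="\t", index=False)
        panel = annotate.HaplotypePanel.from_vcf(inputs.vcf_path)
        eqtl_snp_sets = {
            phen: egenesets[(phen, "combined")].eqtl_snps for phen in phenotypes
        }
        ld_pairs = annotate.screen_ld_confounding(
            eqtl_snp_sets, panel, threshold=run_cfg.ld_threshold
        )
        ld_pairs.to_csv(emit("ld_pairs.tsv"), sep="\t", index=False)
        report["stages"]["annotate"] = {
            "druggable_fraction": fraction,
            "n_druggable": {p: len(druggable[p]) for p in phenotypes},
            "n_druggable_pathways": {p: len(dpw[p]) for p in phenotypes},
            "n_ld_pairs_reported": len(ld_pairs),
        }

        stage = "report"
        with open(emit("report.json"), "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        manifest["complete"] = True
        with open(out_dir / "MANIFEST.json", "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
        return report
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out_dir / "MANIFEST.json", "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
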