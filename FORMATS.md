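# File formats

All pipeline files are plain tab-separated text. Internally every
coordinate is 0-based half-open; dialect conversions happen only at the I/O
boundary, as noted per format.

## Inputs (written by `spatialqtl simulate`, consumed by the pipeline)

### genes.tsv (GTF-like, 1-based inclusive)
Columns: `gene_id  symbol  chrom  start  end`. `start` is converted to
0-based on read.

### fragments.bed (BED, 0-based half-open, no header)
Columns: `chrom  start  end  frag_id`. Fragments on a chromosome must be
disjoint and tile it exactly.

### snps_<phenotype>.tsv (1-based positions)
Columns: `rsid  chrom  pos  assoc_p  phenotype`. One file per phenotype;
rsIDs are globally unique and phenotype SNP sets are disjoint.

### contacts_<dataset>.tsv
Columns: `frag_a  frag_b  count`. Canonical orientation `frag_a <= frag_b`
by fragment ID; one row per unordered pair; `count` is carried but ignored
by pair calling (support is presence/absence).

### eqtl_associations.tsv
Columns: `rsid  gene_id  tissue  nominal_p`. GTEx-like nominal association
p-values for (variant, gene, tissue) triples.

### pathways.gmt
Standard GMT: `name <TAB> description <TAB> gene1 <TAB> gene2 ...`, one
pathway per line.

### dgi.tsv
Columns: `gene_id  drug  source`. A gene is druggable iff it has >=1 row.

### haplotypes.vcf
Minimal phased VCF 4.2; consecutive haplotypes are paired into diploid
samples with `GT` like `0|1`. POS is 1-based; site IDs are the SNP rsIDs.

### truth.tsv (generator ground truth)
Columns: `role  group  id_a  id_b` with roles:

| role | group | id_a | id_b |
|---|---|---|---|
| `egene` | phenotype | gene_id | — |
| `eqtl_snp` | phenotype | rsid | — |
| `edge` | phenotype | rsid | gene_id |
| `shared_egene` | combination (`A+B`) | gene_id | — |
| `cooccur_pathway` | combination | pathway_id | — |
| `ld_pair` | `phenA+phenB` | rsid_a | rsid_b |

## Outputs (per run directory)

- `spatial_pairs.tsv` — `rsid  gene_id  datasets` (comma-joined sorted labels).
- `eqtl_calls_<source>.tsv` — tested triples with `q`, `significant`,
  `cis_trans`, `distance` (bp; empty for inter-chromosomal) and `phenotype`.
- `egenes_<phenotype>_<source>.txt` — one gene ID per line, sorted.
- `untested_pairs.tsv` — spatial pairs with no association rows.
- `summary.tsv` — per (phenotype, source): SNP counts, eQTL fraction,
  eGene count, cis/trans split.
- `egene_intersections.tsv`, `overlaps.tsv` — k-way intersections and
  bootstrap results (`empirical_p`, analytic `analytic_p` for pairs, per
  background).
- `background_all_egenes.txt`, `background_spatial_genes.txt` — the two
  overlap backgrounds, one gene per line.
- `enrichment_<phenotype>.tsv` — ORA rows `pathway_id k K n N p q enriched`.
- `pathway_overlaps.tsv`, `pathway_overlap_bootstrap.tsv`,
  `shared_pathway_classes.tsv` — pathway-space analogues plus
  `driver_class` in {`shared_egenes`, `condition_specific`, `mixed`}.
- `druggable_egenes.tsv`, `druggable_pathways.tsv`,
  `druggable_pathway_overlaps.tsv` — druggability annotation; the overlap
  table flags shared druggable pathways without a shared druggable gene.
- `ld_pairs.tsv` — cross-phenotype eQTL SNP pairs with r² above threshold.
- `report.json`, `validation.json`, `MANIFEST.json` — run report, input
  validation outcome, and file manifest with completeness flag.
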