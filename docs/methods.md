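# Methods

## The analysis chain

`spatialqtl` asks whether phenotypes with disjoint GWAS SNP sets share
downstream regulatory targets. The chain is: GWAS SNPs → restriction
fragments → Hi-C contacts → candidate SNP–gene pairs → multi-tissue eQTL
evidence → per-phenotype eGene sets → cross-phenotype overlap, pathway,
druggability and LD analyses. Each stage is a pure function over tabular
data; the pipeline module only orchestrates and writes artifacts.

### Spatial pair calling

A SNP belongs to exactly one fragment (half-open intervals; a SNP on a
boundary belongs to the right-hand fragment). A gene maps to every fragment
its body overlaps. Pair support is per dataset: dataset *d* supports
(SNP, gene) iff *d*'s contact list contains the unordered fragment pair
{frag(SNP), g} for any gene fragment g, **or** frag(SNP) is itself a
fragment of the gene. The self-fragment rule exists because proximity
ligation cannot report within-fragment contacts and dropping those pairs
would discard promoter SNPs; `self_contact=False` disables it. Adjacent
fragments are *not* assumed in contact, contact counts are ignored
(presence/absence only), and no distance cut is applied.

### eQTL calling and multiple testing

All association rows matching a phenotype's spatial pairs are tested
jointly: one Benjamini–Hochberg correction across every
(SNP, gene, tissue) triple per phenotype per Hi-C source. This is the
conservative scope; `bh_scope="per_tissue"` corrects within tissues
instead, for sensitivity analysis. The BH step-up is implemented directly
(q_i = min over p_(j) ≥ p_(i) of p_(j)·m/rank(j), clipped at 1) and is
oracle-tested element-wise, including against statsmodels.

An eGene is a gene with ≥1 call at q < α (α = 0.05); an eQTL SNP is a SNP
with ≥1 such call; the eQTL fraction divides by the post-threshold SNP
count. cis/trans uses a 1 Mb window, boundary inclusive, anchored at the
nearest gene-body edge (distance 0 inside the gene). The gene models carry
no strand, so the optional `tss` anchor measures to the annotated start.

### Overlap significance

Intersections are *inclusive*: the count for a combination is the
intersection of its members' sets regardless of other phenotypes (an
`exclusive` UpSet-style count is available without a significance test,
since the bootstrap null is defined for inclusive counts). The bootstrap
draws, independently per phenotype, a uniform subset of the background
without replacement, of the observed set's size, and records the
combination's intersection; the empirical p-value is the add-one estimator
(1 + #{null ≥ obs})/(1 + B), never zero, with ties counted in the tail
("≥ obs"). Two backgrounds are evaluated: all genes in the association
table (the testable-gene universe) and all genes with any spatial contact.
Each combination gets its own RNG stream derived by hashing the
combination label together with the run seed, so results are invariant to
evaluation order and identical backgrounds give identical draws. For
pairwise combinations the exact hypergeometric upper tail is reported
alongside and serves as the analytic cross-check.

### Pathway analysis

ORA is the one-sided hypergeometric test with BH across pathways within
one phenotype. The universe is the annotation-restricted choice — genes
annotated to ≥1 pathway, intersected with the gene model — which is
conservative; query genes outside it are dropped with a warning. Pathway
overlap reuses the intersection/bootstrap machinery over pathway IDs
(uniform sampling, no size weighting), against the full collection and
against the pathways containing ≥1 eGene. A pathway shared by a
combination is classified by its eGene hits: `condition_specific` if no
hit gene belongs to ≥2 member phenotypes, `shared_egenes` if every hit
does, `mixed` otherwise; classification requires enrichment in every
member.

### Druggability and LD

A gene is druggable iff it has ≥1 drug–gene interaction row; the headline
fraction is over the union of all phenotypes' eGenes. A pathway is
druggable for a phenotype iff enriched for it and containing ≥1 of its
druggable eGenes; shared druggable pathways with zero shared druggable
genes are flagged explicitly (phenotypes can share a treatable pathway
without sharing a target). LD is computed exactly from phased haplotypes,
r² = D²/(p_A(1−p_A)p_B(1−p_B)) with D = p_AB − p_A·p_B; monomorphic sites
are reported missing with a warning. The screen tests every
cross-phenotype pair of eQTL SNPs on the same chromosome (a superset of an
HLA-style single-region check) and reports pairs with r² above the
threshold (default 0.8); LD-explained overlaps are annotated, never
filtered.

## The synthetic-data generator

The generator emulates the study conditions end to end; it is first-class,
tested code, not a fixture. Defaults encode the emulated conditions:
four phenotypes with SNP counts 179 (GS), 18 (MG), 285 (MS), 135 (ALS),
all SNP association p ≤ 5×10⁻⁶ and pairwise-disjoint SNP sets; eQTL SNP
fractions 0.8/0.8/0.8/0.45; 48 tissues; 536 pathways; druggable fraction
0.13; two Hi-C datasets, a dense "cellline" one (planted-pair inclusion
0.85) and a sparse "muscle" one (0.35, with MG excluded so no MG pair is
muscle-supported); cis fraction 0.95 of planted edges within 1 Mb.

Where the emulated setting supplies no value the defaults are realistic
scale-downs chosen once: a 6×3 Mb genome, exponential restriction
fragments of mean 4 kb (clipped to [400 bp, 24 kb], last fragment
truncated so tiling is exact), 3,000 non-overlapping genes of 1–4 kb
placed uniformly over per-chromosome free space, 20 kb LD blocks, 1,000
haplotypes, and planted pairwise shared-eGene counts of 1–25 sized so the
spec invariant (shared ≤ smallest member set) holds.

Planting works backwards from the truth: true eQTL SNPs are chosen per
phenotype; shared eGenes are assigned to one SNP of each member phenotype
(preferring cis, least-loaded SNPs, ≤4 genes per SNP); condition-specific
eGenes fill every remaining SNP so each true eQTL SNP regulates ≥1 gene —
this makes the recovered eQTL:non-eQTL fraction exactly round(f·n)/n under
noise-free settings. Every planted edge is written to ≥1 contact list
(Bernoulli per dataset with a deterministic fallback) and receives a
nominal association p of 10^−U(5,12) in ≥1 tissue; all other tested pairs
draw p ~ U(decoy_floor, 1). Planted co-occurring pathways contain
condition-specific eGenes of every member (8 per phenotype by default) and
no within-combination shared gene, so their driver class is
`condition_specific` by construction. Haplotypes copy one founder vector
per (chromosome, 20 kb block) with flip probability `ld_noise` (0.01 →
r² ≈ 0.92 for same-block pairs; cross-block SNPs are independent); the
truth file records *every* cross-phenotype same-block pair of true eQTL
SNPs, planted or coincidental, because all of them are genuinely high-LD.

The noise-free preset used for planted-truth recovery reduces scale
(GS/MG/MS/ALS = 70/18/90/40 SNPs, 3,000 genes, 12 tissues, 400
haplotypes), sets `ld_noise = 0` (planted r² = 1) and floors decoy
p-values at 0.1: since a BH q-value is bounded below by its own p, no
decoy can reach q < 0.05, making eGene recovery exact rather than
FDR-approximate.

What the generator does **not** emulate: Hi-C distance decay and coverage
biases, realistic allele-frequency spectra, gene-density/length
correlations, LD beyond block-copying, or tissue-sharing structure in
eQTL effects. Passing tests therefore demonstrate correctness of the
pipeline's logic and calibration of its null models on data satisfying the
stated generative assumptions — not robustness to the artefacts of real
Hi-C or GTEx data.

## Numerical and design choices

- **Determinism.** One seed; every stage draws from its own spawned
  SeedSequence stream in a fixed order; per-combination bootstrap streams
  are derived by stable (blake2b) hashing of the combination label. Reports
  contain no timestamps or absolute paths, so identical configurations are
  byte-identical.
- **Degenerate inputs.** Empty eGene sets propagate as empty results, not
  errors; an empty post-threshold SNP table warns; monomorphic SNPs yield
  missing r²; observed overlaps outside the feasible hypergeometric range
  raise.
- **Tie-breaks.** BH uses a stable sort (ties share the same q); SNPs on a
  fragment boundary go right; planting tie-breaks are lexicographic on
  (cis-status, load, distance, rsid).
- **Problem sizes in tests.** The oracle suites use 1,000 random p-vectors
  (length ≤ 500), 100 random toy genomes (≤ 50×50×2), exhaustive
  hypergeometric instances to N = 30, and 50 bootstrap-vs-analytic
  configurations at B = 10,000. The null-calibration check draws two
  size-1,200 sets from a 4,800-gene background over 200 simulations with
  B = 1,500: at these sizes the overlap statistic's sd (~13) keeps the
  discreteness of the empirical p (max atom ≈ 0.03) well below the KS
  resolution at 200 samples, which a max-pmf calculation fixed before the
  test was written.
- **Known limitations.** The pairwise analytic check does not extend to
  k ≥ 3 combinations (bootstrap only); ORA ignores pathway topology by
  design; the LD screen assumes phased haplotypes and does not estimate r²
  from unphased genotypes; `partition_by_dataset` reports per-source
  exclusive counts plus a pooled "shared" bucket when more than two Hi-C
  sources are supplied.
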