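# smseq

A self-contained toolkit for droplet **single-microbe RNA-seq** analysis:
from raw paired FASTQ to taxonomically annotated single cells, sparse
gene-expression matrices, and alignment-validated host-phage
transcriptional associations — plus a synthetic community simulator that
closes the test loop with machine-readable ground truth.

It is aimed at microbiome researchers working with high-throughput
single-bacterium transcriptomics, where each droplet captures one
bacterium (barcoded 20 bp + 8 bp UMI on R1) and a tube-specific
**pre-index** tag on the reverse-transcription primer (12 variants) lets
two bacteria co-encapsulated in one droplet be told apart.

## What it computes

**Read processing** — barcode/UMI extraction, dA-tail/adapter trimming,
knee-point cell calling on the log-log barcode rank curve (the knee is
the largest log-count drop between consecutive count levels), and
Hamming-distance-≤2 merging of error barcodes into accepted barcodes.
Cells are `(merged barcode, pre-index)` pairs, so droplet doublets split
cleanly.

**MIC-Anno** — per-read taxonomic classification by canonical k-mer
hits against an LCA-labelled reference index (k = 21); per cell, read
counts are summed leaf-to-root into clade counts and the annotation
path is chosen root-to-leaf, at each level taking the child with the
largest clade count. Each selected node *t* with clade count
*c* among *C* competing children holding *n* reads total carries an
exact one-sided binomial P-value

&nbsp;&nbsp;&nbsp;&nbsp;P = Pr[ Bin(*n*, 1/*C*) ≥ *c* ],

and the cell's **purity** at a rank is the fraction of its classified
reads inside the annotated clade at that rank.

**MIC-Bac** — unique-best k-mer pseudo-assignment of reads to genes,
directional UMI network dedup (edge u→v iff Hamming(u,v)=1 and
count(u) ≥ 2·count(v)−1), sparse cells × genes matrix (rRNA/tRNA
excluded), the >3 %-of-barcodes species abundance filter, Leiden
clustering, two-sided Wilcoxon rank-sum markers with Bonferroni
correction (exact enumeration for group sizes ≤ 8), Spearman/BH gene
co-occurrence, and read-subsampling saturation curves.

**MIC-Phage** — rRNA/tRNA read removal by k-mer containment, a cells ×
phages UMI matrix, one-genus-vs-rest phage markers (|log2FC| ≥ 0.1),
top-20 most-active phages per genus, and validation of each candidate
(genus, phage) pair against genome alignments: solid associations need
an alignment of **≥ 3 kb** length at **> 80 %** identity between the
phage and a genome of that genus.

**Simulator** — multi-species communities with a known taxonomy,
log-normal per-cell molecule counts, PCR duplicates, barcode/UMI
errors, ambient barcodes, pre-index-resolvable doublets, rRNA
background, carrier-species prophage transcription, and a planted
alignment table, all emitted in standard formats (FASTQ/FASTA/GFF/
BLAST-tabular TSV) with per-read ground truth.

## Worked example

Simulate the canonical community (5 species in 2 genera, 300 cells,
~64k read pairs) and run the whole pipeline:

```bash
smseq sim --out-dir data --seed 7
cat > pipeline.yaml <<EOF
r1: data/reads_R1.fastq
r2: data/reads_R2.fastq
whitelist: data/whitelist.txt
ref_fasta: data/reference.fa
taxonomy_tsv: data/taxonomy.tsv
genes_gff: data/genes.gff
phage_fasta: data/phages.fa
rrna_fasta: data/rrna.fa
alignments_tsv: data/alignments.tsv
outdir: run
seed: 7
EOF
smseq run --config pipeline.yaml
smseq summarize run
```

The run report prints (abridged):

```json
{
  "ledger": {
    "input_reads": 63892,
    "discarded_barcode": 1766,
    "reads_in_cells": 62126,
    "balanced": true
  },
  "knee_threshold": 63,
  "n_cells": 298,
  "n_associations_validated": 4
}
```

and the summary recomputes the headline metrics from the on-disk
outputs:

```json
{
  "n_cells": 298,
  "median_reads_per_cell": 200.5,
  "n_species": 5,
  "median_genes_per_cell": 41.0,
  "median_umis_per_cell": 109.0,
  "n_associations": 6,
  "n_associations_validated": 4
}
```

Reading: every input read is accounted for (conservation ledger
balances); the knee at 63 reads calls 298 cells (285 true droplets, a
few split by pre-index into doublet pairs, no ambient barcodes); all 5
species are annotated; of 6 candidate host-phage associations the 4
with a ≥ 3 kb / > 80 % alignment validate — exactly the 4 prophages the
simulator planted.

Each stage is also available separately (`smseq extract / anno / bac /
phage`) and as library functions (`smseq.readproc`, `smseq.anno`,
`smseq.bac`, `smseq.phage`, `smseq.sim`, `smseq.pipeline`).

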