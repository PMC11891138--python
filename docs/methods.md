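# Methods

This note documents the models and procedures implemented in `smseq`,
the defaults and why they were chosen, what the simulator does and does
not emulate, and the numerical conventions.

## Read structure and extraction

R1 carries a 20 bp cell barcode followed by an 8 bp UMI; R2 carries a
short pre-index tag (one of 12, tube-specific) followed by cDNA. All
offsets and lengths are configurable (`ReadStructure`) because the
physical layout is instrument configuration, not biology; the defaults
put the barcode at offset 0 and the pre-index at the start of R2. The
package ships a synthetic 12-entry, 6 bp whitelist with pairwise
Hamming distance ≥ 3, so a single sequencing error is always uniquely
correctable; any user whitelist file (one sequence per line) can be
substituted. Pre-index matching tolerates one mismatch by default;
equidistant best matches are left unassigned and such reads are dropped
(default) or pooled per barcode. Reads with any N in barcode+UMI are
dropped (N counts as a mismatch in every Hamming comparison — the
conservative reading of an unread base).

Trimming removes terminal dA-tailing artifacts: a 3′ poly-A (or 5′
poly-T) run of ≥ 6 bases, plus configured adapters at up to one
mismatch. The pass iterates to a fixed point, which makes trimming
idempotent by construction.

## Cell calling (knee point)

Barcodes are ranked by descending read count. On the log-log rank/count
curve, real cells form a high plateau and ambient/error barcodes a low
tail; the knee is the inflection between them. We collapse barcodes to
distinct count levels and take the knee as the **largest log-count drop
between consecutive levels** — the cliff is by definition the largest
multiplicative jump in the sorted counts. Every barcode with count ≥
the level at the top of the cliff is accepted. This criterion is
parameter-free, deterministic, and invariant to input order. Two
alternatives were evaluated and rejected: perpendicular distance to the
rank-curve chord tracks the curvature of the cell count distribution
rather than the cliff (on log-normal counts it lands mid-distribution),
and the steepest-slope variant is dominated by the final 2→1 ambient
step when few barcodes are present. Degenerate inputs: fewer than 10
distinct barcodes, or all counts equal, accept everything.

## Barcode merging

Every non-accepted barcode merges into the accepted barcode at minimal
Hamming distance when that distance is ≤ 2; ties go to the accepted
barcode with more reads, then lexicographically. Accepted barcodes
never merge with each other (merging them would conflate cells).
Implementation enumerates the ≤ 2-substitution neighbourhoods of the
accepted barcodes over the alphabet {A,C,G,T,N} into hash maps, which
is exact and linear in the number of accepted barcodes; the test suite
checks it against the quadratic pairwise scan on hundreds of random
instances. Unmergeable barcodes are discarded, and a conservation
ledger asserts on every run that dropped + discarded + assigned equals
the input read count.

## Taxonomic annotation

Classification uses canonical k-mers (lexicographic minimum of a k-mer
and its reverse complement), k = 21 by default — long enough that
chance collisions are negligible at the genome sizes involved, short
enough that an 80 bp read contributes ~60 informative k-mers. The
reference index maps each canonical k-mer to the LCA of all taxa whose
genomes contain it. A read votes with its k-mer hits: each root-to-leaf
path is scored by the summed hits on its nodes, the read is assigned to
the deepest hit node of the best path, and tied best paths resolve to
the LCA of their deepest nodes. Reads with fewer than `min_hits` total
hits stay unclassified. A TSV import path (`read_id, taxon_id`) lets an
external classifier's output replace the internal one.

Per cell, read assignments are summed leaf-to-root into clade
(cumulative) counts; the invariant cumulative(node) = direct(node) +
Σ cumulative(children) is property-tested. Annotation then descends
root-to-leaf, at each level selecting the child with the largest clade
count (ties: larger direct count, then lexicographic taxon id), down to
species or until no child has a nonzero count. For each selected node
we report an exact one-sided binomial P-value for the null that reads
fall uniformly on the C nonzero-count children: P[Bin(n, 1/C) ≥ c_top].
This is the simplest exact null for "did the winner beat chance"; it is
reported for downstream filtering and never truncates the path. A
multinomial or winner-vs-runner-up test could be swapped in behind the
same interface.

Purity at a rank = clade count of the annotated node at that rank ÷
total classified reads of the cell. Unclassified reads enter neither
term; reads classified to ancestors of the annotated node count in the
denominator only. Purity is therefore monotone non-increasing from
genus to species along the annotation path.

## Expression matrices

Reads are pseudo-assigned to features (genes, or phage genomes) by
counting canonical k-mer hits per feature: a read is assigned iff
exactly one feature attains the maximal hit count *and* that count
covers ≥ 50 % of the read's k-mers; multiple maxima are ambiguous and
discarded, preserving unique-mapping semantics. The ambiguity check
precedes the coverage floor, so a read straddling two genes is reported
ambiguous rather than unassigned.

UMI dedup per (cell, feature) bucket uses the directional network:
directed edge u→v when Hamming(u,v) = 1 and count(u) ≥ 2·count(v) − 1;
clusters grow greedily from the highest-count unabsorbed UMI
(lexicographic on ties), absorbing transitively, and the molecule count
is the number of cluster seeds. The matrix entry is that count;
rRNA/tRNA-biotype features are excluded from the gene matrix by
default. Matrices are AnnData objects (sparse counts + cell/feature
metadata) and export as MTX + TSV triplets.

The abundance filter keeps cells whose annotated species holds
**strictly more than 3 %** of cells (the boundary is exclusive: 3 cells
in 100 are removed), with a `keep_all` escape hatch and a configurable
rank.

## Clustering and markers

Clustering is the standard single-cell recipe via scanpy: per-cell
normalisation to 10⁴ counts, log1p, PCA (20 components by default), a
kNN graph (15 neighbours, lowered with a warning for small data), and
Leiden at resolution 0.5 with a fixed random state, so results are
reproducible for a fixed seed.

Markers are one-group-vs-rest two-sided Wilcoxon rank-sum tests on
depth-normalised expression. For group sizes ≤ 8 on both sides the
P-value is computed by full enumeration of the C(n₁+n₂, n₁) rank
assignments (mid-ranks for ties; two-sided P = twice the smaller tail,
capped at 1); larger groups use the tie-corrected normal approximation.
log2 fold change = log2((mean_in + 1)/(mean_out + 1)) on normalised
means; features with |log2FC| below the threshold (0.1 by default, the
value used throughout the phage analysis) or detected in fewer than
`min_pct` of cells are screened out *before* testing, and Bonferroni
correction is applied over the tests actually performed — the screen is
a filter, not a test. Gene co-occurrence is pairwise Spearman on
normalised expression with BH adjustment across pairs; genes with
constant raw counts are flagged rather than correlated.

Saturation curves subsample assigned reads without replacement at fixed
fractions (fixed seed) and rebuild the matrix downstream of assignment,
reporting median genes and UMIs per cell.

## Host-phage association

rRNA/tRNA reads are removed by k-mer containment: a read is dropped
when more than 20 % of its canonical k-mers occur in the rRNA/tRNA
reference set. The 0.2 default is a conservative read-level proxy for
a dedicated rRNA filter and is configurable.

The phage matrix uses the same assignment and dedup semantics with
phage genomes as features. Genus-associated phages come from the marker
machinery one-genus-vs-rest after removing genera with ≤ 3 % of cells;
per genus, the **top 20 phages by total UMI count in that genus** (its
transcriptional activity; ties by fold change, then id) form the
candidate set — positive-direction markers only. Validation then
requires a genome alignment (BLAST outfmt-6 tabular input) between the
phage and any genome of the candidate genus with **length ≥ 3000 bp
and identity strictly > 80 %**: "at least 3 kb" is read as inclusive
and "above 80 %" as strict, so (3000, 80.0) fails and (3000, 80.1)
passes. Validation is a pure, monotone filter: output pairs are a
subset of candidates, and raising either threshold never adds an
association.

## Simulator

The generator emulates: a multi-species community with a rank-complete
taxonomy (species grouped into genera, sharing a configurable ancestral
genome fraction so genus-level LCA k-mers exist); per-cell molecule
counts ~ LogNormal(median 150, σ 0.35) re-sequenced 1 + Poisson(0.3)
times each so UMI dedup sees real PCR duplicates; an rRNA background
(20 % of molecules); cross-species contamination (5 % of molecules
drawn from another species); droplet doublets (5 % of cells share a
barcode with a partner, pre-indexes drawn independently); ambient
barcodes (600 at ≤ 5 reads) to give the rank curve its noise floor; and
per-base substitution errors in barcodes (0.005) and UMIs (0.002).
Prophages are planted by inserting a 4 kb phage segment into the genome
of one carrier species and emitting phage molecules **only from cells
of that species** — transcription requires carrying the prophage — at
10 % activity; the planted alignment table satisfies the ≥ 3 kb/> 80 %
rule exactly for true pairs and violates it for decoys (short or
low-identity alignments). cDNA is error-free by default so assignment
logic is tested separately from barcode recovery; a knob exists for
none of this because each rate is a config field.

Default study conditions (canonical fixture): 5 species in 2 genera,
300 cells, ~60k read pairs, seed 7. The mock-community variant places 5
species in 5 distinct genera. The 5 % contamination default puts
expected species purity at 0.95, inside the 0.89–0.95 species-level
band typical of this assay class. Problem sizes were chosen so the full
simulate-to-associations loop runs in well under a minute on one CPU;
the test suite and acceptance script reuse one session-scoped bundle.

What the simulator does **not** emulate — and what passing tests
therefore do not show about real data: platform-specific error
profiles (indels, quality-dependent substitutions), phylogenetically
realistic genome evolution (genomes are i.i.d. random DNA plus shared
segments, so k-mer classification is easier than for real sister
species), operon structure and expression covariance, partial rRNA
depletion chemistry, and chimeric reads. Accuracy numbers on synthetic
communities are upper bounds.

## Numerical conventions

- Binomial tails via `scipy.stats.binom.sf`, exact to < 1e-12 against
  rational arithmetic for n ≤ 30 (property-tested).
- All tie-breaks are deterministic (count, then lexicographic), so any
  fixed seed reproduces a run bit-for-bit, including the FASTQ emitted
  by the simulator.
- Degenerate inputs: empty cells annotate as unassigned; an empty
  assignment table yields a 0×0 matrix; zero-variance features give
  P = 1 (markers) or a flagged NaN (co-occurrence); an abundance filter
  that would remove every cell raises instead of returning an empty
  matrix.
- Percent identity is validated to [0, 100] and alignment lengths to
  ≥ 1 on input.

## Known limitations

Strain-level resolution is out of scope (k-mer LCA classification
saturates at species). The internal pseudo-assigner is not a spliced
aligner: it handles unspliced bacterial genes, which is the intended
domain. SNP calling, prophage discovery, and phage taxonomy are not
implemented. The in-memory k-mer index targets desk-scale references
(tens of Mb); production-scale databases would need an external
classifier, whose per-read output can be imported.
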