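# Methods

## Coordinates and gene models

All internal coordinates are 0-based half-open (BED convention); GTF I/O
converts from 1-based inclusive at the boundary and nowhere else. A gene
model is the union of the exons of every transcript sharing a `gene_id`,
merged into maximal disjoint blocks. Book-ended exons ([a,b) + [b,c))
merge into one block: they are a single contiguous genomic run, and the
choice matters because it feeds both the exon count (single- vs
multi-exonic split) and the merged sequence. Gene sequences are exon
concatenations in genomic order, reverse-complemented for minus-strand
genes; lower-case genome bases are upper-cased, anything outside ACGTN is
rejected.

## Identification and positional classification

Candidates are retained when their exonic length is **≥ 200 nt** (the
defining lncRNA length bound; exactly 200 is kept). A candidate is
*known* when ≥1 bp of exonic sequence overlaps a reference lncRNA exon on
the same strand, else *novel*. An external coding-potential table removes
entries labelled `coding`; genes absent from the table are kept and
logged, since the table may be partial.

Classification against protein-coding genes uses **span gaps** (0 when
spans overlap; gap = downstream.start − upstream.end in half-open
arithmetic) and a window of **5 000 bp**, in fixed decision order:

1. same-strand coding gene overlapping or within the window →
   `EXCLUDED_SAME_STRAND` (possible unannotated gene extension; this
   outranks any antisense call);
2. opposite-strand coding gene overlapping the span → `AS`;
3. opposite-strand coding gene within the window → `AS_UPSTREAM` /
   `AS_DOWNSTREAM`, sided by the **coding gene's orientation** (upstream =
   beyond its TSS); nearest gene wins, ties go to the upstream call;
4. otherwise `LINCRNA`.

The measuring points (span gap) and the orientation convention for
"upstream" are genuinely open choices — the positional scheme is usually
stated without them — so both are fixed here, documented, and the window
is a parameter. Setting the window to 0 collapses the proximal classes
into `LINCRNA`, which the tests assert.

Display percentages use half-up integer rounding with the unrounded
values always retained; the class denominators exclude `EXCLUDED` records.

## Expression and differential expression

Expression: a gene is expressed in a cell type when its **mean FPKM over
that cell type's replicates strictly exceeds 1.0** in the control or the
stimulated condition (mean-over-replicates is the fixed reading of the
per-condition threshold; per-sample maxima would reward noise).
Differential expression arrives pre-computed (gene, cell type, log2 fold
change, q-value); the filter is **q < 0.05, strictly**, and is monotone
in the threshold. Cell-type specificity is the multiplicity spectrum:
counts of genes in exactly k of the per-cell-type sets, percentages of
the union. Mean ± SEM expression summarizes each gene by its maximum
condition-mean FPKM; SEM = sample SD/√n, defined as 0 for n = 1.

The cis signature pairs each lncRNA with its nearest coding gene by span
gap (ties: smaller start, then lexicographic id; none beyond 1 Mb) and
computes Pearson's r between the paired log2 fold changes, with the
two-sided p from t = r·√((n−2)/(1−r²)) on n−2 df. Zero variance in
either vector is an error, not r = 0.

## Repeat content and masking

Repeat classes collapse to {SINE, LINE, LTR, DNA, other} by the prefix
before "/" in the class/family string. Coverage is measured against
**exonic bases only** — catalog sequences are merged exons, so intronic
repeats cannot affect any sequence analysis. When annotations overlap,
each base counts once under the fixed precedence SINE > LINE > LTR >
DNA > other (the order is arbitrary but must be fixed for the fractions
to sum to one; it is configurable in principle by reordering the class
tuple). Pooled catalog fractions are base-weighted (each exonic base
equal); per-gene fractions are also available. Masking is hard (N) by
default, matching "removal" of repeats before alignment seeding; a soft
(lower-case) mode exists.

## Microdomain search

The search targets 12–50 nt near-exact shared segments, so the aligner is
**ungapped by design**: exact word seeds (default word size 11, the
blastn default) are extended in both directions under an X-drop of 20
score units, trimmed to the maximal-scoring segment, deduplicated per
diagonal (overlapping same-diagonal hits keep the best scorer), and
scored with match +2 / mismatch −3 (blastn defaults). N bases never seed
and never count as identities. Self-pairs and reciprocal duplicates are
excluded; both subject strands are searched, minus-strand hits reporting
forward-subject coordinates.

Significance is Karlin–Altschul: E = K·m·n·exp(−λS) with m, n the pair's
sequence lengths. λ is the unique positive root of
Σᵢⱼ pᵢpⱼ·exp(λ·s(i,j)) = 1, solved by Brent's method to |f| < 1e−10
(closed form for uniform ±1: λ = ln 3). K is **estimated, not exact**: on
seeded random pairs from the background composition, the maximal segment
score is Gumbel with mean (ln(K·m·n)+γ)/λ, so K follows from the mean of
40 simulated maxima at length 300. E-values are therefore approximate
(typically within a small factor of the series value); rankings by E and
by score coincide per pair, which is what the downstream counting uses.
Hits are counted in the closed 12–50 nt window; group comparisons use
one-way ANOVA over per-length-bin counts (the choice of per-bin counts as
the observational unit is itself a convention, flagged as such).

The null model is a set of random sequences matched to the catalog in
**length, AT fraction and masking**: each control is i.i.d. with
P(A)=P(T)=at/2, P(G)=P(C)=(1−at)/2, then carries the corresponding
catalog sequence's N-mask. Mask matching matters: masked bases cannot
seed, so an unmasked control of equal length holds more seedable words
per base and overstates the null — enough, at small catalog scale, to
swallow a planted enrichment.

## Liftover and synteny

UCSC chains are parsed with their block sums validated against the header
spans; the source side must be '+' (UCSC convention), the target may be
'−', in which case lifted coordinates are flipped through the target
size. An interval maps block by block; the best chain (most mapped bases,
then score) represents it, and the result is kept when the mapped-base
fraction is ≥ `min_match` (default 0.95, the liftOver same-species
default, configurable downward for cross-species chains). Unmapped is a
normal outcome, not an error. Chains built from an explicit edit list
(deletions, insertions, inversions) are exact by construction; inversions
are emitted as separate '−'-strand chains.

Synteny: a catalog-A gene pairs with every catalog-B gene its lifted span
overlaps by ≥1 bp, strand-agnostic (orientation belongs to the chain).
Pairwise sequence conservation runs the aligner on the two gene
sequences, merges hit intervals on the query, and reports covered bases
as a percent of the **query** gene's length (the denominator must be
fixed by convention; the query side is the species being surveyed).
Positional conservation is the mean of a per-base 0–1 score track over
exonic bases, excluding uncovered positions from both numerator and
denominator; a gene with no covered exonic base has no defined score.

## Epigenomic overlap

A gene overlaps the peak set when its **span** (not promoter) shares ≥1
bp with any peak — the locus-overlap reading of "% genomic overlap".
TSS metaprofiles average bedGraph coverage in `[TSS−3000, TSS+3000)` with
30-bp bins (200 bins); the TSS is the span start ('+') or span end − 1
('−'), minus-strand rows are reversed so bins run upstream→downstream in
gene orientation, and windows beyond chromosome ends contribute zero so
the matrix stays rectangular. Bin means come from an exact cumulative
integral of the step function, not sampling.

## The synthetic generator

The generator emulates the full input bundle with planted truth. Layout
is slot-based: chromosomes divide into 25-kb slots whose interiors hold
at most one coding gene plus at most one lncRNA; inter-slot spacing
guarantees >5 kb between genes of different slots, so each planted
positional class is exact by construction (proximal classes are planted
at gaps of 0.5–4 kb on the geometrically correct side and strand).
Defaults — the conditions every test runs under — are: 2 chromosomes ×
1 Mb per species, 60 coding genes (3 exons), 10 lncRNAs per positional
class (2 exons), AT fraction 0.58 (the catalog's AT richness), 4 cell
types × control/stimulated × 3 replicates, planted |log2FC| ≥ 2, cis
correlation ρ = 0.7, a fixed 20-nt motif in 12 carrier genes, repeat
density 0.25 per exon, 8 chain edits, 10 syntenic partners. The full
bundle generates in ~1 s and the complete pipeline over it runs in a few
seconds, which is the problem size all end-to-end tests use.

Expression is log-normal around per-(gene, cell type) baselines with
replicate noise of 0.3 log2 units — a realistic replicate spread for
expressed genes, and one under which the generator's own DE procedure
(two-sample t-test on log2 FPKM, Benjamini–Hochberg within cell type)
recovers planted DE calls with high power at 3 vs 3 replicates. That DE
table is a **stand-in** written by the generator itself: production DE
callers (negative-binomial count models) are out of scope, and the
t-test/BH table exists so the intake and summary operations have a
truth-linked input, not to reproduce any particular caller. Planted
lncRNA fold changes have magnitude ≥ the configured effect; partner mRNA
fold changes are ρ·(lncRNA value) + Gaussian noise scaled so the
population correlation equals ρ. One master seed drives per-stage spawned
streams, so adding a stage never perturbs earlier outputs and equal seeds
give byte-identical bundles.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: genomes are i.i.d. with no
repeat-derived homology or compositional domains, so background alignment
hit rates are lower and cleaner than in real catalogs; transcript
structure is minimal (second transcripts are exon subsets); DE truth is
binary with fixed-magnitude effects rather than a continuous effect
distribution; chains contain a handful of planted edits rather than
genome-wide rearrangement; and coverage bumps are noiseless triangles, so
epigenomic separations are sharper than any real ChIP experiment.

## Degenerate inputs and tie-breaks (summary)

Unstranded records are rejected at classification/profiling time; empty
gene sets, empty sequences and zero-variance correlation inputs raise
rather than return sentinels; parse errors name the offending line. Ties
break deterministically everywhere (nearest gene → smaller start →
lexicographic id; upstream before downstream; higher score for
same-diagonal hits), so all outputs are reproducible across runs and
platforms.
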