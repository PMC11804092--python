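# Methods

This note records the models, parameter choices and numerical conventions
behind `panins`, and what the synthetic cohort does and does not emulate.

## Coordinates and sequences

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted at the parser and nowhere else. Breakpoints are zero-width
positions. Sequences are uppercase over {A,C,G,T,N}; other letters map to N
with a counted warning, so k-mer code stays total. Insertion breakpoints are
**left-aligned** (the VCF convention): while the last inserted base equals
the reference base immediately left of the breakpoint, the allele rotates
one base left. The synthetic generator normalizes its truth the same way,
which is what makes "breakpoint exact" well defined.

## Alignment engine

One scoring scheme is used everywhere a threshold is stated: match +1,
mismatch −4, gap open −6, gap extend −1 (a gap of length *g* costs
6 + (g−1)). Identity is matches / alignment columns; query coverage is
aligned query bases / query length.

* **Local alignment** is seed-and-extend: canonical 11–21-mer seeds cluster
  by diagonal, each cluster defines a window padded 64 bp beyond the seed
  extents, and an exact affine Smith–Waterman runs inside the window. The
  row recurrence exploits the fact that, with open ≥ extend, the best
  horizontal-gap predecessor never itself ends in a horizontal gap, so the
  within-row dependency reduces to a running maximum and rows vectorize.
  Tests hold the result to a classic three-matrix DP oracle (score equal,
  identity within one column).
* **Read mapping** is gapless: candidate placements come from exact seed
  hits at three read offsets, every candidate is rescored over its full
  length, and a read maps when its best score reaches 0.6 of the maximum
  (≈ 92% identity). Gapless placement is exact here because the simulator's
  error model is substitution-only; the same acceptance rule backs both the
  single-pair API and the vectorized batch path used at cohort scale.
* **Breakpoint resolution** anchors a contig to the reference with k-mers
  unique in both (k = 21), keeps the longest colinear chain, and walks exact
  matches inward from the flanking anchors; microhomology overshoot is
  trimmed and the breakpoint left-aligned. A 7 kb extension window can span
  two neighbouring insertions, so resolution prefers the event overlapping
  the read cluster that produced the window.
* **Mash**: canonical k-mers hashed with splitmix64; bottom-1000 sketch at
  k = 21 (the cited tool's defaults); J = 0 capped at distance 1.0.

## Pipeline thresholds

Published pipeline values, frozen in `PipelineParams` and recorded in every
report header: cluster depth band [8, 100]; 7,000 bp cluster extension;
≥ 50 bp insertions; ≥ 50 unique (unmasked) bases; reference-match exclusion
at ≥ 95% identity and 100% query coverage; BBH at 95/95; genotype presence
at ≥ 80% coverage and ≥ 90% consensus identity; MAF ≥ 5%; 300 bp TE flanks;
20 kb nearest-gene window; > 50 bp graph segments (strict); species matches
at 95/95. Values the original left to external tools are explicit defaults
here: cluster merge gap 100 bp, breakpoint slop 10 bp and merge identity
0.95; SDUST window 64 / threshold 20; repeat hits at ≥ 80% identity and
≥ 30 bp; lineage assignment needs ≥ 80% identity over ≥ 50% of the contig.
"Unique" bases are those unmasked by the union of interspersed and
low-complexity masks, and low-complexity bases count as non-unique.

SDUST scores every substring of ≤ 64 bases as Σ c_t(c_t−1)/2 divided by the
substring's triplet count and reports the merged union of substrings scoring
> threshold/10; production scans incrementally, and the test oracle rescores
each substring independently.

## Graph model

Only insertion bubbles are modeled: the graph exists to carry non-reference
sequence and core/flexible statistics, not SNVs or deletions. Backbone
segments split lazily at breakpoints; ids are `ref_<chrom>_<start offset>`
so they are stable across runs. The reference label counts as one of the
n genomes when deciding core membership (the published core covers reference
bases, though its text says "shared by all assemblies" — membership is
decided explicitly on origin sets). A reference segment counts as traversed
by an assembly when the assembly's anchored span reaches within 200 bp of
it; anchors are sparse at sequence ends, and without the allowance terminal
segments would never be core.

## Genotyping

Cohort reads are genotyped against a **NUI panel**: the reference with every
final NUI spliced at its breakpoint — per NUI this is exactly the
pseudohaplotype context (same flanks, same allele) while costing one mapping
pass per sample. Coverage is the fraction of NUI positions with depth ≥ 1
(no depth floor; configurable); consensus is the majority base with ties
resolved toward the panel base. MAF is defined on sample-level presence
frequency, not diploid allele counts, matching a present/absent matrix.
PCA centers but does not scale the 0/1/2 matrix and eigendecomposes its
covariance; the cladogram uses Jaccard distances with average linkage
(UPGMA), with samples pre-sorted by id so ties resolve deterministically,
serialized as an ultrametric Newick (a join at linkage distance d sits at
height d/2).

## Synthetic cohort: what it emulates, and what it does not

The generator reproduces the *shape* of an indicine-cattle pangenome study:
a multi-chromosome reference with 30% interspersed LINE/SINE/LTR/DNA copies
(fragmentary, 5–15% diverged, both strands); insertions of 50 bp–50 kb drawn
from a log-uniform mixture skewed small, with ~60% of insertion bases from
TE fragments (LINE-weighted, 8–15% diverged so insertion interiors do not
cross-map to reference repeat copies); five breeds of 20/19/20/20/19
samples with diploid genotypes drawn binomially from Beta(0.3, 0.3)
frequencies truncated to [0.01, 0.99]; two pseudohaplotypes per individual
(heterozygous alleles on a recorded random haplotype); and 30X paired
100 bp reads with 0.1% substitution errors. Every insertion keeps ≥ 70
unique bases so the planted truth is callable under the ≥ 50-unique-base
retention rule, and all carriers of an insertion share the identical allele
sequence (identity by descent).

It does **not** emulate: indels or quality-score structure in reads,
linked-read barcodes, assembly errors (haplotypes are exact splices;
fragmentation to a target N50 is available but off by default), allele-age
structure in TE divergence, or reference gaps/segmental duplications (these
enter as externally supplied BED files). Passing tests therefore show the
algorithms are correct under clean assemblies and substitution-only noise —
not that the pipeline is robust to assembly artifacts or alignment-ambiguous
repeats at biobank scale.

## Problem sizes

The shipped presets are the package's study conditions: discovery runs on a
2 Mb, 2-chromosome reference with 5 assembled individuals, 60 clean-context
insertions of 50 bp–5 kb and 30X reads; genotyping runs a 98-sample cohort
at 30X over a 200 kb reference with 30 insertions; PCA separation uses a
breed-structured cohort with frequency offsets of 0.4. These sizes keep a
full run to a few minutes on one CPU while leaving every filter and
threshold exercised.

## Known limitations

Deletions, inversions and translocations are out of scope; the graph cannot
represent an insertion at a chromosome's first base; lineage screening uses
a single best hit (not a vote over top hits); repeat masking at 80%/30 bp is
less sensitive than a curated-library masker, so diverged repeat fragments
below the threshold count as unique sequence; and the display convention for
percentages is round-half-up at the printed precision, with raw fractions
always available alongside.
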