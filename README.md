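# panins

Desk-scale discovery and characterization of **non-reference insertions**
(NUIs) for cattle-style pangenome cohorts.

Structural-variant studies of under-represented populations routinely find
megabases of sequence that individuals carry but the reference genome lacks.
`panins` re-implements that analysis as a self-contained Python pipeline for
anyone who wants to study, teach or prototype it without terabytes of raw
data: it discovers breakpoint-resolved insertions from pseudohaplotype
assemblies and short reads by two independent routes, intersects them,
genotypes the result across a cohort, and characterizes the common
insertions by repeat content, genic context, population structure and
cross-species sharing. A fully truth-annotated synthetic-cohort generator
stands in for the original sequencing data, so every stage can be scored
exactly.

## The method

Two discovery branches produce candidate insertions against a reference
genome *R*:

**Alignment branch.** Reads that fail to map to *R* (best gapless placement
scoring < 0.6 of the maximum under the scheme +1/−4 match/mismatch) are
remapped onto both pseudohaplotypes of their sample. Maximal runs with depth
in [8X, 100X] become read clusters; each cluster is extended by 7,000 bp per
side (clipped at contig ends) and resolved against *R* by colinear anchoring:
the best anchor pair on one chromosome whose query gap is ≥ 50 bp and whose
reference gap is within a 10 bp slop defines the insertion sequence and a
zero-width, left-aligned breakpoint. Calls are dropped when the sequence
realigns to *R* at ≥ 95% identity over 100% of its length, when the
breakpoint falls in an assembly gap or segmental duplication, or when fewer
than 50 bases survive repeat + low-complexity masking. Per-sample calls merge
into a non-redundant set when breakpoints agree within 10 bp and sequences
match at ≥ 95% identity and ≥ 95% mutual coverage.

**Graph branch.** Assemblies are ordered by ascending Mash distance
d = −(1/k)·ln(2J/(1+J)) to *R* (k = 21, sketch 1000) and incrementally
augment a backbone graph: each insertion > 50 bp either joins an existing
non-reference segment at the same junction (≥ 95% identity/coverage) or
splits the backbone and adds a new segment with two reference↔non-reference
edges. Core segments carry all genomes; the flexible remainder splits into
shared (≥ 2 genomes) and singleton nodes.

The branches are intersected by **best bidirectional hits** (BLAST-style
reciprocal best matches at ≥ 95% identity and ≥ 95% query coverage). The
final NUIs are genotyped in a read cohort: a NUI is *present* in a sample
when ≥ 80% of its positions are covered and the read consensus matches at
≥ 90% identity; insertions with minor allele frequency
MAF = min(f, 1−f) ≥ 0.05 across samples form the common-insertion (BICI)
set, summarized by a 0/1/2 occurrence matrix, covariance-PCA and UPGMA
clustering on Jaccard distances, major-TE composition with 300 bp flank
analysis, nearest genes within 20 kb, and presence in related species at
≥ 95% identity/coverage.

## Worked example

```python
from panins.pipeline import (make_discovery_cohort, run_discovery,
                             run_graph, run_intersection)

data = make_discovery_cohort(seed=42, chrom_len=250_000, n_insertions=12)
disc = run_discovery(data)
graph = run_graph(data)
inter = run_intersection(disc, graph, data)

m = disc["metrics"]
print(f"NUIs called: {m['n_calls']}  (truth carried: {m['n_truth_carried']})")
print(f"recall {m['recall']:.3f}  precision {m['precision']:.3f}  "
      f"exact breakpoints {m['breakpoint_exact_fraction']:.3f}")
s = graph["stats"]
print(f"graph: {s.n_nodes} nodes ({s.n_nodes_nonref} non-reference, "
      f"{s.bp_nonref} bp), core {s.pct_core}%")
print(f"final intersected NUIs: {inter['metrics']['n_final']} "
      f"({inter['metrics']['final_bp']} bp)")
```

prints

```
NUIs called: 10  (truth carried: 10)
recall 1.000  precision 1.000  exact breakpoints 1.000
graph: 22 nodes (10 non-reference, 13938 bp), core 97.29%
final intersected NUIs: 10 (13938 bp)
```

Ten of the twelve planted insertions are carried by at least one of the five
simulated individuals; both branches recover all ten with exact breakpoints,
and the reciprocal-best-hit intersection keeps all of them. The graph's core
(reference bases present in every genome) covers 97.29% of its total
sequence; the 10 non-reference segments hold the 13.9 kb of inserted
sequence.

A thin CLI mirrors the library: `panins simulate --preset small --seed 1`
writes a synthetic cohort (reference, truth tables, haplotype FASTAs, paired
FASTQ), and `panins run --seed 1 --out report.json` runs discovery, graph,
intersection and genotyping on a preset and writes the summary report.

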