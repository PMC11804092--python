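"""Genic context and cross-species sharing of common insertions.

Breakpoints are classified exonic / intronic / intergenic against gene
models, intergenic breakpoints search for the nearest gene within 20 kb, and
the insertion sequences are searched in related-species genomes (95%
identity, 95% query coverage) to build a sharing matrix and its summary.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .io_formats import DEFAULT_PARAMS, GeneModel, Interval, PipelineParams
from .kmer_align import KmerIndex, local_align


def percentage(n: float, d: float, digits: int = 2) -> float:
    """round-half-up percentage at the displayed precision."""
    if d == 0:
        return 0.0
    q = Decimal(100 * n) / Decimal(d)
    exp = Decimal(1).scaleb(-digits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Breakpoint classification
# ---------------------------------------------------------------------------

def classify_breakpoints(bicis, genes: list[GeneModel]) -> dict:
    """Per-BICI genic category plus gene-level tallies.

    A zero-width breakpoint is exonic when inside any exon, else intronic
    when inside a gene span, else intergenic; overlapping genes each get
    credit but the BICI counts once per category (exonic dominates).
    """
    per_bici = {}
    gene_hits: dict[str, list] = {}
    for call in bicis:
        bp = call.ref_breakpoint
        category = "intergenic"
        for g in genes:
            if g.span.chrom != bp.chrom or not g.span.contains(bp.start):
                continue
            gene_hits.setdefault(g.gene_id, []).append(call.id)
            if any(ex.contains(bp.start) for ex in g.exons):
                category = "exonic"
            elif category != "exonic":
                category = "intronic"
        per_bici[call.id] = category
    counts = {"exonic": 0, "intronic": 0, "intergenic": 0}
    for cat in per_bici.values():
        counts[cat] += 1
    biotype_tally: dict[str, int] = {}
    by_id = {g.gene_id: g for g in genes}
    for gid in gene_hits:
        bt = by_id[gid].biotype
        biotype_tally[bt] = biotype_tally.get(bt, 0) + 1
    multi = sorted(gid for gid, hits in gene_hits.items() if len(hits) >= 2)
    return {"per_bici": per_bici, "category_counts": counts,
            "genes_hit": {g: sorted(v) for g, v in sorted(gene_hits.items())},
            "biotype_tally": biotype_tally, "genes_multi_bici": multi,
            "genic": counts["exonic"] + counts["intronic"],
            "intergenic": counts["intergenic"]}


def nearest_gene(breakpoint: Interval, genes: list[GeneModel],
                 window: int | None = None,
                 params: PipelineParams = DEFAULT_PARAMS) -> list[tuple]:
    """Nearest gene(s) within `window` bp of the breakpoint (distance to the
    nearer span boundary; 0 inside a gene).  Exact ties all report."""
    window = params.nearest_gene_window if window is None else window
    best: list[tuple] = []
    best_d = None
    for g in genes:
        if g.span.chrom != breakpoint.chrom:
            continue
        p = breakpoint.start
        if g.span.contains(p):
            d = 0
        elif p < g.span.start:
            d = g.span.start - p
        else:
            d = p - g.span.end
        if d > window:
            continue
        if best_d is None or d < best_d:
            best, best_d = [(g, d)], d
        elif d == best_d:
            best.append((g, d))
    return sorted(best, key=lambda x: x[0].gene_id)


# ---------------------------------------------------------------------------
# Cross-species sharing
# ---------------------------------------------------------------------------

def species_presence(bicis, species_indexes: dict,
                     params: PipelineParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """BICI × species boolean presence: present when any hit in that species'
    genome reaches species_identity and species_coverage."""
    species = sorted(species_indexes)
    rows = {}
    for call in bicis:
        row = {}
        for sp in species:
            index = species_indexes[sp]
            present = False
            for h in local_align(call.seq, index, min_score=20, max_windows=8):
                if (h.identity >= params.species_identity
                        and h.query_coverage >= params.species_coverage):
                    present = True
                    break
            row[sp] = present
        rows[call.id] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=species).fillna(False)


def sharing_summary(matrix: pd.DataFrame) -> dict:
    """Counts and display percentages from the sharing matrix."""
    n = len(matrix)
    per_species = matrix.sum(axis=0).astype(int).to_dict()
    row_sums = matrix.sum(axis=1)
    any_species = int((row_sums >= 1).sum())
    all_species = int((row_sums == len(matrix.columns)).sum()) if len(matrix.columns) else 0
    unique_rows = matrix.loc[row_sums == 1] if n else matrix
    unique_per_species = {sp: int(unique_rows[sp].sum()) for sp in matrix.columns}
    return {
        "n_bicis": n,
        "per_species": per_species,
        "any_species": any_species,
        "any_species_pct": percentage(any_species, n) if n else 0.0,
        "all_species": all_species,
        "all_species_pct": percentage(all_species, n) if n else 0.0,
        "unique_per_species": unique_per_species,
    }


# ---------------------------------------------------------------------------
# Master report
# ---------------------------------------------------------------------------

def report(graph_stats=None, discovery=None, intersection=None,
           genotyping=None, repeats=None, annotation=None, sharing=None,
           params: PipelineParams = DEFAULT_PARAMS) -> dict:
    """Deterministic JSON-ready report assembling the per-stage summaries.

    Every value is taken from an upstream artifact; empty inputs yield empty
    sections.
    """
    out = {"parameters": {k: getattr(params, k)
                          for k in vars(params)}}
    if discovery is not None:
        out["discovery"] = discovery
    if graph_stats is not None:
        gs = graph_stats
        out["graph"] = {
            "nodes": {"total": gs.n_nodes, "reference": gs.n_nodes_ref,
                      "non_reference": gs.n_nodes_nonref},
            "bases": {"total": gs.bp_total, "reference": gs.bp_ref,
                      "non_reference": gs.bp_nonref},
            "edges": {"total": gs.edges_total, "ref_ref": gs.edges_ref_ref,
                      "ref_nonref": gs.edges_ref_nonref,
                      "nonref_nonref": gs.edges_nonref_nonref},
            "core": {"nodes": gs.core_nodes, "bp": gs.core_bp,
                     "pct": gs.pct_core},
            "flexible": {"nodes": gs.flexible_nodes, "bp": gs.flexible_bp,
                         "pct": gs.pct_flexible,
                         "shared_nodes": gs.flexible_shared_nodes,
                         "single_nodes": gs.flexible_single_nodes},
            "per_assembly_added": {k: {"nodes": v[0], "bp": v[1]}
                                   for k, v in gs.per_assembly_added.items()},
        }
    if intersection is not None:
        out["intersection"] = intersection
    if genotyping is not None:
        out["genotyping"] = genotyping
    if repeats is not None:
        out["repeats"] = repeats
    if annotation is not None:
        out["annotation"] = annotation
    if sharing is not None:
        out["sharing"] = sharing
    return out
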