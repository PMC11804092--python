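"""Multi-assembly graph branch.

A reference backbone is augmented incrementally with assemblies ordered by
ascending Mash distance; each assembly contributes insertion bubbles as
non-reference segments.  Only insertion bubbles are modeled — the graph
exists to yield non-reference sequence and core/flexible statistics, not to
represent SNVs or deletions.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .io_formats import (DEFAULT_PARAMS, GenomeSequence, PangenomeGraph,
                         PipelineParams, REFERENCE_LABEL)
from .kmer_align import ReferenceScanner, mash_distance, mash_sketch


# ---------------------------------------------------------------------------
# Assembly ordering
# ---------------------------------------------------------------------------

def order_assemblies(reference: list[GenomeSequence], assemblies: dict,
                     k: int = 21, sketch_size: int = 1000) -> list[tuple]:
    """Assemblies sorted by ascending Mash distance to the reference, ties by
    name.  Returns [(name, distance), ...]."""
    ref_sketch = mash_sketch("".join(s.seq for s in reference), k, sketch_size)
    rows = []
    for name in sorted(assemblies):
        sk = mash_sketch("".join(s.seq for s in assemblies[name]), k, sketch_size)
        rows.append((name, mash_distance(ref_sketch, sk)))
    rows.sort(key=lambda r: (r[1], r[0]))
    return rows


# ---------------------------------------------------------------------------
# Backbone and augmentation
# ---------------------------------------------------------------------------

def build_backbone(reference: list[GenomeSequence]) -> PangenomeGraph:
    """One reference segment per chromosome; no inter-chromosome links."""
    g = PangenomeGraph()
    for chrom in reference:
        sid = f"ref_{chrom.name}_0"
        g.add_segment(sid, chrom.seq, {REFERENCE_LABEL})
        g.backbone_order.append(sid)
    return g


def _ref_layout(graph: PangenomeGraph) -> dict:
    """chrom -> ordered list of (start_offset, end_offset, segment_id)."""
    layout: dict[str, list] = {}
    for sid in graph.backbone_order:
        chrom = sid.split("_")[1]
        offset = int(sid.split("_")[2])
        layout.setdefault(chrom, []).append(
            (offset, offset + len(graph.seq(sid)), sid))
    for rows in layout.values():
        rows.sort()
    return layout


def _split_backbone(graph: PangenomeGraph, layout: dict, chrom: str, bp: int) -> tuple:
    """Ensure a backbone junction at `bp`; returns (left_segment,
    right_segment) flanking the junction."""
    rows = layout[chrom]
    for i, (s, e, sid) in enumerate(rows):
        if s < bp < e:
            seq, origins = graph.segments.pop(sid)
            left_id = f"ref_{chrom}_{s}"
            right_id = f"ref_{chrom}_{bp}"
            graph.add_segment(left_id, seq[:bp - s], set(origins))
            graph.add_segment(right_id, seq[bp - s:], set(origins))
            # rewire links: a link leaving sid exits its right end (now the
            # right half); a link entering sid arrives at its left end
            old_links = [l for l in graph.links if l[0] == sid or l[2] == sid]
            for a, oa, b, ob in old_links:
                graph.links.discard((a, oa, b, ob))
                na = right_id if a == sid else a
                nb = left_id if b == sid else b
                graph.links.add((na, oa, nb, ob))
            graph.add_link(left_id, "+", right_id, "+")
            k = graph.backbone_order.index(sid)
            graph.backbone_order[k:k + 1] = [left_id, right_id]
            rows[i:i + 1] = [(s, bp, left_id), (bp, e, right_id)]
            return left_id, right_id
        if bp == s and i > 0:
            return rows[i - 1][2], sid
        if bp == e and i + 1 < len(rows):
            return sid, rows[i + 1][2]
    if bp == rows[0][0]:
        raise ValueError("insertion at chromosome start is not representable")
    raise ValueError(f"breakpoint {chrom}:{bp} outside backbone")


def _existing_nonref_at(graph: PangenomeGraph, left_id: str, right_id: str) -> list[str]:
    """Non-reference segments bridging the junction left_id -> right_id."""
    out = []
    from_left = {b for a, _oa, b, _ob in graph.links if a == left_id}
    for sid in from_left:
        if REFERENCE_LABEL in graph.origins(sid):
            continue
        if any(a == sid and b == right_id for a, _oa, b, _ob in graph.links):
            out.append(sid)
    return sorted(out)


def _seq_match(a: str, b: str, identity: float, coverage: float) -> bool:
    if min(len(a), len(b)) / max(len(a), len(b)) < coverage:
        return False
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b)) >= identity


def augment(graph: PangenomeGraph, assembly_name: str,
            assembly_seqs: list[GenomeSequence],
            params: PipelineParams = DEFAULT_PARAMS,
            scanner: ReferenceScanner | None = None) -> tuple[int, int]:
    """Add one assembly to the graph; returns (nodes_added, bp_added).

    Each contig is scanned against the original reference coordinates; every
    insertion longer than graph_min_segment either joins an existing
    non-reference segment at (near) the same junction — when it matches at
    merge identity/coverage — or becomes a new segment bridging a backbone
    split.  Reference segments spanned by the contig's aligned anchors gain
    the assembly in their origin set.
    """
    layout = _ref_layout(graph)
    reference = [GenomeSequence(chrom,
                                "".join(graph.seq(sid) for _s, _e, sid in rows))
                 for chrom, rows in layout.items()]
    if scanner is None:
        scanner = ReferenceScanner(reference, k=params.mash_k)
    added_nodes = 0
    added_bp = 0
    counter = sum(1 for sid in graph.segments if sid.startswith(f"{assembly_name}_"))
    any_anchor = False
    for contig in assembly_seqs:
        events, spans = scanner.scan(contig.seq,
                                     min_insertion_len=params.graph_min_segment + 1,
                                     max_target_gap=params.merge_breakpoint_slop,
                                     with_span=True)
        if spans:
            any_anchor = True
        for chrom, (t0, t1) in spans.items():
            # anchors are sparse near sequence ends; a segment counts as
            # traversed when the anchored span reaches within 200 bp of it
            for s, e, sid in layout.get(chrom, []):
                if s >= t0 - 200 and e <= t1 + 200:
                    graph.origins(sid).add(assembly_name)
        for ev in events:
            if len(ev["seq"]) <= params.graph_min_segment:
                continue
            chrom, bp, seq = ev["chrom"], ev["breakpoint"], ev["seq"]
            merged = False
            # look for an existing bubble at a junction within the slop
            for cand_bp in _junctions_near(layout[chrom], bp, params.merge_breakpoint_slop):
                li, ri = _split_backbone(graph, layout, chrom, cand_bp)
                for sid in _existing_nonref_at(graph, li, ri):
                    if _seq_match(seq, graph.seq(sid), params.merge_identity, 0.95):
                        graph.origins(sid).add(assembly_name)
                        merged = True
                        break
                if merged:
                    break
            if merged:
                continue
            left_id, right_id = _split_backbone(graph, layout, chrom, bp)
            counter += 1
            sid = f"{assembly_name}_{counter}"
            graph.add_segment(sid, seq, {assembly_name})
            graph.add_link(left_id, "+", sid, "+")
            graph.add_link(sid, "+", right_id, "+")
            added_nodes += 1
            added_bp += len(seq)
    if not any_anchor and assembly_seqs:
        import logging
        logging.getLogger("panins").warning(
            "assembly %s has no anchor to the backbone", assembly_name)
    return added_nodes, added_bp


def _junctions_near(rows: list, bp: int, slop: int) -> list[int]:
    """Existing junction offsets within `slop` of bp, then bp itself."""
    near = [s for s, _e, _sid in rows[1:] if abs(s - bp) <= slop]
    return sorted(near, key=lambda x: (abs(x - bp), x)) + ([bp] if bp not in near else [])


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass
class GraphStats:
    n_nodes: int
    n_nodes_ref: int
    n_nodes_nonref: int
    bp_total: int
    bp_ref: int
    bp_nonref: int
    edges_total: int
    edges_ref_ref: int
    edges_ref_nonref: int
    edges_nonref_nonref: int
    core_nodes: int
    core_bp: int
    flexible_nodes: int
    flexible_bp: int
    flexible_shared_nodes: int
    flexible_single_nodes: int
    pct_core: float
    pct_flexible: float
    per_assembly_added: dict


def graph_stats(graph: PangenomeGraph, n_genomes: int,
                per_assembly_added: dict | None = None) -> GraphStats:
    """Node/edge/bp tallies and the core/flexible partition.

    Core segments carry all `n_genomes` labels (the reference counts as one
    genome); flexible segments split into shared (≥2 genomes) and singletons.
    Percentages are bp shares of the total, rounded to 2 decimals.
    """
    n_ref = n_nonref = bp_ref = bp_nonref = 0
    core_n = core_bp = flex_n = flex_bp = shared_n = single_n = 0
    for sid, (seq, origins) in graph.segments.items():
        is_ref = REFERENCE_LABEL in origins
        if is_ref:
            n_ref += 1
            bp_ref += len(seq)
        else:
            n_nonref += 1
            bp_nonref += len(seq)
        if len(origins) >= n_genomes:
            core_n += 1
            core_bp += len(seq)
        else:
            flex_n += 1
            flex_bp += len(seq)
            if len(origins) >= 2:
                shared_n += 1
            else:
                single_n += 1
    err = enr = enn = 0
    for a, _oa, b, _ob in graph.links:
        ra, rb = graph.is_reference(a), graph.is_reference(b)
        if ra and rb:
            err += 1
        elif ra or rb:
            enr += 1
        else:
            enn += 1
    bp_total = bp_ref + bp_nonref
    pct_core = round(100.0 * core_bp / bp_total, 2) if bp_total else 0.0
    return GraphStats(
        n_nodes=n_ref + n_nonref, n_nodes_ref=n_ref, n_nodes_nonref=n_nonref,
        bp_total=bp_total, bp_ref=bp_ref, bp_nonref=bp_nonref,
        edges_total=err + enr + enn, edges_ref_ref=err,
        edges_ref_nonref=enr, edges_nonref_nonref=enn,
        core_nodes=core_n, core_bp=core_bp,
        flexible_nodes=flex_n, flexible_bp=flex_bp,
        flexible_shared_nodes=shared_n, flexible_single_nodes=single_n,
        pct_core=pct_core, pct_flexible=round(100.0 - pct_core, 2),
        per_assembly_added=dict(per_assembly_added or {}))


def extract_nonref(graph: PangenomeGraph, min_len: int | None = None,
                   params: PipelineParams = DEFAULT_PARAMS) -> list[GenomeSequence]:
    """Non-reference segments strictly longer than graph_min_segment, in
    stable id order."""
    cut = params.graph_min_segment if min_len is None else min_len
    out = []
    for sid in sorted(graph.segments):
        seq, origins = graph.segments[sid]
        if REFERENCE_LABEL not in origins and len(seq) > cut:
            out.append(GenomeSequence(sid, seq))
    return out


def build_pangenome(reference: list[GenomeSequence], assemblies: dict,
                    params: PipelineParams = DEFAULT_PARAMS,
                    ) -> tuple[PangenomeGraph, GraphStats, list]:
    """Full graph branch: Mash ordering, incremental augmentation, stats."""
    graph = build_backbone(reference)
    scanner = ReferenceScanner(reference, k=params.mash_k)
    order = order_assemblies(reference, assemblies, k=params.mash_k,
                             sketch_size=params.mash_sketch)
    added = {}
    for name, _dist in order:
        added[name] = augment(graph, name, assemblies[name], params, scanner)
    stats = graph_stats(graph, n_genomes=len(assemblies) + 1,
                        per_assembly_added=added)
    return graph, stats, order
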