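"""Alignment-branch insertion caller.

Unmapped reads are collected per sample, remapped onto both pseudohaplotypes,
clustered by depth, the clusters extended and resolved against the reference
to breakpoint precision, then filtered (reference-match, gap/segdup overlap,
unique-base content) and merged across samples into a non-redundant NUI set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .io_formats import DEFAULT_PARAMS, GenomeSequence, Interval, PipelineParams
from .kmer_align import (KmerIndex, ReferenceScanner, decode_seq, local_align,
                         map_reads_batch)


@dataclass(frozen=True)
class ReadCluster:
    hap_iv: Interval
    mean_depth: float
    n_reads: int

    def __post_init__(self):
        if self.n_reads < 1:
            raise ValueError("cluster must contain reads")


@dataclass
class InsertionCall:
    id: str
    ref_breakpoint: Interval          # zero-width
    seq: str
    hap_source: tuple                 # (sample, haplotype index, Interval on contig)
    left_anchor_len: int = 0
    right_anchor_len: int = 0
    unique_bases: int = -1            # filled by filter_candidates
    sample_occurrence: set = field(default_factory=set)

    def __post_init__(self):
        if len(self.seq) < 50:
            raise ValueError("insertion shorter than 50 bp")


# ---------------------------------------------------------------------------
# Unmapped-read extraction
# ---------------------------------------------------------------------------

def unmapped_reads(map1: dict, map2: dict) -> np.ndarray:
    """Pair indices where either mate failed to map; mates of unmapped reads
    are carried along.  Deterministic ascending order."""
    bad = ~(map1["mapped"] & map2["mapped"])
    return np.nonzero(bad)[0]


# ---------------------------------------------------------------------------
# Depth clusters on a pseudohaplotype
# ---------------------------------------------------------------------------

def find_clusters(depth: np.ndarray, params: PipelineParams = DEFAULT_PARAMS,
                  read_len: int = 100, contig: str = "contig") -> list[ReadCluster]:
    """Maximal runs with depth ≥ cluster_cov_min; runs closer than
    cluster_merge_gap merge first, then clusters whose mean depth exceeds
    cluster_cov_max are discarded."""
    ok = depth >= params.cluster_cov_min
    if not ok.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    runs = list(zip(edges[::2], edges[1::2]))
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < params.cluster_merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        mean = float(depth[s:e].mean())
        if mean > params.cluster_cov_max:
            continue
        n_reads = max(1, int(round(depth[s:e].sum() / read_len)))
        out.append(ReadCluster(Interval(contig, int(s), int(e)), mean, n_reads))
    return out


def extend_cluster(cluster: ReadCluster, contig_length: int,
                   extension: int = 7000) -> Interval:
    """Cluster padded by `extension` bp each side, clipped at contig ends."""
    iv = cluster.hap_iv
    return Interval(iv.chrom, max(0, iv.start - extension),
                    min(contig_length, iv.end + extension))


# ---------------------------------------------------------------------------
# Breakpoint resolution
# ---------------------------------------------------------------------------

def resolve_insertion(extended_seq: str, scanner: ReferenceScanner,
                      params: PipelineParams = DEFAULT_PARAMS,
                      hap_source: tuple = ("NA", 0, None),
                      cluster_span: tuple | None = None) -> InsertionCall | None:
    """Resolve one extended cluster sequence against the reference.

    The colinear anchor scan yields candidate insertion events; events
    overlapping `cluster_span` (the unmapped-read cluster's coordinates
    within the extended sequence) are preferred — a 7 kb extension can span
    a neighbouring insertion — then the event with the largest summed anchor
    support wins (ties → leftmost reference coordinate).  Returns None when
    no anchor pair brackets a ≥50 bp query gap with a reference gap within
    the breakpoint slop.
    """
    if len(extended_seq) < 100:
        return None
    events = scanner.scan(extended_seq,
                          min_insertion_len=params.min_insertion_len,
                          max_target_gap=params.merge_breakpoint_slop)
    events = [e for e in events if e["left_anchor"] >= 1 and e["right_anchor"] >= 1]
    if not events:
        return None
    if cluster_span is not None:
        s0, s1 = cluster_span
        near = [e for e in events if e["q_end"] > s0 and e["q_start"] < s1]
        if near:
            events = near
    events.sort(key=lambda e: (-(e["left_anchor"] + e["right_anchor"]),
                               e["chrom"], e["breakpoint"]))
    ev = events[0]
    return InsertionCall(
        id="cand",
        ref_breakpoint=Interval(ev["chrom"], ev["breakpoint"], ev["breakpoint"]),
        seq=ev["seq"],
        hap_source=hap_source,
        left_anchor_len=ev["left_anchor"],
        right_anchor_len=ev["right_anchor"],
    )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_candidates(calls: list[InsertionCall], reference_index: KmerIndex,
                      segdup_bed: list[Interval], gap_bed: list[Interval],
                      masker, params: PipelineParams = DEFAULT_PARAMS,
                      ) -> list[InsertionCall]:
    """Drop calls explained by the reference (identity ≥ ref_match_identity
    at full query coverage), calls whose breakpoint falls in an assembly gap
    or segmental duplication, and calls with < min_unique_bases unmasked
    bases.  `masker` maps a sequence to its unique-base count."""
    excluded = segdup_bed + gap_bed
    out = []
    for call in calls:
        bp = call.ref_breakpoint
        if any(iv.chrom == bp.chrom and iv.contains(bp.start) for iv in excluded):
            continue
        if _kmer_match_fraction(call.seq, reference_index) >= 0.15:
            # only sequences with substantial exact k-mer sharing can reach a
            # ≥95%-identity full-coverage reference match
            hits = local_align(call.seq, reference_index, min_score=30,
                               max_windows=8)
            if any(h.identity >= params.ref_match_identity
                   and h.query_coverage >= params.ref_match_coverage - 1e-9
                   for h in hits):
                continue
        call.unique_bases = masker(call.seq)
        if call.unique_bases < params.min_unique_bases:
            continue
        out.append(call)
    return out


def _kmer_match_fraction(seq: str, index: KmerIndex) -> float:
    """Fraction of the sequence's k-mers with an exact hit in the index."""
    from .kmer_align import encode_seq, kmer_codes
    codes, valid = kmer_codes(encode_seq(seq), index.k)
    codes = codes[valid]
    if len(codes) == 0:
        return 0.0
    lo, hi = index.lookup(codes)
    return float((hi > lo).mean())


# ---------------------------------------------------------------------------
# Cross-sample merge
# ---------------------------------------------------------------------------

def _pair_identity(a: str, b: str) -> float:
    """Global (NW) identity estimate from the edit distance."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def merge_call_set(per_sample_calls: dict, params: PipelineParams = DEFAULT_PARAMS,
                   ) -> tuple[list[InsertionCall], dict]:
    """Collapse calls across samples into a non-redundant NUI set.

    Calls merge when their breakpoints lie within merge_breakpoint_slop and
    their sequences match at ≥ merge_identity with mutual coverage ≥ 0.95
    (global-alignment identity; the length ratio bounds mutual coverage).
    The longest sequence represents the merged NUI.  Returns (nuis,
    occurrence) with occurrence[nui_id] = set of (sample, haplotype).
    """
    flat = []
    for sample in sorted(per_sample_calls):
        for call in per_sample_calls[sample]:
            flat.append((call.ref_breakpoint.chrom, call.ref_breakpoint.start,
                         -len(call.seq), call.seq, sample, call))
    flat.sort(key=lambda x: (x[0], x[1], x[2], x[3], x[4]))
    clusters: list[list] = []
    for row in flat:
        chrom, bp, _nl, seq, sample, call = row
        placed = False
        for cl in clusters:
            rep = cl[0][5]
            if (rep.ref_breakpoint.chrom == chrom
                    and abs(rep.ref_breakpoint.start - bp) <= params.merge_breakpoint_slop
                    and min(len(seq), len(rep.seq)) / max(len(seq), len(rep.seq)) >= 0.95
                    and _pair_identity(seq, rep.seq) >= params.merge_identity):
                cl.append(row)
                placed = True
                break
        if not placed:
            clusters.append([row])
    nuis: list[InsertionCall] = []
    occurrence: dict[str, set] = {}
    clusters.sort(key=lambda cl: (cl[0][0], cl[0][1]))
    for i, cl in enumerate(clusters, 1):
        rep = max((r[5] for r in cl), key=lambda c: (len(c.seq), c.seq))
        nui = InsertionCall(
            id=f"NUI_{i}", ref_breakpoint=rep.ref_breakpoint, seq=rep.seq,
            hap_source=rep.hap_source, left_anchor_len=rep.left_anchor_len,
            right_anchor_len=rep.right_anchor_len, unique_bases=rep.unique_bases)
        nui.sample_occurrence = {r[4] for r in cl}
        occurrence[nui.id] = {(r[4], r[5].hap_source[1]) for r in cl}
        nuis.append(nui)
    return nuis, occurrence


# ---------------------------------------------------------------------------
# Per-sample discovery pipeline
# ---------------------------------------------------------------------------

def discover_sample(sample: str, reads, reference_index: KmerIndex,
                    scanner: ReferenceScanner,
                    haplotypes: tuple,
                    params: PipelineParams = DEFAULT_PARAMS) -> list[InsertionCall]:
    """Run the alignment branch for one sample.

    `reads` is a ReadSet; `haplotypes` the two pseudohaplotype sequence
    lists.  Returns breakpoint-resolved candidate calls (unfiltered).
    """
    read_len = reads.r1.shape[1]
    m1 = map_reads_batch(reads.r1, reference_index, params.map_accept_fraction)
    m2 = map_reads_batch(reads.r2, reference_index, params.map_accept_fraction)
    sel = unmapped_reads(m1, m2)
    if len(sel) == 0:
        return []
    pool = np.concatenate([reads.r1[sel], reads.r2[sel]])
    calls: list[InsertionCall] = []
    for hap_i, hapseqs in enumerate(haplotypes):
        hap_index = KmerIndex(hapseqs, k=reference_index.k)
        placed = map_reads_batch(pool, hap_index, params.map_accept_fraction)
        depth = np.zeros(len(hap_index.cat) + read_len, np.int32)
        pos = placed["cat_pos"][placed["mapped"]]
        np.add.at(depth, pos, 1)
        np.add.at(depth, pos + read_len, -1)
        depth = np.cumsum(depth)
        for ci, contig in enumerate(hapseqs):
            lo, hi = hap_index.seq_bounds(ci)
            clusters = find_clusters(depth[lo:hi], params, read_len, contig.name)
            for cluster in clusters:
                ext = extend_cluster(cluster, contig.length, params.cluster_extension)
                call = resolve_insertion(
                    contig.seq[ext.start:ext.end], scanner, params,
                    hap_source=(sample, hap_i, ext),
                    cluster_span=(cluster.hap_iv.start - ext.start,
                                  cluster.hap_iv.end - ext.start))
                if call is not None:
                    calls.append(call)
    return calls
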