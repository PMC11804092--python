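"""Contamination screening, set intersection and external comparison.

Lineage-based screening assigns each insertion contig the taxonomy of its
best database hit and flags anything not associated with Chordata (microbial,
plant, or non-chordate metazoan lineages); contigs with no hit are novel and
kept.  The two discovery branches are intersected by best bidirectional hits
(BBH), and call sets are compared one-directionally against published
non-reference sequence collections.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import DEFAULT_PARAMS, GenomeSequence, Interval, PipelineParams
from .kmer_align import AlignmentHit, KmerIndex, local_align

_CONTAMINANT_MARKERS = ("archaea", "bacteria", "viruses", "viridiplantae")


@dataclass(frozen=True)
class LineageRecord:
    db_seq_id: str
    lineage: tuple      # ordered taxonomy path, e.g. ("Eukaryota", ..., "Chordata", ...)

    def __post_init__(self):
        if not self.lineage:
            raise ValueError("empty lineage path")


def read_lineage_table(path) -> dict[str, LineageRecord]:
    """2-column TSV: seq_id <tab> semicolon-separated taxonomy path."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sid, path_str = line.split("\t")[:2]
            out[sid] = LineageRecord(sid, tuple(p.strip() for p in path_str.split(";") if p.strip()))
    return out


def classify_lineage(lineage: tuple) -> str:
    """clean | contaminant under the Chordata rule: a hit is clean only when
    its lineage contains Chordata."""
    lowered = [p.lower() for p in lineage]
    if "chordata" in lowered:
        return "clean"
    return "contaminant"


def lineage_screen(contigs: list[GenomeSequence], db_seqs: list[GenomeSequence],
                   db_lineages: dict, params: PipelineParams = DEFAULT_PARAMS,
                   ) -> dict[str, dict]:
    """Per-contig screening result {status: clean|contaminant,
    call: novel|<lineage string>}.

    The best database hit with identity ≥ lineage_min_identity and query
    coverage ≥ lineage_min_coverage assigns its lineage; contigs without a
    qualifying hit are novel (and clean).
    """
    index = KmerIndex(db_seqs, k=11) if db_seqs else None
    out = {}
    for contig in contigs:
        assigned = None
        if index is not None and contig.length >= index.k:
            for h in local_align(contig.seq, index, min_score=20):
                if (h.identity >= params.lineage_min_identity
                        and h.query_coverage >= params.lineage_min_coverage):
                    assigned = h.target_iv.chrom
                    break       # hits are score-sorted: first qualifying = best
        if assigned is None:
            out[contig.name] = {"status": "clean", "call": "novel"}
        else:
            rec = db_lineages.get(assigned)
            if rec is None:
                raise KeyError(f"database sequence {assigned!r} has no lineage")
            out[contig.name] = {"status": classify_lineage(rec.lineage),
                                "call": ";".join(rec.lineage)}
    return out


# ---------------------------------------------------------------------------
# Best bidirectional hits
# ---------------------------------------------------------------------------

def _best_qualifying(queries: list[GenomeSequence], targets: list[GenomeSequence],
                     identity: float, coverage: float) -> dict[str, str]:
    """For each query, the id of its best qualifying hit in `targets`
    (by score; ties → longer alignment, then lexicographic target id)."""
    index = KmerIndex(targets, k=11)
    best: dict[str, str] = {}
    for q in queries:
        if q.length < index.k:
            continue
        ranked = []
        for h in local_align(q.seq, index, min_score=20):
            if h.identity >= identity and h.query_coverage >= coverage:
                ranked.append((-h.score, -(h.columns), h.target_iv.chrom))
        if ranked:
            ranked.sort()
            best[q.name] = ranked[0][2]
    return best


def best_bidirectional_hits(set_a: list[GenomeSequence], set_b: list[GenomeSequence],
                            params: PipelineParams = DEFAULT_PARAMS,
                            ) -> tuple[list[tuple], list[str]]:
    """Reciprocal best hits between two sequence sets at bbh_identity /
    bbh_coverage.  Returns (pairs, paired_a_ids): (a, b) is kept iff b is a's
    best qualifying hit and a is b's."""
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    fwd = _best_qualifying(set_a, set_b, params.bbh_identity, params.bbh_coverage)
    rev = _best_qualifying(set_b, set_a, params.bbh_identity, params.bbh_coverage)
    pairs = [(a, b) for a, b in sorted(fwd.items()) if rev.get(b) == a]
    return pairs, [a for a, _b in pairs]


# ---------------------------------------------------------------------------
# Region overlap and external comparison
# ---------------------------------------------------------------------------

def region_overlap(calls, regions: list[Interval]) -> tuple[list, dict]:
    """Calls whose breakpoint position lies in a region ([start, end)
    half-open).  Returns (flagged calls, per-region counts)."""
    flagged = []
    counts = {(r.chrom, r.start, r.end): 0 for r in regions}
    for call in calls:
        bp = call.ref_breakpoint
        for r in regions:
            if r.chrom == bp.chrom and r.start <= bp.start < r.end:
                flagged.append(call)
                counts[(r.chrom, r.start, r.end)] += 1
                break
    return flagged, counts


def compare_external(calls, external: list[GenomeSequence],
                     params: PipelineParams = DEFAULT_PARAMS) -> tuple[list, int]:
    """One-directional comparison: a call is shared when any hit against the
    external set reaches species_identity / species_coverage.  Returns
    (shared calls, shared bp)."""
    if not external:
        return [], 0
    index = KmerIndex(external, k=11)
    shared = []
    for call in calls:
        for h in local_align(call.seq, index, min_score=20):
            if (h.identity >= params.species_identity
                    and h.query_coverage >= params.species_coverage):
                shared.append(call)
                break
    return shared, sum(len(c.seq) for c in shared)
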