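"""Low-complexity and repeat-library masking of insertion sequences.

Implements symmetric DUST low-complexity masking, alignment-based repeat
annotation against a consensus library with TE classification, the
≥50-unique-base retention criterion, major-TE assignment, breakpoint-flank TE
analysis, and call-set repeat summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import DEFAULT_PARAMS, GenomeSequence, Interval, PipelineParams
from .kmer_align import KmerIndex, local_align

TE_LABELS = ("LINE", "SINE", "LTR", "DNA")
LOW_COMPLEXITY = "LOW_COMPLEXITY"
_TE_TIE_ORDER = {c: i for i, c in enumerate(TE_LABELS)}


# ---------------------------------------------------------------------------
# SDUST
# ---------------------------------------------------------------------------

def sdust(seq: str, window: int = 64, threshold: int = 20) -> list[tuple[int, int]]:
    """Symmetric DUST low-complexity intervals.

    Every substring of length ≤ `window` is scored
    S = Σ_t c_t(c_t−1)/2 / (w−2), where c_t are its triplet counts and w its
    base length; substrings with S > threshold/10 are reported as the merged
    union of their intervals.  Runs in O(n·window) by extending each start
    with incremental triplet counts.
    """
    n = len(seq)
    if n < 3:
        return []
    tri = _triplet_codes(seq)
    return _sdust_scan(tri, n, window, threshold / 10.0)


def _triplet_codes(seq: str) -> list[int]:
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    b = [code.get(c, -1) for c in seq]
    out = []
    for i in range(len(seq) - 2):
        if b[i] < 0 or b[i + 1] < 0 or b[i + 2] < 0:
            out.append(-1)
        else:
            out.append(b[i] * 16 + b[i + 1] * 4 + b[i + 2])
    return out


def _sdust_scan(tri: list[int], n: int, window: int, cut: float) -> list[tuple[int, int]]:
    raw: list[tuple[int, int]] = []
    for i in range(len(tri)):
        counts = [0] * 64
        num = 0
        jmax = min(len(tri), i + window - 2)
        for j in range(i, jmax):
            code = tri[j]
            if code < 0:
                break                      # N interrupts a window
            num += counts[code]
            counts[code] += 1
            w = (j + 3) - i                # substring base length
            if num / (w - 2) > cut:
                raw.append((i, j + 3))
    if not raw:
        return []
    raw.sort()
    merged = [list(raw[0])]
    for s, e in raw[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# Repeat annotation
# ---------------------------------------------------------------------------

@dataclass
class RepeatAnnotation:
    """Per-sequence masked intervals with TE class labels."""

    target_id: str
    length: int
    intervals: list = field(default_factory=list)     # (Interval, label)
    class_bp: dict = field(default_factory=dict)      # label -> bases
    class_score: dict = field(default_factory=dict)   # label -> summed hit score
    unique_bp: int = 0

    @property
    def masked_bp(self) -> int:
        return self.length - self.unique_bp


def annotate_repeats(seq: str, repeat_library, params: PipelineParams = DEFAULT_PARAMS,
                     target_id: str = "seq", seed_k: int = 11) -> RepeatAnnotation:
    """Mask `seq` with the consensus library plus SDUST.

    Each consensus is locally aligned on both strands; hits with identity ≥
    `repeat_hit_identity` and target length ≥ `repeat_hit_minlen` claim bases
    best-score-first.  SDUST intervals are appended as LOW_COMPLEXITY on
    still-unclaimed bases; `unique_bp` counts bases claimed by neither.
    """
    n = len(seq)
    ann = RepeatAnnotation(target_id, n)
    labels = [None] * n
    hits = []
    if repeat_library and n >= seed_k:
        index = KmerIndex([GenomeSequence("t", seq)], k=seed_k)
        for cons in repeat_library:
            for h in local_align(cons.seq, index, min_score=10):
                tlen = len(h.target_iv)
                if h.identity >= params.repeat_hit_identity and tlen >= params.repeat_hit_minlen:
                    hits.append((h.score, cons.te_class, h.target_iv.start, h.target_iv.end))
    hits.sort(key=lambda x: (-x[0], x[2], x[1]))
    for score, cls, s, e in hits:
        claimed = 0
        for p in range(s, min(e, n)):
            if labels[p] is None:
                labels[p] = cls
                claimed += 1
        if claimed:
            ann.class_score[cls] = ann.class_score.get(cls, 0) + score
    for s, e in sdust(seq, params.dust_window, params.dust_threshold):
        for p in range(s, e):
            if labels[p] is None:
                labels[p] = LOW_COMPLEXITY
    # maximal runs of a single label become the interval list
    p = 0
    while p < n:
        if labels[p] is None:
            p += 1
            continue
        q = p
        while q < n and labels[q] == labels[p]:
            q += 1
        ann.intervals.append((Interval(target_id, p, q), labels[p]))
        ann.class_bp[labels[p]] = ann.class_bp.get(labels[p], 0) + (q - p)
        p = q
    ann.unique_bp = n - sum(ann.class_bp.values())
    return ann


def unique_bases(seq: str, annotation: RepeatAnnotation) -> int:
    if annotation.length != len(seq):
        raise ValueError("annotation does not match sequence length")
    return annotation.unique_bp


def passes_unique_filter(seq: str, annotation: RepeatAnnotation,
                         params: PipelineParams = DEFAULT_PARAMS) -> bool:
    return unique_bases(seq, annotation) >= params.min_unique_bases


def major_te(annotation: RepeatAnnotation) -> str:
    """Interspersed class with the largest base share; NONE when no
    interspersed repeat was detected.  Ties break by summed hit score, then
    the fixed order LINE > SINE > LTR > DNA."""
    cand = [(c, bp) for c, bp in annotation.class_bp.items() if c in TE_LABELS and bp > 0]
    if not cand:
        return "NONE"
    cand.sort(key=lambda x: (-x[1],
                             -annotation.class_score.get(x[0], 0),
                             _TE_TIE_ORDER[x[0]]))
    return cand[0][0]


# ---------------------------------------------------------------------------
# Flank / breakpoint-crossing analysis
# ---------------------------------------------------------------------------

def flank_te_analysis(insertion_seq: str, breakpoint: Interval,
                      reference: dict, repeat_library,
                      params: PipelineParams = DEFAULT_PARAMS) -> dict:
    """TE context of an insertion's two junctions.

    The insertion is extended by `te_flank` reference bases on each side (the
    haplotype context of the spliced allele) and re-masked.  ``flanked_X``:
    a TE interval overlaps the X-side flank.  ``crossing_X``: one TE interval
    covers ≥1 base on both sides of the X junction.
    """
    chrom = reference[breakpoint.chrom]
    seq = chrom.seq if hasattr(chrom, "seq") else chrom
    bp = breakpoint.start
    left = seq[max(0, bp - params.te_flank):bp]
    right = seq[bp:bp + params.te_flank]
    ext = left + insertion_seq + right
    ann = annotate_repeats(ext, repeat_library, params, target_id="ext")
    jl = len(left)
    jr = len(left) + len(insertion_seq)
    flags = {"flanked_left": False, "flanked_right": False,
             "crossing_left": False, "crossing_right": False}
    for iv, label in ann.intervals:
        if label not in TE_LABELS:
            continue
        if iv.start < jl:
            flags["flanked_left"] = True
        if iv.end > jr:
            flags["flanked_right"] = True
        if iv.start < jl < iv.end:
            flags["crossing_left"] = True
        if iv.start < jr < iv.end:
            flags["crossing_right"] = True
    return flags


# ---------------------------------------------------------------------------
# Call-set summary
# ---------------------------------------------------------------------------

SIZE_BINS = (("<200", 0, 200), ("200-1000", 200, 1001), (">1000", 1001, None))


def repeat_summary(annotations: list[RepeatAnnotation]) -> dict:
    """Per-class base fractions over the call set and per-size-bin major-TE
    tallies (bins <200, 200–1000, >1000 bp)."""
    total_bp = sum(a.length for a in annotations)
    class_bp: dict[str, int] = {}
    for a in annotations:
        for c, bp in a.class_bp.items():
            class_bp[c] = class_bp.get(c, 0) + bp
    fractions = {c: (bp / total_bp if total_bp else 0.0) for c, bp in class_bp.items()}
    tallies = {name: {} for name, _, _ in SIZE_BINS}
    for a in annotations:
        for name, lo, hi in SIZE_BINS:
            if a.length >= lo and (hi is None or a.length < hi):
                mt = major_te(a)
                tallies[name][mt] = tallies[name].get(mt, 0) + 1
                break
    masked_fraction = sum(class_bp.values()) / total_bp if total_bp else 0.0
    interspersed_fraction = (sum(bp for c, bp in class_bp.items() if c in TE_LABELS)
                             / total_bp if total_bp else 0.0)
    return {"n": len(annotations), "total_bp": total_bp,
            "class_fractions": fractions, "masked_fraction": masked_fraction,
            "interspersed_fraction": interspersed_fraction,
            "size_bin_major_te": tallies}


def mask_lowercase(seq: str, annotation: RepeatAnnotation) -> str:
    """Masked bases in lowercase (for masked-FASTA output)."""
    out = list(seq)
    for iv, _label in annotation.intervals:
        for p in range(iv.start, iv.end):
            out[p] = out[p].lower()
    return "".join(out)
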