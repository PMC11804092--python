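"""Shared alignment engine.

k-mer indexed seeding, windowed Smith–Waterman with affine gaps under a fixed
scoring scheme (match +1, mismatch −4, gap open −6, gap extend −1), batch
gapless read mapping, colinear anchor scanning for insertion breakpoints, and
MinHash sketching with the Mash distance.

The scored aligner is the arbiter for every identity/coverage threshold in
the pipeline; its identities agree with a full-DP oracle because the window
DP is exact within the seeded window and windows are padded beyond seed
extents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenomeSequence, Interval

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 1, -4, -6, -1
_NEG = -(10 ** 7)

# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def encode_seq(seq: str) -> np.ndarray:
    """2-bit codes A=0 C=1 G=2 T=3, anything else 4."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_seq(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    rev = arr[::-1]
    return np.where(rev == 4, np.uint8(4), (3 - rev).astype(np.uint8))


def kmer_codes(b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward-strand k-mer codes and a validity mask (no N in window)."""
    n = len(b) - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    c = np.zeros(n, np.uint64)
    bad = np.zeros(n, bool)
    for j in range(k):
        col = b[j:j + n]
        c = (c << np.uint64(2)) | (col & np.uint8(3)).astype(np.uint64)
        bad |= col == 4
    return c, ~bad


def rc_kmer_codes(b: np.ndarray, k: int) -> np.ndarray:
    """Codes of the reverse complement of each forward k-mer."""
    n = len(b) - k + 1
    c = np.zeros(n, np.uint64)
    for j in range(k):
        col = b[j:j + n]
        comp = (np.uint8(3) - (col & np.uint8(3))).astype(np.uint64)
        c |= comp << np.uint64(2 * j)
    return c


def canonical_codes(b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    fwd, valid = kmer_codes(b, k)
    if len(fwd) == 0:
        return fwd, valid
    rc = rc_kmer_codes(b, k)
    return np.minimum(fwd, rc), valid


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + np.uint64(0x9E3779B97F4A7C15))
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


# ---------------------------------------------------------------------------
# k-mer index over a sequence set
# ---------------------------------------------------------------------------

class KmerIndex:
    """Sorted-array index of forward-strand k-mers over a concatenated
    sequence set.  Sequences are separated by runs of N so no k-mer spans a
    boundary."""

    def __init__(self, seqs: list[GenomeSequence], k: int = 15):
        if not 11 <= k <= 31:
            raise ValueError("k must be in [11, 31]")
        self.k = k
        self.names = [s.name for s in seqs]
        self.lengths = np.array([s.length for s in seqs], dtype=np.int64)
        sep = "N" * k
        self.cat = encode_seq(sep.join(s.seq for s in seqs))
        starts = np.zeros(len(seqs), dtype=np.int64)
        pos = 0
        for i, s in enumerate(seqs):
            starts[i] = pos
            pos += s.length + k
        self.starts = starts
        codes, valid = kmer_codes(self.cat, k)
        positions = np.nonzero(valid)[0]
        codes = codes[valid]
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_pos = positions[order].astype(np.int64)

    @property
    def n_kmers(self) -> int:
        return len(self.sorted_codes)

    def lookup(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.sorted_codes, codes, side="left")
        hi = np.searchsorted(self.sorted_codes, codes, side="right")
        return lo, hi

    def locate(self, cat_pos) -> tuple[int, int]:
        """Map a concatenated-space position to (sequence index, local pos)."""
        i = int(np.searchsorted(self.starts, cat_pos, side="right") - 1)
        return i, int(cat_pos - self.starts[i])

    def seq_bounds(self, seq_idx: int) -> tuple[int, int]:
        s = int(self.starts[seq_idx])
        return s, s + int(self.lengths[seq_idx])

    def same_seq(self, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """True where [start, end) lies inside a single sequence."""
        i1 = np.searchsorted(self.starts, start, side="right") - 1
        within = (start >= 0) & (end <= self.starts[i1] + self.lengths[i1])
        return within & (end > start)


# ---------------------------------------------------------------------------
# Smith–Waterman (exact affine local DP, row-vectorized)
# ---------------------------------------------------------------------------

def _sw_matrices(q: np.ndarray, t: np.ndarray):
    m, n = len(q), len(t)
    if (m + 1) * (n + 1) > 40_000_000:
        raise ValueError(f"alignment too large: {m}x{n}")
    H = np.zeros((m + 1, n + 1), np.int32)
    G = np.zeros((m + 1, n + 1), np.int32)
    F = np.full((m + 1, n + 1), _NEG, np.int32)
    jj = np.arange(n + 1, dtype=np.int32)
    t_valid = t != 4
    for i in range(1, m + 1):
        qb = q[i - 1]
        sub = np.where((t == qb) & t_valid & (qb != 4), MATCH, MISMATCH).astype(np.int32)
        Fi = np.maximum(H[i - 1] + GAP_OPEN, F[i - 1] + GAP_EXT)
        Gi = np.maximum(Fi, 0)
        Gi[1:] = np.maximum(Gi[1:], H[i - 1, :-1] + sub)
        # horizontal affine gap via running max: a gap of length g costs
        # -(6 + (g-1)); predecessor never itself ends in a horizontal gap.
        M = np.maximum.accumulate(Gi + jj)
        Hi = Gi.copy()
        Hi[1:] = np.maximum(Hi[1:], M[:-1] - jj[1:] + (GAP_OPEN - GAP_EXT))
        F[i] = Fi
        G[i] = Gi
        H[i] = Hi
    return H, G, F


def _sw_traceback(q, t, H, G, F, i, j):
    """Walk back from (i, j); returns (qs, ts, matches, columns).

    ``at_g`` tracks whether the path arrived via a horizontal gap, in which
    case the current cell's value is G (best path not ending horizontally),
    not H.
    """
    matches = 0
    columns = 0
    at_g = False
    while True:
        cur = G[i, j] if at_g else H[i, j]
        if cur <= 0:
            break
        if not at_g and H[i, j] != G[i, j]:
            # horizontal gap: find the donor column
            h = int(H[i, j])
            jp = j - 1
            while jp >= 0 and G[i, jp] + GAP_OPEN + GAP_EXT * (j - jp - 1) != h:
                jp -= 1
            assert jp >= 0, "traceback inconsistency (horizontal)"
            columns += j - jp
            j = jp
            at_g = True
            continue
        g = int(G[i, j])
        qb, tb = q[i - 1], t[j - 1]
        sub = MATCH if (qb == tb and qb != 4 and tb != 4) else MISMATCH
        if H[i - 1, j - 1] + sub == g:
            if sub == MATCH:
                matches += 1
            columns += 1
            i -= 1
            j -= 1
            at_g = False
            continue
        # vertical gap
        assert g == F[i, j], "traceback inconsistency (vertical)"
        while F[i, j] != H[i - 1, j] + GAP_OPEN:
            assert F[i, j] == F[i - 1, j] + GAP_EXT
            i -= 1
            columns += 1
        i -= 1
        columns += 1
        at_g = False
    return i, j, matches, columns


@dataclass(frozen=True)
class AlignmentHit:
    """A scored local alignment of a query against a target sequence.

    Intervals are 0-based half-open; for strand '-' the query interval is on
    the forward query with orientation flagged.
    """

    query_iv: Interval
    target_iv: Interval
    strand: str
    identity: float
    query_coverage: float
    score: int
    matches: int = 0
    columns: int = 0


def _sw_align(qarr: np.ndarray, tarr: np.ndarray):
    """Best local alignment; returns (score, qs, qe, ts, te, matches, columns)
    or None when the best score is ≤ 0."""
    if len(qarr) == 0 or len(tarr) == 0:
        return None
    H, G, F = _sw_matrices(qarr, tarr)
    flat = int(np.argmax(H))
    i, j = divmod(flat, H.shape[1])
    score = int(H[i, j])
    if score <= 0:
        return None
    qs, ts, matches, columns = _sw_traceback(qarr, tarr, H, G, F, i, j)
    return score, qs, i, ts, j, matches, columns


def align_pair(query: str, target: str, min_score: int = 1) -> AlignmentHit | None:
    """Best local alignment of two sequences, both strands, exact DP.

    Intended for pairwise identity decisions (merge, BBH verification); for
    queries against large sequence sets use :func:`local_align`.
    """
    tarr = encode_seq(target)
    qlen = len(query)
    best = None
    for strand, q in (("+", query), ("-", revcomp(query))):
        qarr = encode_seq(q)
        if (len(qarr) + 1) * (len(tarr) + 1) > 40_000_000:
            hits = local_align(q, KmerIndex([GenomeSequence("t", target)], k=11),
                               min_score=min_score, both_strands=False)
            if hits:
                h = hits[0]
                if strand == "-":
                    h = AlignmentHit(
                        Interval(h.query_iv.chrom, qlen - h.query_iv.end,
                                 qlen - h.query_iv.start),
                        h.target_iv, "-", h.identity, h.query_coverage,
                        h.score, h.matches, h.columns)
                if best is None or h.score > best.score:
                    best = h
            continue
        res = _sw_align(qarr, tarr)
        if res is None:
            continue
        score, qs, qe, ts, te, matches, columns = res
        if strand == "-":
            qs, qe = qlen - qe, qlen - qs
        hit = AlignmentHit(Interval("query", qs, qe), Interval("t", ts, te),
                           strand, matches / columns if columns else 0.0,
                           (qe - qs) / qlen, score, matches, columns)
        if best is None or hit.score > best.score:
            best = hit
    if best is not None and best.score >= min_score:
        return best
    return None


# ---------------------------------------------------------------------------
# Seeded local alignment against an index
# ---------------------------------------------------------------------------

_SEED_CAP = 16          # max index occurrences used per query k-mer
_DIAG_GAP = 75          # diagonal split between seed clusters
_WINDOW_PAD = 64


def _seed_matches(qarr: np.ndarray, index: KmerIndex):
    codes, valid = kmer_codes(qarr, index.k)
    qpos = np.nonzero(valid)[0]
    codes = codes[valid]
    if len(codes) == 0:
        return (np.empty(0, np.int64),) * 2
    lo, hi = index.lookup(codes)
    cnt = np.minimum(hi - lo, _SEED_CAP)
    total = int(cnt.sum())
    if total == 0:
        return (np.empty(0, np.int64),) * 2
    rep_q = np.repeat(qpos, cnt)
    idx = np.repeat(lo, cnt) + (np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt))
    return rep_q.astype(np.int64), index.sorted_pos[idx]


def _cluster_windows(qp, tp, qlen, index: KmerIndex, max_windows: int):
    """Group seed matches into padded (q-range, t-range) DP windows."""
    diag = tp - qp
    order = np.lexsort((tp, diag))
    qp, tp, diag = qp[order], tp[order], diag[order]
    brk = np.nonzero((np.diff(diag) > _DIAG_GAP)
                     | (np.abs(np.diff(tp)) > qlen + 500))[0] + 1
    windows = []
    for seg in np.split(np.arange(len(qp)), brk):
        if len(seg) == 0:
            continue
        q0, q1 = int(qp[seg].min()), int(qp[seg].max()) + index.k
        t0, t1 = int(tp[seg].min()), int(tp[seg].max()) + index.k
        # pad so the DP can extend past the outermost seeds
        pad_l = min(q0, (q0 + _WINDOW_PAD))
        qlo = max(0, q0 - _WINDOW_PAD)
        qhi = min(qlen, q1 + _WINDOW_PAD)
        tlo = t0 - (q0 - qlo) - _WINDOW_PAD
        thi = t1 + (qhi - q1) + _WINDOW_PAD
        seq_i, _ = index.locate(min(max(t0, 0), len(index.cat) - 1))
        b0, b1 = index.seq_bounds(seq_i)
        tlo, thi = max(tlo, b0), min(thi, b1)
        if thi <= tlo:
            continue
        windows.append((len(seg), qlo, qhi, tlo, thi, seq_i))
    windows.sort(key=lambda w: (-w[0], w[3]))
    # drop windows nested inside an already-kept one
    kept = []
    for w in windows[:max_windows * 3]:
        if any(w[3] >= k[3] and w[4] <= k[4] and w[1] >= k[1] and w[2] <= k[2]
               for k in kept):
            continue
        kept.append(w)
        if len(kept) >= max_windows:
            break
    return kept


def local_align(query: str, index: KmerIndex, min_score: int = 30,
                max_windows: int = 32, both_strands: bool = True) -> list[AlignmentHit]:
    """Seed-and-extend local alignment of `query` against every sequence in
    `index`.  Hits are sorted by score descending, ties broken by
    (target name, target start)."""
    qlen = len(query)
    hits: list[AlignmentHit] = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        oriented = query if strand == "+" else revcomp(query)
        qarr = encode_seq(oriented)
        if len(qarr) < index.k:
            continue
        qp, tp = _seed_matches(qarr, index)
        if len(qp) == 0:
            continue
        for _, qlo, qhi, tlo, thi, seq_i in _cluster_windows(qp, tp, qlen, index, max_windows):
            res = _sw_align(qarr[qlo:qhi], index.cat[tlo:thi])
            if res is None:
                continue
            score, qs, qe, ts, te, matches, columns = res
            if score < min_score:
                continue
            qs, qe = qs + qlo, qe + qlo
            if strand == "-":
                qs, qe = qlen - qe, qlen - qs
            t_start_cat, t_end_cat = ts + tlo, te + tlo
            _, t_s = index.locate(t_start_cat)
            t_e = t_s + (t_end_cat - t_start_cat)
            hit = AlignmentHit(
                Interval("query", qs, qe),
                Interval(index.names[seq_i], t_s, t_e),
                strand, matches / columns if columns else 0.0,
                (qe - qs) / qlen, score, matches, columns)
            hits.append(hit)
    # dedupe identical target intervals (same alignment found twice)
    seen = {}
    for h in hits:
        key = (h.target_iv.chrom, h.target_iv.start, h.target_iv.end, h.strand)
        if key not in seen or h.score > seen[key].score:
            seen[key] = h
    out = sorted(seen.values(),
                 key=lambda h: (-h.score, h.target_iv.chrom, h.target_iv.start))
    return out


def hits_to_table(hits: list[AlignmentHit], query_name: str = "query") -> list[list]:
    """PAF-like rows: query, target, q-start, q-end, t-start, t-end, strand,
    identity, coverage, score."""
    return [[query_name, h.target_iv.chrom, h.query_iv.start, h.query_iv.end,
             h.target_iv.start, h.target_iv.end, h.strand,
             round(h.identity, 4), round(h.query_coverage, 4), h.score]
            for h in hits]


# ---------------------------------------------------------------------------
# Batch gapless read mapping
# ---------------------------------------------------------------------------

def map_reads_batch(reads: np.ndarray, index: KmerIndex,
                    accept_fraction: float = 0.60,
                    n_offsets: int = 3, chunk: int = 200_000) -> dict:
    """Map equal-length reads (rows of a uint8 code matrix) to the index.

    Placements are gapless (the read-level error model is substitutions), so
    a read's score is L − 5·mismatches.  A read is mapped when its best score
    reaches ``accept_fraction`` of the maximum possible score L; ties are
    broken toward the lower target position.  Returns arrays: ``mapped``,
    ``cat_pos`` (−1 when unmapped), ``strand`` (+1/−1), ``score``.
    """
    n, L = reads.shape
    k = index.k
    if L < k:
        raise ValueError("reads shorter than index k")
    offsets = sorted({0, (L - k) // 2, L - k})[:max(1, n_offsets)]
    out_pos = np.full(n, -1, np.int64)
    out_strand = np.zeros(n, np.int8)
    out_score = np.full(n, _NEG, np.int32)
    min_score = int(np.ceil(accept_fraction * L))
    cat = index.cat
    for c0 in range(0, n, chunk):
        rows = reads[c0:min(c0 + chunk, n)]
        nr = len(rows)
        rc_rows = np.where(rows[:, ::-1] == 4, np.uint8(4),
                           (3 - rows[:, ::-1]).astype(np.uint8))
        cand_r, cand_p, cand_s = [], [], []
        for sgn, mat in ((1, rows), (-1, rc_rows)):
            for off in offsets:
                code = np.zeros(nr, np.uint64)
                bad = np.zeros(nr, bool)
                for j in range(k):
                    col = mat[:, off + j]
                    code = (code << np.uint64(2)) | (col & np.uint8(3)).astype(np.uint64)
                    bad |= col == 4
                lo, hi = index.lookup(np.where(bad, np.uint64(0xFFFFFFFFFFFFFFFF), code))
                cnt = np.where(bad, 0, np.minimum(hi - lo, 4))
                total = int(cnt.sum())
                if total == 0:
                    continue
                rep = np.repeat(np.arange(nr), cnt)
                idx = np.repeat(lo, cnt) + (np.arange(total)
                                            - np.repeat(np.cumsum(cnt) - cnt, cnt))
                cand_r.append(rep)
                cand_p.append(index.sorted_pos[idx] - off)
                cand_s.append(np.full(total, sgn, np.int8))
        if not cand_r:
            continue
        r = np.concatenate(cand_r)
        p = np.concatenate(cand_p)
        s = np.concatenate(cand_s)
        ok = (p >= 0) & (p + L <= len(cat)) & index.same_seq(p, p + L)
        r, p, s = r[ok], p[ok], s[ok]
        if len(r) == 0:
            continue
        # dedupe (read, strand, pos)
        order = np.lexsort((p, s, r))
        r, p, s = r[order], p[order], s[order]
        keep = np.ones(len(r), bool)
        keep[1:] = (np.diff(r) != 0) | (np.diff(s) != 0) | (np.diff(p) != 0)
        r, p, s = r[keep], p[keep], s[keep]
        # score candidates in sub-chunks
        score = np.empty(len(r), np.int32)
        colidx = np.arange(L)
        for b0 in range(0, len(r), 100_000):
            b1 = min(b0 + 100_000, len(r))
            tb = cat[p[b0:b1, None] + colidx]
            rb = np.where(s[b0:b1, None] == 1, rows[r[b0:b1]], rc_rows[r[b0:b1]])
            match = (tb == rb) & (tb != 4) & (rb != 4)
            mm = L - match.sum(1)
            score[b0:b1] = L - 5 * mm
        # best per read: highest score, then lowest position, then + strand
        order = np.lexsort((-s, p, -score, r))
        r, p, s, score = r[order], p[order], s[order], score[order]
        first = np.ones(len(r), bool)
        first[1:] = np.diff(r) != 0
        r, p, s, score = r[first], p[first], s[first], score[first]
        acc = score >= min_score
        gi = r[acc] + c0
        out_pos[gi] = p[acc]
        out_strand[gi] = s[acc]
        out_score[gi] = score[acc]
    return {"mapped": out_pos >= 0, "cat_pos": out_pos,
            "strand": out_strand, "score": out_score}


def map_read_pair(r1: str, r2: str, index: KmerIndex,
                  accept_fraction: float = 0.60) -> dict:
    """Map a read pair; each read gets its best placement or an unmapped flag.

    Returns per-read dicts (mapped, target, pos, strand, score) plus the pair
    insert size when both ends map to the same target.
    """
    out = {}
    for key, read in (("r1", r1), ("r2", r2)):
        res = map_reads_batch(encode_seq(read)[None, :], index,
                              accept_fraction=accept_fraction)
        if res["mapped"][0]:
            seq_i, pos = index.locate(int(res["cat_pos"][0]))
            out[key] = {"mapped": True, "target": index.names[seq_i], "pos": pos,
                        "strand": "+" if res["strand"][0] > 0 else "-",
                        "score": int(res["score"][0])}
        else:
            out[key] = {"mapped": False, "target": None, "pos": -1,
                        "strand": ".", "score": int(res["score"][0])}
    a, b = out["r1"], out["r2"]
    if a["mapped"] and b["mapped"] and a["target"] == b["target"]:
        lo = min(a["pos"], b["pos"])
        hi = max(a["pos"] + len(r1), b["pos"] + len(r2))
        out["insert"] = hi - lo
        out["proper"] = a["strand"] != b["strand"]
    else:
        out["insert"] = None
        out["proper"] = False
    return out


# ---------------------------------------------------------------------------
# Colinear anchor scan (whole-contig insertion detection)
# ---------------------------------------------------------------------------

def _lis_indices(values: np.ndarray) -> np.ndarray:
    """Longest strictly increasing subsequence (patience algorithm)."""
    import bisect
    tails: list[int] = []          # values
    tails_idx: list[int] = []
    prev = np.full(len(values), -1, np.int64)
    for i, v in enumerate(values):
        j = bisect.bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        out.append(i)
        i = prev[i]
    return np.array(out[::-1], dtype=np.int64)


class ReferenceScanner:
    """Anchors a query contig to a reference by k-mers unique in both, then
    reports gaps where the query advances without the reference — candidate
    insertions with exact, left-aligned breakpoints."""

    def __init__(self, reference: list[GenomeSequence], k: int = 21):
        self.index = KmerIndex(reference, k=k)
        # reference-unique k-mers
        codes = self.index.sorted_codes
        uniq = np.ones(len(codes), bool)
        if len(codes) > 1:
            same = codes[1:] == codes[:-1]
            uniq[1:] &= ~same
            uniq[:-1] &= ~same
        self.uniq_mask = uniq
        self.ref_seqs = {s.name: encode_seq(s.seq) for s in reference}

    def _anchors(self, qarr: np.ndarray):
        k = self.index.k
        codes, valid = kmer_codes(qarr, k)
        qpos = np.nonzero(valid)[0]
        codes = codes[valid]
        if len(codes) == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        # query-unique too
        srt = np.sort(codes)
        dup = srt[1:][srt[1:] == srt[:-1]]
        if len(dup):
            keep = ~np.isin(codes, dup)
            codes, qpos = codes[keep], qpos[keep]
        lo, hi = self.index.lookup(codes)
        one = (hi - lo == 1)
        one &= self.uniq_mask[np.minimum(lo, len(self.uniq_mask) - 1)]
        qpos, lo = qpos[one], lo[one]
        return qpos.astype(np.int64), self.index.sorted_pos[lo]

    def scan(self, contig: str, min_insertion_len: int = 50,
             max_target_gap: int = 10, max_anchors: int = 150_000,
             with_span: bool = False):
        """Return insertion events for one contig.

        Each event: dict(chrom, breakpoint, seq, q_start, q_end,
        left_anchor, right_anchor, strand).  With ``with_span`` the return
        value is (events, spans) where spans maps each anchored chromosome to
        its (min, max) anchored reference coordinates.
        """
        events: list[dict] = []
        spans: dict[str, tuple] = {}
        best = None
        for strand in ("+", "-"):
            oriented = contig if strand == "+" else revcomp(contig)
            qarr = encode_seq(oriented)
            qp, tp = self._anchors(qarr)
            if best is None or len(qp) > best[3]:
                best = (strand, oriented, qarr, len(qp), qp, tp)
            if len(qp) > len(contig) // 4:
                break        # clearly the right orientation
        strand, oriented, qarr, n_anchor, qp, tp = best
        if n_anchor < 2:
            return (events, spans) if with_span else events
        order = np.argsort(qp, kind="stable")
        qp, tp = qp[order], tp[order]
        if len(qp) > max_anchors:
            stride = int(np.ceil(len(qp) / max_anchors))
            qp, tp = qp[::stride], tp[::stride]
        keep = _lis_indices(tp)
        qp, tp = qp[keep], tp[keep]
        k = self.index.k
        seq_idx = np.searchsorted(self.index.starts, tp, side="right") - 1
        for si in np.unique(seq_idx):
            sel = tp[seq_idx == si] - self.index.starts[si]
            spans[self.index.names[si]] = (int(sel.min()), int(sel.max()) + k)
        for a in range(len(qp) - 1):
            q1, t1 = int(qp[a]), int(tp[a])
            q2, t2 = int(qp[a + 1]), int(tp[a + 1])
            dq, dt = q2 - (q1 + k), t2 - (t1 + k)
            if dq - dt < min_insertion_len:
                continue
            seq_i1, _ = self.index.locate(t1)
            seq_i2, _ = self.index.locate(t2)
            if seq_i1 != seq_i2:
                continue
            chrom = self.index.names[seq_i1]
            ref = self.ref_seqs[chrom]
            base = int(self.index.starts[seq_i1])
            # exact extension inward from both anchors
            le_q, le_t = q1 + k, t1 + k - base
            while le_q < q2 and le_t < len(ref) and qarr[le_q] == ref[le_t] and qarr[le_q] != 4:
                le_q += 1
                le_t += 1
            rs_q, rs_t = q2, t2 - base
            while rs_q > le_q and rs_t > 0 and qarr[rs_q - 1] == ref[rs_t - 1] and qarr[rs_q - 1] != 4:
                rs_q -= 1
                rs_t -= 1
            if rs_t < le_t:               # microhomology overshoot
                shift = le_t - rs_t
                rs_q += shift
                rs_t += shift
            ins_len = rs_q - le_q
            target_gap = rs_t - le_t
            if ins_len < min_insertion_len or target_gap > max_target_gap:
                continue
            # left-align the breakpoint (tandem-context ambiguity)
            while le_t > 0 and qarr[rs_q - 1] == ref[le_t - 1] and qarr[rs_q - 1] != 4:
                le_q -= 1
                rs_q -= 1
                le_t -= 1
                rs_t -= 1
            seq = decode_seq(qarr[le_q:rs_q])
            q_start, q_end = le_q, rs_q
            if strand == "-":
                q_start, q_end = len(contig) - rs_q, len(contig) - le_q
            events.append({
                "chrom": chrom, "breakpoint": le_t, "seq": seq,
                "q_start": q_start, "q_end": q_end,
                "left_anchor": le_q, "right_anchor": len(oriented) - rs_q,
                "strand": strand, "target_gap": target_gap,
            })
        return (events, spans) if with_span else events


# ---------------------------------------------------------------------------
# MinHash / Mash
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MinHashSketch:
    k: int
    s: int
    hashes: tuple     # sorted ascending, ≤ s entries

    def __post_init__(self):
        if len(self.hashes) > self.s:
            raise ValueError("sketch larger than s")


def mash_sketch(seq: str, k: int = 21, s: int = 1000) -> MinHashSketch:
    b = encode_seq(seq)
    codes, valid = canonical_codes(b, k)
    codes = np.unique(codes[valid])
    h = np.unique(_splitmix64(codes))
    if len(h) > s:
        h = np.sort(np.partition(h, s)[:s])
    return MinHashSketch(k, s, tuple(int(x) for x in h))


def mash_distance(a: MinHashSketch, b: MinHashSketch) -> float:
    """d = −(1/k)·ln(2J/(1+J)) with J estimated from the s smallest hashes of
    the union; J = 0 is capped at distance 1.0."""
    if a.k != b.k or a.s != b.s:
        raise ValueError("sketches not comparable (k or s differ)")
    ha = np.array(a.hashes, np.uint64)
    hb = np.array(b.hashes, np.uint64)
    union = np.union1d(ha, hb)
    if len(union) == 0:
        return 0.0
    if len(union) > a.s:
        union = union[:a.s]
    shared = np.intersect1d(ha, hb, assume_unique=True)
    j = len(np.intersect1d(union, shared, assume_unique=True)) / len(union)
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    d = -np.log(2.0 * j / (1.0 + j)) / a.k
    return float(min(d, 1.0))
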