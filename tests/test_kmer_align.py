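import numpy as np
import pytest

from panins.io_formats import GenomeSequence
from panins.kmer_align import (KmerIndex, ReferenceScanner, align_pair,
                               canonical_codes, encode_seq, kmer_codes,
                               local_align, map_read_pair, map_reads_batch,
                               mash_distance, mash_sketch, revcomp)
from conftest import mutate_seq, random_seq


def sw_oracle_score_identity(q: str, t: str):
    """Full affine Smith–Waterman (match +1, mismatch −4, open −6, ext −1),
    written as the classic three-matrix cell recurrence with an explicit
    traceback — independent of the production row-vectorized DP."""
    m, n = len(q), len(t)
    NEG = -10 ** 6
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    move = [[None] * (n + 1) for _ in range(m + 1)]
    best = (0, 0, 0)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - 6, E[i][j - 1] - 1)
            F[i][j] = max(H[i - 1][j] - 6, F[i - 1][j] - 1)
            s = 1 if q[i - 1] == t[j - 1] else -4
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] == 0:
                move[i][j] = None
            elif H[i][j] == H[i - 1][j - 1] + s:
                move[i][j] = "d"
            elif H[i][j] == E[i][j]:
                move[i][j] = "e"
            else:
                move[i][j] = "f"
            if H[i][j] > best[0]:
                best = (H[i][j], i, j)
    score, i, j = best
    matches = columns = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        mv = move[i][j]
        if mv == "d":
            matches += q[i - 1] == t[j - 1]
            columns += 1
            i, j = i - 1, j - 1
        elif mv == "e":
            while E[i][j] != H[i][j - 1] - 6:
                j -= 1
                columns += 1
            j -= 1
            columns += 1
            if H[i][j] == 0:
                break
        elif mv == "f":
            while F[i][j] != H[i - 1][j] - 6:
                i -= 1
                columns += 1
            i -= 1
            columns += 1
            if H[i][j] == 0:
                break
        else:
            break
    return score, matches, columns


class TestIndex:
    def test_number_of_indexed_positions(self):
        idx = KmerIndex([GenomeSequence("s", "ACGTACGT")], k=11)
        assert idx.n_kmers == 0
        idx = KmerIndex([GenomeSequence("s", "ACGTACGTACGTACG")], k=11)
        assert idx.n_kmers == 5          # L - k + 1

    def test_canonical_key_shared_with_reverse_complement(self):
        b1 = encode_seq("ACGTACGTACGTA")
        b2 = encode_seq(revcomp("ACGTACGTACGTA"))
        c1, _ = canonical_codes(b1, 11)
        c2, _ = canonical_codes(b2, 11)
        assert set(c1.tolist()) == set(c2.tolist())

    def test_kmers_containing_n_are_skipped(self):
        # N at offset 1 invalidates every window that spans it
        codes, valid = kmer_codes(encode_seq("ANGTACGTACGTA"), 11)
        assert valid.tolist() == [False, False, True]


class TestLocalAlign:
    def test_exact_substring_has_perfect_identity_and_interval(self, rng):
        t = random_seq(rng, 4000)
        idx = KmerIndex([GenomeSequence("chr1", t)], k=15)
        h = local_align(t[700:1200], idx, min_score=50)[0]
        assert h.identity == 1.0
        assert h.query_coverage == 1.0
        assert (h.target_iv.start, h.target_iv.end) == (700, 1200)
        assert h.strand == "+"

    def test_reverse_complement_query_flips_strand_only(self, rng):
        t = random_seq(rng, 4000)
        idx = KmerIndex([GenomeSequence("chr1", t)], k=15)
        h = local_align(revcomp(t[700:1200]), idx, min_score=50)[0]
        assert h.strand == "-"
        assert (h.target_iv.start, h.target_iv.end) == (700, 1200)

    def test_single_substitution_identity(self, rng):
        """One mid-sequence substitution in a 100 bp query: the full-length
        local alignment (identity 99/100) outscores trimming at the
        mismatch."""
        t = random_seq(rng, 2000)
        q = list(t[500:600])
        q[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[50]]
        q = "".join(q)
        idx = KmerIndex([GenomeSequence("chr1", t)], k=15)
        h = local_align(q, idx, min_score=20)[0]
        o_score, o_m, o_c = sw_oracle_score_identity(q, t[450:650])
        assert h.score == o_score
        assert h.identity == pytest.approx(o_m / o_c)
        assert h.identity == pytest.approx(0.99)

    def test_identity_matches_full_dp_oracle_within_one_column(self, rng):
        for _ in range(12):
            a = random_seq(rng, rng.randint(60, 120))
            b = mutate_seq(rng, a, subs=rng.randint(0, 6),
                           indels=rng.randint(0, 3))
            h = align_pair(a, b)
            o_score, o_m, o_c = sw_oracle_score_identity(a, b)
            assert h.score == o_score
            assert abs(h.matches - o_m) <= 1
            assert abs(h.columns - o_c) <= 1

    def test_substitutions_never_increase_best_identity(self, rng):
        t = random_seq(rng, 3000)
        idx = KmerIndex([GenomeSequence("chr1", t)], k=11)
        q = t[1000:1300]
        prev = 1.0
        for n_subs in (1, 3, 6, 12):
            q = mutate_seq(rng, q, subs=2)
            hits = local_align(q, idx, min_score=20)
            ident = hits[0].identity if hits else 0.0
            assert ident <= prev + 1e-9
            prev = ident


class TestReadMapping:
    def test_reference_read_maps_at_true_locus(self, rng):
        t = random_seq(rng, 30_000)
        idx = KmerIndex([GenomeSequence("chr1", t)], k=21)
        res = map_read_pair(t[5000:5100], revcomp(t[5200:5300]), idx)
        assert res["r1"]["mapped"] and res["r1"]["pos"] == 5000
        assert res["r2"]["mapped"] and res["r2"]["pos"] == 5200
        assert res["r2"]["strand"] == "-"
        assert res["proper"] and res["insert"] == 300

    def test_novel_read_is_unmapped(self, rng):
        t = random_seq(rng, 30_000)
        idx = KmerIndex([GenomeSequence("chr1", t)], k=21)
        res = map_read_pair(random_seq(rng, 100), t[100:200], idx)
        assert not res["r1"]["mapped"]
        assert res["r2"]["mapped"]

    def test_batch_acceptance_threshold(self, rng):
        """A read more than ~8% diverged from its source fails the 0.6×max
        score rule; below that it maps."""
        t = random_seq(rng, 30_000)
        idx = KmerIndex([GenomeSequence("chr1", t)], k=21)
        good = mutate_seq(rng, t[1000:1100], subs=7)    # score 100-35=65 ≥ 60
        bad = mutate_seq(rng, t[2000:2100], subs=20)
        reads = np.vstack([encode_seq(good), encode_seq(bad)])
        res = map_reads_batch(reads, idx)
        assert res["mapped"][0]
        assert not res["mapped"][1]


class TestMash:
    def test_identical_sequences_have_distance_zero(self, rng):
        s = random_seq(rng, 20_000)
        assert mash_distance(mash_sketch(s), mash_sketch(s)) == 0.0

    def test_disjoint_kmer_sets_cap_at_one(self):
        a = mash_sketch("A" * 1000)
        b = mash_sketch("C" * 1000)
        assert mash_distance(a, b) == 1.0

    def test_symmetry(self, rng):
        a = mash_sketch(random_seq(rng, 30_000))
        b = mash_sketch(mutate_seq(rng, random_seq(rng, 30_000), subs=500))
        assert mash_distance(a, b) == mash_distance(b, a)

    def test_mismatched_parameters_error(self, rng):
        s = random_seq(rng, 5000)
        with pytest.raises(ValueError):
            mash_distance(mash_sketch(s, k=21), mash_sketch(s, k=15))

    def test_sketch_estimate_tracks_exact_jaccard(self, rng):
        """Two 50 kb sequences at 2% divergence: the sketch distance stays
        within ±0.005 of the distance computed from exact k-mer Jaccard."""
        a = random_seq(rng, 50_000)
        b = mutate_seq(rng, a, subs=1000)
        ca, va = canonical_codes(encode_seq(a), 21)
        cb, vb = canonical_codes(encode_seq(b), 21)
        sa, sb = set(ca[va].tolist()), set(cb[vb].tolist())
        j = len(sa & sb) / len(sa | sb)
        exact_d = -np.log(2 * j / (1 + j)) / 21
        est = mash_distance(mash_sketch(a), mash_sketch(b))
        assert abs(est - exact_d) <= 0.005


class TestReferenceScanner:
    def test_recovers_planted_insertions_with_exact_breakpoints(self, rng):
        ref = random_seq(rng, 100_000)
        ins = random_seq(rng, 400)
        contig = ref[:40_000] + ins + ref[40_000:]
        sc = ReferenceScanner([GenomeSequence("chr1", ref)], k=21)
        for query in (contig, revcomp(contig)):
            ev = sc.scan(query)
            assert len(ev) == 1
            assert ev[0]["chrom"] == "chr1"
            assert ev[0]["breakpoint"] in (39_998, 39_999, 40_000)
            assert ins in ev[0]["seq"] or ev[0]["seq"] in (ins, )
            assert len(ev[0]["seq"]) == 400

    def test_pure_reference_contig_yields_no_events(self, rng):
        ref = random_seq(rng, 60_000)
        sc = ReferenceScanner([GenomeSequence("chr1", ref)], k=21)
        assert sc.scan(ref[5000:55_000]) == []
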