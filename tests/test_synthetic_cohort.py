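import numpy as np
import pytest

from panins.kmer_align import ReferenceScanner, align_pair
from panins.synthetic_cohort import (CLASS_LENGTH_RANGE, DEFAULT_SIZE_MIX,
                                     TE_CLASSES, build_pseudohaplotypes,
                                     contig_n50, fragment_contigs,
                                     make_cohort, make_insertions,
                                     make_reference, make_repeat_library,
                                     mixture_median, simulate_reads,
                                     write_fastq_pair)


class TestRepeatLibrary:
    def test_counts_classes_and_length_ranges(self):
        lib = make_repeat_library(1, seed=7)
        assert [r.te_class for r in lib] == list(TE_CLASSES)
        for r in lib:
            lo, hi = CLASS_LENGTH_RANGE[r.te_class]
            assert lo <= len(r.seq) <= hi

    def test_same_seed_reproduces_sequences(self):
        assert make_repeat_library(2, seed=3) == make_repeat_library(2, seed=3)

    def test_consensi_are_mutually_dissimilar(self):
        """Best local alignment between any two consensi covers <80% of the
        shorter one with matches (all-pairs alignment check)."""
        lib = make_repeat_library(1, seed=7)
        for i in range(len(lib)):
            for j in range(i + 1, len(lib)):
                h = align_pair(lib[i].seq[:1500], lib[j].seq[:1500])
                sim = (h.matches / min(1500, len(lib[i].seq), len(lib[j].seq))
                       if h else 0.0)
                assert sim < 0.80


class TestReference:
    def test_zero_density_plants_nothing(self, repeat_library):
        _ref, truth = make_reference(1, 50_000, repeat_library, 0.0, seed=1)
        assert truth == []

    def test_masked_fraction_tracks_requested_density(self, small_reference):
        ref, truth = small_reference
        total = sum(s.length for s in ref)
        planted = sum(len(iv) for iv, _c, _n in truth)
        assert abs(planted / total - 0.3) <= 0.05

    def test_same_seed_reproduces_genome(self, repeat_library):
        a, _ = make_reference(1, 30_000, repeat_library, 0.2, seed=5)
        b, _ = make_reference(1, 30_000, repeat_library, 0.2, seed=5)
        assert a == b

    def test_excessive_density_rejected(self, repeat_library):
        with pytest.raises(ValueError):
            make_reference(1, 30_000, repeat_library, 0.9, seed=5)


class TestInsertions:
    def test_zero_insertions(self, small_reference, repeat_library):
        ref, _ = small_reference
        assert make_insertions(ref, repeat_library, 0, seed=1) == []

    def test_all_lengths_at_least_fifty(self, small_reference, repeat_library):
        ref, truth = small_reference
        ins = make_insertions(ref, repeat_library, 40, seed=2, repeat_truth=truth)
        assert all(len(i.seq) >= 50 for i in ins)

    def test_breakpoints_spaced_and_clean(self, small_reference, repeat_library):
        ref, truth = small_reference
        ins = make_insertions(ref, repeat_library, 40, seed=2, repeat_truth=truth)
        by_chrom = {}
        for i in ins:
            by_chrom.setdefault(i.ref_breakpoint.chrom, []).append(i.ref_breakpoint.start)
        for positions in by_chrom.values():
            positions.sort()
            assert all(b - a >= 1000 for a, b in zip(positions, positions[1:]))
        for i in ins:
            for iv, _c, _n in truth:
                if iv.chrom == i.ref_breakpoint.chrom:
                    assert not (iv.start - 100 <= i.ref_breakpoint.start < iv.end + 100)

    def test_truth_breakpoints_are_left_aligned(self, small_reference, repeat_library):
        ref, truth = small_reference
        seqs = {s.name: s.seq for s in ref}
        for i in make_insertions(ref, repeat_library, 40, seed=2, repeat_truth=truth):
            bp = i.ref_breakpoint.start
            if bp > 0:
                assert i.seq[-1] != seqs[i.ref_breakpoint.chrom][bp - 1]

    def test_median_length_tracks_mixture_median(self, small_reference, repeat_library):
        ref, truth = small_reference
        mix = (((50, 500), 0.6), ((500, 5000), 0.4))
        ins = make_insertions(ref, repeat_library, 150, size_mix=mix, seed=4,
                              repeat_truth=truth, min_spacing=1000)
        med = np.median([len(i.seq) for i in ins])
        analytic = mixture_median(mix)
        # log-uniform bins: allow half a decade of sampling spread
        assert analytic / 2 <= med <= analytic * 2

    def test_mixture_median_closed_form(self):
        # 60% of mass on [50,500): the median sits at 50*10^(0.5/0.6)
        assert mixture_median(DEFAULT_SIZE_MIX) == pytest.approx(
            50 * 10 ** (0.5 / 0.6))


class TestCohort:
    def test_degenerate_frequency_gives_homozygous_everyone(self, small_reference, repeat_library):
        ref, truth = small_reference
        ins = make_insertions(ref, repeat_library, 5, seed=2, repeat_truth=truth)
        ct = make_cohort(ins, freq_model=lambda rng, n, breeds: np.ones((n, len(breeds))),
                         seed=1)
        assert (ct.genotypes == 2).all()

    def test_realized_frequency_within_binomial_bounds(self, small_reference, repeat_library):
        """98-sample cohorts at target 0.5: the realized allele frequency
        stays within 3 binomial standard errors for nearly all replicates."""
        ref, truth = small_reference
        ins = make_insertions(ref, repeat_library, 20, seed=2, repeat_truth=truth)
        half = lambda rng, n, breeds: np.full((n, len(breeds)), 0.5)
        se3 = 3 * np.sqrt(0.5 * 0.5 / (2 * 98))
        ok = 0
        for seed in range(10):
            ct = make_cohort(ins, freq_model=half, seed=seed)
            f = ct.genotypes.sum(axis=0) / (2 * 98)
            ok += int((np.abs(f - 0.5) <= se3).mean() >= 0.95)
        assert ok >= 9

    def test_same_seed_reproduces_genotypes(self, small_reference, repeat_library):
        ref, truth = small_reference
        ins = make_insertions(ref, repeat_library, 5, seed=2, repeat_truth=truth)
        a = make_cohort(ins, seed=9)
        b = make_cohort(ins, seed=9)
        assert (a.genotypes == b.genotypes).all()
        assert (a.hap_choice == b.hap_choice).all()


class TestPseudohaplotypes:
    def test_no_insertions_reproduces_reference(self, small_reference):
        ref, _ = small_reference
        h1, h2 = build_pseudohaplotypes(ref, [], np.zeros(0, np.int8),
                                        np.zeros(0, np.int8))
        assert [s.seq for s in h1] == [s.seq for s in ref]
        assert [s.seq for s in h2] == [s.seq for s in ref]

    def test_homozygous_insertion_lengthens_both_haplotypes(self, small_reference, repeat_library):
        ref, truth = small_reference
        ins = make_insertions(ref, repeat_library, 1, seed=3, repeat_truth=truth)
        L = len(ins[0].seq)
        h1, h2 = build_pseudohaplotypes(ref, ins, np.array([2], np.int8),
                                        np.array([0], np.int8))
        chrom = ins[0].ref_breakpoint.chrom
        ref_len = {s.name: s.length for s in ref}[chrom]
        assert {s.name: s.length for s in h1}[chrom] == ref_len + L
        assert {s.name: s.length for s in h2}[chrom] == ref_len + L

    def test_heterozygote_lands_on_recorded_haplotype(self, small_reference, repeat_library):
        ref, truth = small_reference
        ins = make_insertions(ref, repeat_library, 1, seed=3, repeat_truth=truth)
        h1, h2 = build_pseudohaplotypes(ref, ins, np.array([1], np.int8),
                                        np.array([1], np.int8))
        chrom = ins[0].ref_breakpoint.chrom
        ref_len = {s.name: s.length for s in ref}[chrom]
        assert {s.name: s.length for s in h1}[chrom] == ref_len
        assert {s.name: s.length for s in h2}[chrom] == ref_len + len(ins[0].seq)

    def test_fragmentation_hits_requested_n50(self, small_reference):
        ref, _ = small_reference
        contigs = fragment_contigs(ref, n50_target=30_000, seed=4)
        assert abs(contig_n50(contigs) - 30_000) / 30_000 <= 0.2

    def test_truth_closure_scan_recovers_spliced_insertions(self, small_reference, repeat_library):
        """Splicing then scanning a haplotype against the reference recovers
        every insertion exactly (sequence and left-aligned breakpoint)."""
        ref, truth = small_reference
        ins = make_insertions(ref, repeat_library, 8, seed=5, repeat_truth=truth)
        h1, _ = build_pseudohaplotypes(ref, ins, np.full(8, 2, np.int8),
                                       np.zeros(8, np.int8))
        scanner = ReferenceScanner(ref, k=21)
        events = [e for s in h1 for e in scanner.scan(s.seq)]
        got = {(e["chrom"], e["breakpoint"], e["seq"]) for e in events}
        want = {(i.ref_breakpoint.chrom, i.ref_breakpoint.start, i.seq) for i in ins}
        assert got == want


class TestReads:
    def test_emitted_bases_track_requested_coverage(self, plain_chromosome):
        rs = simulate_reads([plain_chromosome, plain_chromosome], coverage=30,
                            seed=1)
        total = rs.n_pairs * 200
        expect = 30 * plain_chromosome.length
        assert abs(total - expect) / expect <= 0.1

    def test_error_free_reads_match_source_exactly(self, plain_chromosome):
        from panins.kmer_align import KmerIndex, map_reads_batch
        rs = simulate_reads([plain_chromosome, plain_chromosome], coverage=2,
                            err_rate=0.0, seed=2)
        idx = KmerIndex([plain_chromosome], k=21)
        res = map_reads_batch(rs.r1[:200], idx)
        assert res["mapped"].all()
        assert (res["score"][res["mapped"]] == rs.r1.shape[1]).all()

    def test_same_seed_gives_byte_identical_fastq(self, plain_chromosome, tmp_path):
        for run in ("a", "b"):
            rs = simulate_reads([plain_chromosome], coverage=1, seed=3)
            write_fastq_pair(rs, tmp_path / f"{run}1.fq", tmp_path / f"{run}2.fq")
        assert (tmp_path / "a1.fq").read_bytes() == (tmp_path / "b1.fq").read_bytes()
        assert (tmp_path / "a2.fq").read_bytes() == (tmp_path / "b2.fq").read_bytes()

    def test_invalid_parameters_rejected(self, plain_chromosome):
        with pytest.raises(ValueError):
            simulate_reads([plain_chromosome], coverage=0)
        with pytest.raises(ValueError):
            simulate_reads([plain_chromosome], coverage=10, read_len=100,
                           frag_mean=150)
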