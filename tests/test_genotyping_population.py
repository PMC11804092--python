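import numpy as np
import pytest

import dendropy

from panins.genotyping_population import (GenotypeCall, GenotypeMatrix,
                                          OccurrenceMatrix, build_matrix,
                                          build_nui_panel, genotype_nui,
                                          hierarchical_cluster, maf_filter,
                                          occurrence_matrix, pca,
                                          pileup_consensus)
from panins.io_formats import GenomeSequence, Interval
from panins.kmer_align import KmerIndex, encode_seq
from panins.nui_discovery import InsertionCall
from panins.synthetic_cohort import simulate_reads
from conftest import mutate_seq, random_seq


def _nui(seq, chrom, bp, nid):
    return InsertionCall(nid, Interval(chrom, bp, bp), seq, ("s", 0, None))


class TestPanelAndPileup:
    def test_panel_splices_every_nui_at_its_breakpoint(self, rng):
        ref = [GenomeSequence("chr1", random_seq(rng, 10_000))]
        nuis = [_nui(random_seq(rng, 200), "chr1", 2000, "NUI_1"),
                _nui(random_seq(rng, 100), "chr1", 5000, "NUI_2")]
        panel, ivs = build_nui_panel(ref, nuis)
        assert panel[0].length == 10_300
        assert (ivs["NUI_1"].start, ivs["NUI_1"].end) == (2000, 2200)
        assert (ivs["NUI_2"].start, ivs["NUI_2"].end) == (5200, 5300)
        assert panel[0].seq[2000:2200] == nuis[0].seq

    def test_carrier_reads_make_a_present_call(self, rng):
        ref = [GenomeSequence("chr1", random_seq(rng, 20_000))]
        nui = _nui(random_seq(rng, 500), "chr1", 8000, "NUI_1")
        panel, ivs = build_nui_panel(ref, [nui])
        idx = KmerIndex(panel, k=21)
        reads = simulate_reads(panel + panel, coverage=30, err_rate=0.0, seed=1)
        depth, cons = pileup_consensus(reads.r1, reads.r2, idx)
        call = genotype_nui(depth, cons, idx, ivs["NUI_1"], "s1", "NUI_1")
        assert call.covered_fraction == 1.0
        assert call.consensus_identity == 1.0
        assert call.present

    def test_noncarrier_reads_leave_the_nui_uncovered(self, rng):
        ref = [GenomeSequence("chr1", random_seq(rng, 20_000))]
        nui = _nui(random_seq(rng, 1000), "chr1", 8000, "NUI_1")
        panel, ivs = build_nui_panel(ref, [nui])
        idx = KmerIndex(panel, k=21)
        reads = simulate_reads(ref + ref, coverage=30, err_rate=0.0, seed=2)
        depth, cons = pileup_consensus(reads.r1, reads.r2, idx)
        call = genotype_nui(depth, cons, idx, ivs["NUI_1"], "s1", "NUI_1")
        assert call.covered_fraction < 0.80
        assert not call.present

    def test_diverged_carrier_is_called_absent(self, rng):
        """A carrier whose insertion copy diverged ~15% from the panel allele
        fails the presence rule (its reads cannot support the panel allele)."""
        ref = [GenomeSequence("chr1", random_seq(rng, 20_000))]
        allele = random_seq(rng, 1000)
        nui = _nui(allele, "chr1", 8000, "NUI_1")
        panel, ivs = build_nui_panel(ref, [nui])
        idx = KmerIndex(panel, k=21)
        diverged = mutate_seq(rng, allele, subs=150)
        carrier, _ = build_nui_panel(ref, [_nui(diverged, "chr1", 8000, "NUI_1")])
        reads = simulate_reads(carrier + carrier, coverage=30, err_rate=0.0, seed=3)
        depth, cons = pileup_consensus(reads.r1, reads.r2, idx)
        call = genotype_nui(depth, cons, idx, ivs["NUI_1"], "s1", "NUI_1")
        assert not call.present

    def test_identity_rule_on_constructed_pileup(self, rng):
        """Full coverage but a mismatching consensus: 15% consensus
        divergence fails the 90% identity rule, 5% passes it."""
        ref = [GenomeSequence("chr1", random_seq(rng, 3000))]
        idx = KmerIndex(ref, k=21)
        iv = Interval("chr1", 1000, 1100)
        depth = np.ones(len(idx.cat), np.int32)
        for n_bad, expect_present in ((15, False), (5, True)):
            cons = idx.cat.copy()
            bad = rng.sample(range(1000, 1100), n_bad)
            cons[bad] = (cons[bad] + 1) % 4
            call = genotype_nui(depth, cons, idx, iv, "s", "n")
            assert call.covered_fraction == 1.0
            assert call.consensus_identity == pytest.approx(1 - n_bad / 100)
            assert call.present is expect_present

    def test_zero_length_interval_is_an_error(self, rng):
        ref = [GenomeSequence("chr1", random_seq(rng, 2000))]
        idx = KmerIndex(ref, k=21)
        with pytest.raises(ValueError):
            genotype_nui(np.zeros(10), np.zeros(10, np.uint8), idx,
                         Interval("chr1", 5, 5), "s", "n")


class TestMatrix:
    def _call(self, sample, nid, present):
        return GenotypeCall(sample, nid, 1.0 if present else 0.1,
                            1.0 if present else 0.0, present)

    def test_single_cell_matrix(self):
        m = build_matrix({"s1": [self._call("s1", "n1", True)]})
        assert m.presence.shape == (1, 1)
        assert m.presence[0, 0]

    def test_missing_cell_is_an_error(self):
        calls = {"s1": [self._call("s1", "n1", True), self._call("s1", "n2", False)],
                 "s2": [self._call("s2", "n1", True)]}
        with pytest.raises(ValueError, match="missing"):
            build_matrix(calls)

    def test_breed_labels_preserved(self):
        m = build_matrix({"s1": [self._call("s1", "n1", True)]}, {"s1": "Gir"})
        assert m.breed["s1"] == "Gir"


class TestMafFilter:
    def _matrix(self, presence):
        presence = np.asarray(presence, bool)
        ns, nn = presence.shape
        return GenotypeMatrix([f"s{i}" for i in range(ns)],
                              [f"n{j}" for j in range(nn)], presence,
                              np.ones_like(presence, float),
                              np.ones_like(presence, float))

    def test_fixed_and_absent_nuis_are_excluded(self):
        m = self._matrix(np.stack([np.ones(98), np.zeros(98),
                                   (np.arange(98) < 10)], axis=1))
        kept = maf_filter(m)
        assert kept == ["n2"]          # 10/98 ≈ 0.102 ≥ 0.05

    def test_frequency_just_below_threshold_excluded(self):
        col = np.zeros((98, 1))
        col[:4, 0] = 1                 # 4/98 ≈ 0.041 < 0.05
        assert maf_filter(self._matrix(col)) == []

    def test_matches_brute_force_column_count(self, rng):
        presence = np.array([[rng.random() < 0.3 for _ in range(40)]
                             for _ in range(98)])
        m = self._matrix(presence)
        expected = []
        for j in range(40):
            f = sum(presence[:, j]) / 98
            if 0 < f < 1 and min(f, 1 - f) >= 0.05:
                expected.append(f"n{j}")
        assert maf_filter(m) == expected


class TestOccurrence:
    def test_zero_one_two_coding(self):
        occ = {"n1": {("a1", 0), ("a1", 1), ("a2", 0)}, "n2": {("a2", 1)}}
        m = occurrence_matrix(occ, ["a1", "a2"], ["n1", "n2"])
        assert m.values.tolist() == [[2, 0], [1, 1]]

    def test_values_validated(self):
        with pytest.raises(ValueError):
            OccurrenceMatrix(["a"], ["n"], np.array([[3]]))


class TestPca:
    def test_identical_rows_get_identical_scores(self):
        X = np.array([[1, 0, 2], [1, 0, 2], [0, 1, 0]], float)
        scores, _ = pca(X)
        assert np.allclose(scores[0], scores[1])

    def test_toy_matrix_matches_eigendecomposition_oracle(self):
        X = np.array([[0.0, 0.0], [2.0, 1.0], [4.0, 5.0]])
        scores, evr = pca(X)
        from sklearn.decomposition import PCA as SkPCA
        sk = SkPCA(n_components=2).fit(X)
        sk_scores = sk.transform(X)
        for j in range(2):
            assert (np.allclose(scores[:, j], sk_scores[:, j], atol=1e-9)
                    or np.allclose(scores[:, j], -sk_scores[:, j], atol=1e-9))
        assert np.allclose(evr, sk.explained_variance_ratio_)

    def test_explained_fractions_sum_to_one(self, rng):
        X = np.array([[rng.random() for _ in range(6)] for _ in range(10)])
        _scores, evr = pca(X)
        assert evr.sum() == pytest.approx(1.0)

    def test_constant_columns_dropped(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        scores, _ = pca(X)
        assert scores.shape[1] == 1


class TestHierarchical:
    def _matrix(self, presence, samples):
        presence = np.asarray(presence, bool)
        return GenotypeMatrix(samples, [f"n{j}" for j in range(presence.shape[1])],
                              presence, np.ones_like(presence, float),
                              np.ones_like(presence, float))

    def test_duplicate_samples_join_first_at_height_zero(self):
        m = self._matrix([[1, 0, 1, 1], [1, 0, 1, 1], [0, 1, 0, 0]],
                         ["dupA", "dupB", "other"])
        tree = dendropy.Tree.get(data=hierarchical_cluster(m), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["dupA"], taxa["dupB"]) == pytest.approx(0.0)

    def test_three_sample_tree_matches_hand_computed_upgma(self):
        # Jaccard distances: d(s1,s2) = 1/3, d(s1,s3) = 3/4, d(s2,s3) = 2/3.
        # UPGMA joins (s1,s2) first at height 1/6; the root then sits at
        # mean(3/4, 2/3)/2 = 17/48, so the s1–s3 path is 17/24.
        m = self._matrix([[1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 0, 1]],
                         ["s1", "s2", "s3"])
        newick = hierarchical_cluster(m)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["s1"], taxa["s2"]) == pytest.approx(1 / 3, abs=1e-5)
        assert pdm.distance(taxa["s1"], taxa["s3"]) == pytest.approx(17 / 24, abs=1e-5)
        assert pdm.distance(taxa["s2"], taxa["s3"]) == pytest.approx(17 / 24, abs=1e-5)

    def test_newick_contains_all_sample_labels(self):
        m = self._matrix(np.eye(4, 6, dtype=bool), [f"smp{i}" for i in range(4)])
        newick = hierarchical_cluster(m)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {t.label for t in tree.taxon_namespace} == {f"smp{i}" for i in range(4)}
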