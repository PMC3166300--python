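import itertools

import numpy as np
import pytest

from betamarkers.motifs import (
    MarkovBackground,
    PSSM,
    binomial_enrichment,
    consensus_report,
    enrich,
    permutation_control,
    scan,
    score_distribution,
)
from betamarkers.simulate import simulate_promoters

COUNTS4 = np.array([[8, 1, 0, 2], [1, 6, 1, 1], [0, 2, 8, 1], [1, 1, 1, 6]], float)
COUNTS8 = np.array([[12, 0, 0, 0, 10, 0, 2, 0],
                    [0, 12, 0, 1, 0, 1, 0, 10],
                    [0, 0, 12, 0, 1, 11, 0, 1],
                    [0, 0, 0, 11, 1, 0, 10, 1]], float)
RES = 1e-3


def word_probability(word, bg):
    p = bg.stationary[word[0]]
    for a, b in zip(word[:-1], word[1:]):
        p *= bg.transition[a, b]
    return p


class TestPSSM:
    def test_frequencies_and_weights(self):
        pssm = PSSM(COUNTS4)
        np.testing.assert_allclose(pssm.frequencies.sum(axis=0), 1.0)
        w = pssm.weights(np.full(4, 0.25))
        assert np.isfinite(w).all()
        # most frequent base gets the highest weight in each column
        assert (np.argmax(w, axis=0) == np.argmax(COUNTS4, axis=0)).all()

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            PSSM(np.empty((4, 0)))
        with pytest.raises(ValueError):
            PSSM(-COUNTS4)
        with pytest.raises(ValueError):
            PSSM(np.zeros((4, 2)))


class TestBackground:
    def test_alternating_sequence_transitions(self):
        bg = MarkovBackground.fit(["AC" * 200])
        assert bg.transition[0, 1] > 0.95  # A -> C
        assert bg.transition[1, 0] > 0.95  # C -> A

    def test_uniform_random_sequence_near_uniform(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        bg = MarkovBackground.fit([seq])
        assert np.abs(bg.transition - 0.25).max() < 0.01

    def test_n_breaks_chain(self):
        bg_with_n = MarkovBackground.fit(["ACAC" * 30 + "N" + "ACAC" * 30])
        bg_without = MarkovBackground.fit(["ACAC" * 60])
        assert np.abs(bg_with_n.transition - bg_without.transition).max() < 0.02

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            MarkovBackground.fit(["ACGT"])

    def test_stationary_consistency(self):
        bg = MarkovBackground.cpg_depleted()
        np.testing.assert_allclose(bg.stationary @ bg.transition, bg.stationary,
                                   atol=1e-10)


class TestScan:
    def test_consensus_window_scores_column_max_sum(self):
        pssm = PSSM(COUNTS8)
        bg = MarkovBackground.uniform()
        w = pssm.weights(bg.stationary, resolution=RES)
        result = scan([pssm.consensus()], pssm, bg)
        assert result.scores.max() == pytest.approx(sum(w.max(axis=0)), abs=1e-9)

    def test_palindromic_motif_symmetric_scores(self):
        # GAATTC (EcoRI site) is its own reverse complement
        counts = np.zeros((4, 6))
        for i, b in enumerate("GAATTC"):
            counts["ACGT".index(b), i] = 10.0
        counts += 1.0
        pssm = PSSM(counts)
        bg = MarkovBackground.uniform()
        result = scan(["TTGAATTCAA"], pssm, bg)
        # scores come back forward-strand windows first, then reverse strand
        n = len(result.scores) // 2
        np.testing.assert_allclose(result.scores[:n], result.scores[n:], atol=1e-9)

    def test_windows_with_n_skipped(self):
        pssm = PSSM(COUNTS4)
        bg = MarkovBackground.uniform()
        clean = scan(["ACGTACGTACGT"], pssm, bg)
        with_n = scan(["ACGTANGTACGT"], pssm, bg)
        assert with_n.n_scanned == clean.n_scanned - 8  # 4 windows x 2 strands lost

    def test_brute_force_window_rescoring(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        pssm = PSSM(COUNTS4)
        bg = MarkovBackground.cpg_depleted()
        w = pssm.weights(bg.stationary, resolution=RES)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        expected = []
        for start in range(len(seq) - 3):
            window = seq[start : start + 4]
            expected.append(sum(w["ACGT".index(b), i] for i, b in enumerate(window)))
            rc = "".join(comp[b] for b in reversed(window))
            expected.append(sum(w["ACGT".index(b), i] for i, b in enumerate(rc)))
        result = scan([seq], pssm, bg)
        np.testing.assert_allclose(np.sort(result.scores), np.sort(expected), atol=1e-9)


class TestScoreDistribution:
    def test_single_column_uniform_background(self):
        counts = np.array([[9.0], [4.0], [2.0], [1.0]])
        pssm = PSSM(counts)
        bg = MarkovBackground.uniform()
        dist = score_distribution(pssm, bg, resolution=RES)
        w = pssm.weights(bg.stationary, resolution=RES).ravel()
        np.testing.assert_allclose(np.sort(dist.support), np.sort(w), atol=1e-9)
        np.testing.assert_allclose(dist.pmf, 0.25)

    @pytest.mark.parametrize("bg_factory", [
        MarkovBackground.uniform, MarkovBackground.cpg_depleted,
    ])
    def test_matches_exhaustive_enumeration(self, bg_factory):
        bg = bg_factory()
        pssm = PSSM(COUNTS4)
        w = pssm.weights(bg.stationary, resolution=RES)
        dist = score_distribution(pssm, bg, resolution=RES)
        scores, probs = [], []
        for word in itertools.product(range(4), repeat=4):
            scores.append(sum(w[b, i] for i, b in enumerate(word)))
            probs.append(word_probability(word, bg))
        scores, probs = np.array(scores), np.array(probs)
        for t in np.unique(scores):
            exact = probs[scores >= t - 1e-9].sum()
            assert dist.sf(t) == pytest.approx(exact, abs=1e-9)

    def test_total_mass_one_for_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            counts = rng.integers(0, 20, size=(4, 6)).astype(float) + 0.5
            dist = score_distribution(PSSM(counts), MarkovBackground.cpg_depleted(),
                                      resolution=RES)
            assert dist.total_mass == pytest.approx(1.0, abs=1e-9)
            assert (np.diff(dist._sf) <= 1e-12).all()  # sf non-increasing

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError):
            score_distribution(PSSM(COUNTS4), MarkovBackground.uniform(), resolution=0)


class TestBinomialEnrichment:
    def test_no_informative_scores_gives_sig_zero(self):
        pssm = PSSM(COUNTS4)
        bg = MarkovBackground.uniform()
        dist = score_distribution(pssm, bg, resolution=RES)
        # all observed scores at the distribution minimum: p(t) = 1 > cap
        result = binomial_enrichment(np.full(10, dist.support.min()), 10, dist)
        assert result.sig == 0.0 and result.p_value == 1.0

    def test_empty_scores(self):
        dist = score_distribution(PSSM(COUNTS4), MarkovBackground.uniform())
        result = binomial_enrichment(np.empty(0), 0, dist)
        assert result.sig == 0.0

    def test_sig_nondecreasing_in_planted_sites(self):
        sigs = []
        for n_planted in (0, 4, 8):
            seqs, _, _ = simulate_promoters(20, n_planted, COUNTS8,
                                            sites_per_seq=2, length=400, seed=3)
            bg = MarkovBackground.fit(seqs.values())
            sigs.append(enrich(seqs, PSSM(COUNTS8, name="m"), bg).sig)
        assert sigs[0] <= sigs[1] <= sigs[2]
        assert sigs[2] > sigs[0]

    def test_duplicating_input_does_not_decrease_sig(self):
        seqs, _, _ = simulate_promoters(10, 5, COUNTS8, sites_per_seq=2,
                                        length=300, seed=4)
        bg = MarkovBackground.fit(seqs.values())
        pssm = PSSM(COUNTS8, name="m")
        single = enrich(seqs, pssm, bg)
        doubled_seqs = list(seqs.values()) * 2
        doubled = enrich(doubled_seqs, pssm, bg)
        assert doubled.sig >= single.sig - 1e-9

    def test_reverse_complement_inputs_invariant(self):
        seqs, _, _ = simulate_promoters(10, 5, COUNTS8, sites_per_seq=2,
                                        length=300, seed=5)
        bg = MarkovBackground.fit(seqs.values())
        pssm = PSSM(COUNTS8, name="m")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = ["".join(comp[b] for b in reversed(s)) for s in seqs.values()]
        a = enrich(seqs, pssm, bg)
        b = enrich(rc, pssm, bg)
        assert a.sig == pytest.approx(b.sig, abs=1e-9)
        assert a.hits == b.hits and a.n_scanned == b.n_scanned


class TestPermutationControl:
    def test_uniform_matrix_invariant_under_permutation(self):
        counts = np.full((4, 5), 3.0)
        seqs, _, _ = simulate_promoters(5, 0, None, 0, length=200, seed=6)
        bg = MarkovBackground.fit(seqs.values())
        pssm = PSSM(counts, name="uniform")
        base = enrich(seqs, pssm, bg)
        ctrl = permutation_control(seqs, pssm, bg, n_permutations=5, seed=1)
        for r in ctrl.results:
            assert r.sig == pytest.approx(base.sig, abs=1e-9)

    def test_seed_determinism(self):
        seqs, _, _ = simulate_promoters(5, 3, COUNTS8, sites_per_seq=1,
                                        length=200, seed=7)
        pssm = PSSM(COUNTS8, name="m")
        a = permutation_control(seqs, pssm, n_permutations=6, seed=42)
        b = permutation_control(seqs, pssm, n_permutations=6, seed=42)
        assert a.orders == b.orders
        np.testing.assert_allclose(a.sigs, b.sigs)

    def test_identity_excluded_and_orders_distinct(self):
        seqs, _, _ = simulate_promoters(5, 0, None, 0, length=200, seed=8)
        pssm = PSSM(COUNTS8, name="m")
        ctrl = permutation_control(seqs, pssm, n_permutations=10, seed=0)
        identity = list(range(8))
        assert identity not in ctrl.orders
        assert len({tuple(o) for o in ctrl.orders}) == len(ctrl.orders)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            permutation_control(["ACGT" * 50], PSSM(np.array([[5.], [1.], [1.], [1.]])),
                                n_permutations=3)


class TestConsensusReport:
    def test_intersection_and_union(self):
        report = consensus_report({"scan": ["m1", "m2", "m3"], "dire": ["m2", "m3", "m4"]})
        assert report.intersection == ["m2", "m3"]
        assert report.union == ["m1", "m2", "m3", "m4"]
        assert report.only == {"scan": ["m1"], "dire": ["m4"]}
        assert report.counts["intersection"] == 2

    def test_disjoint_sets(self):
        report = consensus_report({"a": ["m1"], "b": ["m2"]})
        assert report.intersection == []

    def test_single_configuration_rejected(self):
        with pytest.raises(ValueError):
            consensus_report({"a": ["m1"]})
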