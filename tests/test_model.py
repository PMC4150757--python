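"""Emission, site and duration model estimation and scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anchorgene.io_formats import Contig, GenomeSequence, JunctionEvidence
from anchorgene.model import (DEFAULT_WINDOWS, HSMMParameters, MarkovChainModel,
                              SiteModel, estimate_duration, estimate_markov,
                              estimate_site_model, heuristic_coding_model,
                              heuristic_init, score_coding, score_noncoding,
                              score_site, site_window)
from anchorgene.simulate import _ChainSampler, make_true_params


def tv(p, q):
    return 0.5 * np.abs(np.asarray(p) - np.asarray(q)).sum()


class TestEstimateMarkov:
    def test_order0_all_a(self):
        m = estimate_markov([("AAAA", 0)], order=0, periodicity=1, pseudocount=0)
        assert np.exp(m.logp[0, 0, 0]) == pytest.approx(1.0)

    def test_pseudocount_gives_uniform_on_empty_counts(self):
        with pytest.warns(UserWarning):
            m = estimate_markov([], order=1, periodicity=1, pseudocount=1)
        assert np.allclose(np.exp(m.logp), 0.25)

    def test_order2_recovery_from_100kb(self):
        truth = make_true_params().noncoding  # order-2 homogeneous chain
        rng = np.random.default_rng(3)
        seq = _ChainSampler(truth, rng).sample(100_000)
        est = estimate_markov([(seq, 0)], order=2, periodicity=1)
        worst = max(tv(np.exp(est.logp[0, c]), np.exp(truth.logp[0, c]))
                    for c in range(16))
        assert worst < 0.02

    def test_three_periodic_frame_shift_permutes_submodels(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=9000))
        a = estimate_markov([(seq, 0)], order=0, periodicity=3)
        b = estimate_markov([(seq, 1)], order=0, periodicity=3)
        # shifting the frame offset by 1 relabels codon position g as g+1
        for f in range(3):
            assert np.allclose(a.logp[(f + 2) % 3], b.logp[f])

    def test_estimation_invariant_to_input_order(self):
        frags = [("ACGTACGGT", 0), ("TTTACGGA", 2), ("GGCATTTA", 1)]
        a = estimate_markov(frags, 1, 3)
        b = estimate_markov(frags[::-1], 1, 3)
        assert np.allclose(a.logp, b.logp)

    def test_normalization(self):
        m = estimate_markov([("ACGTTTGCA" * 30, 0)], order=2, periodicity=3)
        assert np.allclose(np.exp(m.logp).sum(axis=2), 1.0, atol=1e-9)
        assert np.all(np.exp(m.logp) > 0)


class TestSiteModel:
    def test_identical_windows_prob_one(self):
        m = estimate_site_model(["ACGTACGTA"] * 5, "donor", pseudocount=0)
        assert score_site(m, "ACGTACGTA") == pytest.approx(0.0)

    def test_unequal_windows_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            estimate_site_model(["ACGTACGTA", "ACGT"], "donor")

    def test_pwm_recovery_n500(self):
        truth = make_true_params().sites["donor"]
        rng = np.random.default_rng(5)
        p = np.exp(truth.logp)
        wins = ["".join("ACGT"[rng.choice(4, p=p[i] / p[i].sum())]
                        for i in range(truth.length)) for _ in range(500)]
        est = estimate_site_model(wins, "donor")
        for i in range(truth.length):
            assert tv(np.exp(est.logp[i]), p[i]) < 0.05

    def test_n_scores_as_uniform(self):
        m = SiteModel.uniform("stop")
        L = m.length
        assert m.score("N" * L) == pytest.approx(L * np.log(0.25))


class TestDuration:
    def test_point_mass_no_smoothing(self):
        d = estimate_duration([80] * 50, "intron", smoothing_bandwidth=0,
                              l_max=200, min_floor=10, pseudocount=0)
        assert int(np.argmax(d.logpmf)) == 80
        assert np.exp(d.logpmf[80]) == pytest.approx(1.0)

    @given(st.lists(st.integers(1, 400), min_size=1, max_size=60))
    @settings(max_examples=25, deadline=None)
    def test_mass_sums_to_one(self, lengths):
        d = estimate_duration(lengths, "intron", l_max=500, min_floor=1)
        assert d.total_mass() == pytest.approx(1.0, abs=1e-9)

    def test_geometric_tail_mean_matches_mean_excess(self):
        rng = np.random.default_rng(1)
        lengths = 1 + rng.exponential(300, size=20_000).astype(int)
        l_max = 500
        d = estimate_duration(lengths, "intron", l_max=l_max, min_floor=1)
        excess = lengths[lengths > l_max] - l_max
        tail_mean = 1.0 / (1.0 - d.tail_rate)
        assert tail_mean == pytest.approx(excess.mean(), rel=0.05)

    def test_sampling_respects_support(self):
        d = estimate_duration([50, 60, 70], "intron", l_max=100, min_floor=40)
        s = d.sample(np.random.default_rng(0), 200)
        assert np.all(s >= d.min_len)


class TestScoring:
    def test_uniform_model_scores_quarter_per_base(self):
        m = MarkovChainModel.uniform(1, 1)
        assert score_noncoding(m, "ACGTACGT") == pytest.approx(8 * np.log(0.25))

    def test_chain_rule_concatenation(self):
        m = make_true_params().coding
        s1, s2 = "ATGGCTAAC", "GGTTCAGCA"
        whole = score_coding(m, s1 + s2, frame_offset=0)
        parts = (score_coding(m, s1, frame_offset=0)
                 + score_coding(m, s2, frame_offset=len(s1) % 3, context=s1))
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_agreement_with_direct_product_on_10mers(self):
        rng = np.random.default_rng(2)
        m = make_true_params().noncoding
        tables = np.exp(m.logp[0])
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT"), size=10))
            codes = [("ACGT").index(c) for c in s]
            p = 0.25 * 0.25  # first two bases lack full order-2 context
            for i in range(2, 10):
                ctx = codes[i - 2] * 4 + codes[i - 1]
                p *= tables[ctx, codes[i]]
            assert score_noncoding(m, s) == pytest.approx(np.log(p), abs=1e-12)

    def test_scoring_decreases_with_length(self):
        m = make_true_params().noncoding
        s = "ACGTTGCA" * 6
        scores = [score_noncoding(m, s[:k]) for k in range(4, len(s))]
        assert all(b < a for a, b in zip(scores, scores[1:]))


class TestHeuristicInit:
    def _uniform_gc_genome(self):
        g = GenomeSequence()
        g.add(Contig("c", "ACGT" * 2500, np.zeros(10_000, bool)))
        return g

    def test_50pct_gc_hits_anchor_point(self):
        g = self._uniform_gc_genome()
        with pytest.warns(UserWarning):
            params = heuristic_init(g, [])
        assert np.allclose(params.coding.logp, heuristic_coding_model(0.5).logp)
        assert np.allclose(np.exp(params.noncoding.logp), 0.25)

    def test_donor_pwm_recovered_from_hc_introns(self):
        truth = make_true_params()
        rng = np.random.default_rng(7)
        from anchorgene.simulate import _sample_pwm, _force
        da, db = DEFAULT_WINDOWS["donor"]
        aa, ab = DEFAULT_WINDOWS["acceptor"]
        n = 120_000
        seq = list("".join(rng.choice(list("ACGT"), size=n)))
        introns = []
        pos = 100
        while pos + 120 < n and len(introns) < 1000:
            don = _force(_sample_pwm(truth.sites["donor"], rng), da, "GT")
            acc = _force(_sample_pwm(truth.sites["acceptor"], rng), aa - 2, "AG")
            L = 80
            seq[pos - da:pos + db] = don
            seq[pos + L - aa:pos + L + ab] = acc
            introns.append(JunctionEvidence("c", pos, pos + L, "+", score=0.9))
            pos += 120
        g = GenomeSequence()
        g.add(Contig("c", "".join(seq), np.zeros(n, bool)))
        params = heuristic_init(g, introns)
        est = np.exp(params.sites["donor"].logp)
        tru = np.exp(truth.sites["donor"].logp)
        for i in range(est.shape[0]):
            assert tv(est[i], tru[i]) < 0.05
        # all introns of length 80 -> duration concentrated at 80
        d = params.durations["intron"]
        assert abs(d.mean() - 80) < 2

    def test_empty_hc_set_warns_and_uses_consensus_priors(self):
        g = self._uniform_gc_genome()
        with pytest.warns(UserWarning, match="high-confidence"):
            params = heuristic_init(g, [])
        don = np.exp(params.sites["donor"].logp)
        da, _ = DEFAULT_WINDOWS["donor"]
        assert don[da, 2] > 0.9 and don[da + 1, 3] > 0.9  # G, T pinned

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            heuristic_init(GenomeSequence(), [])


class TestParameterSet:
    def test_transition_distributions_normalize(self):
        p = make_true_params()
        for dist in p.transition_distributions():
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_serialization_roundtrip(self, tmp_path):
        p = make_true_params()
        path = tmp_path / "model.yaml"
        p.save(path)
        q = HSMMParameters.load(path)
        assert np.allclose(p.coding.logp, q.coding.logp)
        assert np.allclose(p.sites["acceptor"].logp, q.sites["acceptor"].logp)
        d1, d2 = p.durations["intron"], q.durations["intron"]
        assert d1.min_len == d2.min_len and d1.l_max == d2.l_max
        body1 = np.where(np.isfinite(d1.logpmf), d1.logpmf, -1e30)
        body2 = np.where(np.isfinite(d2.logpmf), d2.logpmf, -1e30)
        assert np.allclose(body1, body2)
        assert p.transitions == q.transitions

    def test_site_window_orientation(self):
        #            0123456789
        seq = "AAACGTAAGTCCC"
        w = {"donor": (3, 6)}
        assert site_window(seq, "donor", "+", 5, w) == seq[2:11]
        # reverse donor anchored at intron end: revcomp of left window
        from anchorgene.io_formats import revcomp
        assert site_window(seq, "donor", "-", 8, w) == revcomp(seq[2:11])
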