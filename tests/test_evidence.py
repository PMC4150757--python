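"""Evidence integration: high-confidence filtering, anchoring, training-set
selection and constrained decoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anchorgene.decoder import viterbi_parse
from anchorgene.evidence import (anchor_splice_sites,
                                 constrain_parse_with_introns,
                                 filter_high_confidence,
                                 select_training_elements)
from anchorgene.io_formats import (Contig, GeneStructure, GenomeSequence,
                                   JunctionEvidence)
from conftest import make_random_contig, make_reduced_params


def J(cid, a, b, strand="+", score=0.9):
    return JunctionEvidence(cid, a, b, strand, score=score)


class TestHighConfidence:
    def test_score_threshold_strict(self):
        js = [J("c", 0, 10, score=0.6), J("c", 20, 30, score=0.5),
              J("c", 40, 50, score=0.50001)]
        kept = filter_high_confidence(js, "score")
        assert [j.start for j in kept] == [0, 40]

    def test_coverage_threshold_strict(self):
        js = [JunctionEvidence("c", 0, 10, "+", coverage=4),
              JunctionEvidence("c", 20, 30, "+", coverage=3)]
        kept = filter_high_confidence(js, "coverage")
        assert [j.start for j in kept] == [0]

    def test_empty_input(self):
        assert filter_high_confidence([], "score") == []

    def test_mode_dialect_mismatch(self):
        with pytest.raises(ValueError, match="coverage"):
            filter_high_confidence([JunctionEvidence("c", 0, 9, "+",
                                                     coverage=5)], "score")


class TestAnchoring:
    def _gene(self, strand="+"):
        return GeneStructure("c", strand, [(100, 200), (260, 350), (420, 520)],
                             id="g")

    def test_exact_match_anchors_both_sites(self):
        g = self._gene()
        [a] = anchor_splice_sites([g], [J("c", 200, 260)])
        assert a.donor_anchored == [True, False]
        assert a.acceptor_anchored == [True, False]
        assert a.both_anchored == [True, False]

    def test_off_by_one_does_not_anchor(self):
        g = self._gene()
        [a] = anchor_splice_sites([g], [J("c", 201, 261)])
        assert a.donor_anchored == [False, False]
        assert a.acceptor_anchored == [False, False]

    def test_strand_mismatch_does_not_anchor(self):
        g = self._gene()
        [a] = anchor_splice_sites([g], [J("c", 200, 260, strand="-")])
        assert not any(a.donor_anchored)

    def test_minus_strand_boundary_roles(self):
        g = self._gene("-")
        # transcript intron 0 of a '-' gene is the genomically RIGHT intron,
        # its donor boundary the intron end
        [a] = anchor_splice_sites([g], [J("c", 350, 420, strand="-")])
        assert a.donor_anchored == [True, False]
        assert a.acceptor_anchored == [True, False]

    def test_two_junctions_each_matching_one_end(self):
        g = self._gene()
        [a] = anchor_splice_sites(
            [g], [J("c", 200, 300), J("c", 150, 260)])
        assert a.donor_anchored[0] and a.acceptor_anchored[0]
        assert not a.both_anchored[0]  # no single junction spans both

    @given(st.sets(st.integers(0, 1), max_size=2))
    @settings(max_examples=8, deadline=None)
    def test_monotone_in_junction_set(self, subset_idx):
        g = self._gene()
        full = [J("c", 200, 260), J("c", 350, 420)]
        sub = [full[i] for i in sorted(subset_idx)]
        [a_sub] = anchor_splice_sites([g], sub)
        [a_full] = anchor_splice_sites([g], full)
        for x, y in zip(a_sub.donor_anchored, a_full.donor_anchored):
            assert (not x) or y
        for x, y in zip(a_sub.acceptor_anchored, a_full.acceptor_anchored):
            assert (not x) or y


def _fixture_genome_and_genes():
    """Hand-built six-gene fixture on one 6 kb contig.

    g1 '+' 2 exons, intron fully supported          -> all sites anchored
    g2 '+' single 900 nt exon, no anchors possible  -> long-exon fragment
    g3 '-' 3 exons, one donor anchored
    g4 '+' 2 exons, 400 nt exons, no anchors        -> contributes nothing
    g5 '+' 2 exons with donor+acceptor anchored; g6 '+' 2 exons with donor
    anchored; g5.terminal acceptor & g6.initial donor anchored -> the gap
    between g5 and g6 is an intergenic fragment.
    """
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=6000))
    genome = GenomeSequence()
    genome.add(Contig("c", seq, np.zeros(6000, bool)))
    g1 = GeneStructure("c", "+", [(100, 250), (310, 460)], id="g1")
    g2 = GeneStructure("c", "+", [(600, 1500)], id="g2")          # 900 nt
    g3 = GeneStructure("c", "-", [(1700, 1850), (1910, 2060), (2120, 2270)],
                       id="g3")
    g4 = GeneStructure("c", "+", [(2500, 2900), (2960, 3360)], id="g4")
    g5 = GeneStructure("c", "+", [(3600, 3750), (3810, 3960)], id="g5")
    g6 = GeneStructure("c", "+", [(4400, 4550), (4610, 4760)], id="g6")
    junctions = [
        J("c", 250, 310),            # g1 intron, both ends
        J("c", 1850, 1910, "-"),     # g3 genomic intron 0 = transcript intron 1
        J("c", 3750, 3810),          # g5 intron, both ends
        J("c", 4550, 4610),          # g6 intron, both ends
    ]
    genes = anchor_splice_sites([g1, g2, g3, g4, g5, g6], junctions)
    return genome, genes


class TestSelection:
    def test_hand_enumerated_counts(self):
        genome, genes = _fixture_genome_and_genes()
        ts = select_training_elements(genes, genome, long_exon_min=800, trim=60)
        c = ts.counts()
        # anchored exons: g1 both, g3 two exons adjacent to its anchored
        # donor (transcript intron 1 = genomic intron 0), g5 both, g6 both
        assert c["anchored_exon_fragments"] == 2 + 2 + 2 + 2
        assert c["long_exon_fragments"] == 1          # g2 only
        assert c["coding_fragments"] == 9
        # both-ends anchored introns: g1, g3(genomic intron 0), g5, g6
        assert c["anchored_introns"] == 4
        assert c["intergenic_fragments"] == 1         # between g5 and g6
        assert c["complete_structures"] == 6
        n_donor = sum(v for k, v in c.items() if k.startswith("site_donor"))
        n_acc = sum(v for k, v in c.items() if k.startswith("site_acceptor"))
        assert n_donor == 4 and n_acc == 4
        # start sites: anchored initial exons of g1, g5, g6 ('+') only
        assert c["site_start"] == 3
        # stop sites: anchored terminal exons: g1, g5, g6; g3's terminal
        # exon is adjacent to its anchored transcript-intron-1 acceptor
        assert c["site_stop"] == 4

    def test_long_unanchored_exon_trimmed_to_780(self):
        genome, genes = _fixture_genome_and_genes()
        ts = select_training_elements(genes, genome, long_exon_min=800, trim=60)
        long = [f for f in ts.coding_fragments if f[2] == "long_exon"]
        assert len(long) == 1
        seq, off, _ = long[0]
        assert len(seq) == 900 - 2 * 60
        assert off == 60 % 3

    def test_exactly_800_exon_not_selected(self):
        genome = GenomeSequence()
        genome.add(Contig("c", "A" * 2000, np.zeros(2000, bool)))
        g = GeneStructure("c", "+", [(100, 900)], id="x")  # exactly 800
        [a] = anchor_splice_sites([g], [])
        ts = select_training_elements([a], genome)
        assert ts.coding_fragments == []

    def test_provenance_partition_exact(self):
        genome, genes = _fixture_genome_and_genes()
        ts = select_training_elements(genes, genome)
        assert all(f[2] in ("anchored", "long_exon") for f in ts.coding_fragments)

    def test_es_mode_takes_everything(self):
        genome, genes = _fixture_genome_and_genes()
        ts = select_training_elements(genes, genome, es_mode=True)
        c = ts.counts()
        assert c["coding_fragments"] == 12          # every exon of 6 genes
        assert c["anchored_introns"] == 6           # every predicted intron
        assert c["intergenic_fragments"] == 5       # every gap


class TestConstrainedDecoding:
    def test_empty_constraint_set_is_plain_viterbi(self):
        rng = np.random.default_rng(4)
        params = make_reduced_params(rng)
        contig = make_random_contig(rng, 0)
        a = viterbi_parse(params, contig)
        b = constrain_parse_with_introns(params, contig, [])
        assert [(s.kind, s.start, s.end) for s in a.segments] == \
               [(s.kind, s.start, s.end) for s in b.segments]
        assert a.score == pytest.approx(b.score, abs=1e-9)

    def test_forced_intron_appears(self):
        # constrain decoding with a GT..AG junction in a region the free
        # parse leaves intergenic: whenever the constraint is feasible the
        # returned parse contains an intron at exactly those coordinates
        rng = np.random.default_rng(9)
        n_satisfied = 0
        for i in range(0, 40, 2):
            params = make_reduced_params(rng)
            contig = make_random_contig(rng, i, 80, 120)
            seq = contig.seq
            gts = [k for k in range(len(seq) - 12) if seq[k:k + 2] == "GT"]
            ags = [k for k in range(12, len(seq)) if seq[k - 2:k] == "AG"]
            pair = next(((d, a) for d in gts for a in ags
                         if 6 <= a - d <= 24), None)
            if pair is None:
                continue
            free = viterbi_parse(params, contig)
            free_keys = {(s.start, s.end) for s in free.segments
                         if s.kind == "intron"}
            j = JunctionEvidence(contig.id, pair[0], pair[1], "+", score=0.9)
            cp = constrain_parse_with_introns(params, contig, [j])
            keys = {(s.start, s.end, s.strand) for s in cp.segments
                    if s.kind == "intron"}
            if cp.satisfied_constraints:
                assert (j.start, j.end, "+") in keys
                if (j.start, j.end) not in free_keys:
                    n_satisfied += 1
        assert n_satisfied >= 3, \
            "expected several feasible constraints forced into the parse"

    def test_constrained_score_never_exceeds_unconstrained(self):
        rng = np.random.default_rng(23)
        checked = 0
        for i in range(40):
            params = make_reduced_params(rng)
            contig = make_random_contig(rng, i, 60, 110)
            free = viterbi_parse(params, contig)
            # constrain with a junction at an arbitrary canonical GT..AG pair
            seq = contig.seq
            gts = [k for k in range(len(seq) - 12) if seq[k:k + 2] == "GT"]
            ags = [k for k in range(12, len(seq)) if seq[k - 2:k] == "AG"]
            pair = next(((d, a) for d in gts for a in ags
                         if 5 <= a - d <= 25), None)
            if pair is None:
                continue
            j = JunctionEvidence(contig.id, pair[0], pair[1], "+", score=0.9)
            cp = constrain_parse_with_introns(params, contig, [j])
            assert cp.score <= free.score + 1e-9
            checked += 1
        assert checked >= 10
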