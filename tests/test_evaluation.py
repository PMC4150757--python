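"""Test-set filters and multi-level accuracy computation."""

import numpy as np
import pytest

from anchorgene.evaluation import build_test_set, compare, EVAL_LEVELS
from anchorgene.io_formats import Contig, GeneStructure, GenomeSequence


def _clean_gene_seq(n_codons):
    return "ATG" + "GCT" * (n_codons - 2) + "TAA"


def _place(seq_list, pos, s):
    for i, ch in enumerate(s):
        seq_list[pos + i] = ch
    return pos + len(s)


def build_filter_fixture():
    """One contig; ten transcripts engineered so filters (i)-(vi) each
    remove specific genes, leaving exactly four survivors.

    v1: exon overlaps a masked repeat                       (i)
    v2: exons overlap v1's exons (other gene)               (ii)
    v3: contains a 5 nt exon                                (iii)
    v4: contains a 10 001 nt intron                         (iv)
    v5: non-GT-AG splice dinucleotides                      (v)
    v6a/v6b: two isoforms of one gene                       (vi)
    k1..k4 (interleaved): clean single-exon genes           survive
    Note v6a/v6b count as one gene with two transcripts, so the fixture
    holds 9 genes / 10 transcripts.
    """
    n = 40_000
    rng = np.random.default_rng(8)
    seq = list(rng.choice(list("ACGT"), size=n))
    mask = np.zeros(n, bool)
    genes = []

    # v1 on masked repeat
    mask[1000:1300] = True
    _place(seq, 1000, _clean_gene_seq(50))
    genes.append(GeneStructure("c", "+", [(1000, 1150)], id="v1", gene_id="v1"))
    # v2 overlapping v1
    _place(seq, 1100, _clean_gene_seq(50))
    genes.append(GeneStructure("c", "+", [(1100, 1250)], id="v2", gene_id="v2"))
    # k1 clean
    _place(seq, 2000, _clean_gene_seq(60))
    genes.append(GeneStructure("c", "+", [(2000, 2180)], id="k1", gene_id="k1"))
    # v3: 5 nt exon (two-exon gene, GT..AG intron)
    _place(seq, 3000, "ATGGC")
    _place(seq, 3005, "GT" + "C" * 26 + "AG")
    _place(seq, 3035, "T" * 100 + "TAA")  # 5 + 103 = 108 nt CDS
    genes.append(GeneStructure("c", "+", [(3000, 3005), (3035, 3138)],
                               id="v3", gene_id="v3"))
    # k2 clean
    _place(seq, 4000, _clean_gene_seq(60))
    genes.append(GeneStructure("c", "+", [(4000, 4180)], id="k2", gene_id="k2"))
    # v4: 10001 nt intron
    _place(seq, 5000, "ATG" + "GCT" * 20)
    _place(seq, 5063, "GT" + "A")
    _place(seq, 15062, "AG")
    _place(seq, 15064, "GCT" * 20 + "TAA")
    genes.append(GeneStructure("c", "+", [(5000, 5063), (15064, 15127)],
                               id="v4", gene_id="v4"))
    # k3 clean
    _place(seq, 16000, _clean_gene_seq(60))
    genes.append(GeneStructure("c", "+", [(16000, 16180)], id="k3", gene_id="k3"))
    # v5: non-canonical splice (CC..AG)
    _place(seq, 17000, "ATG" + "GCT" * 20)
    _place(seq, 17063, "CC" + "A" * 26 + "AG")
    _place(seq, 17093, "GCT" * 20 + "TAA")
    genes.append(GeneStructure("c", "+", [(17000, 17063), (17093, 17156)],
                               id="v5", gene_id="v5"))
    # v6: one gene, two isoforms
    _place(seq, 18000, _clean_gene_seq(60))
    genes.append(GeneStructure("c", "+", [(18000, 18180)], id="v6a", gene_id="v6"))
    genes.append(GeneStructure("c", "+", [(18000, 18150)], id="v6b", gene_id="v6"))
    # k4 clean
    _place(seq, 19000, _clean_gene_seq(60))
    genes.append(GeneStructure("c", "+", [(19000, 19180)], id="k4", gene_id="k4"))

    genome = GenomeSequence()
    genome.add(Contig("c", "".join(seq), mask))
    return genome, genes


class TestBuildTestSet:
    def test_exactly_the_hand_enumerated_survivors(self):
        genome, genes = build_filter_fixture()
        kept = build_test_set(genes, genome)
        assert sorted(g.id for g in kept) == ["k1", "k2", "k3", "k4"]

    def test_boundary_10000_intron_retained(self):
        n = 25_000
        seq = list("A" * n)
        _place(seq, 100, "ATG" + "GCT" * 20)
        _place(seq, 163, "GT" + "C")
        _place(seq, 10161, "AG")  # intron [163, 10163) = exactly 10000 nt
        _place(seq, 10163, "GCT" * 20 + "TAA")
        genome = GenomeSequence()
        genome.add(Contig("c", "".join(seq), np.zeros(n, bool)))
        g = GeneStructure("c", "+", [(100, 163), (10163, 10226)], id="b")
        assert (10163 - 163) == 10_000
        assert len(build_test_set([g], genome)) == 1

    def test_exclusion_hook(self):
        genome, genes = build_filter_fixture()
        kept = build_test_set(genes, genome, exclusions={"k1"})
        assert sorted(g.id for g in kept) == ["k2", "k3", "k4"]


def _toy_genome(n=8000):
    genome = GenomeSequence()
    genome.add(Contig("c", "A" * n, np.zeros(n, bool)))
    return genome


class TestCompare:
    def test_identity_scores_100_at_every_level(self, small_sim):
        prof, genome, truth, _ = small_sim
        rep = compare(truth, truth, genome)
        for lv in EVAL_LEVELS:
            assert rep.sn(lv) == pytest.approx(100.0)
            assert rep.sp(lv) == pytest.approx(100.0)

    def test_internal_exon_half_match(self):
        genome = _toy_genome()
        ann = [GeneStructure("c", "+", [(100, 200), (260, 360), (420, 520),
                                        (580, 682)], id="a")]
        pred = [GeneStructure("c", "+", [(100, 200), (260, 360), (423, 520),
                                         (580, 682)], id="p")]
        rep = compare(pred, ann, genome)
        d = rep.levels["internal_exon"]
        assert (d["tp"], d["annotated"], d["predicted"]) == (1, 2, 2)
        assert d["sn"] == pytest.approx(50.0)
        assert d["sp"] == pytest.approx(50.0)

    def test_start_moved_in_frame_partial_but_not_gene(self):
        genome = _toy_genome()
        ann = [GeneStructure("c", "+", [(100, 202), (260, 360)], id="a")]
        pred = [GeneStructure("c", "+", [(106, 202), (260, 360)], id="p")]
        rep = compare(pred, ann, genome)
        assert rep.levels["gene"]["tp"] == 0
        assert rep.levels["partial_gene"]["tp"] == 1
        # same check on the reverse strand: initiation is the RIGHT boundary
        ann_m = [GeneStructure("c", "-", [(100, 202), (260, 360)], id="am")]
        pred_m = [GeneStructure("c", "-", [(100, 202), (260, 354)], id="pm")]
        rep_m = compare(pred_m, ann_m, genome)
        assert rep_m.levels["gene"]["tp"] == 0
        assert rep_m.levels["partial_gene"]["tp"] == 1

    def test_partial_ge_gene_on_random_perturbations(self):
        rng = np.random.default_rng(5)
        genome = _toy_genome(30_000)
        ann = [GeneStructure("c", "+", [(i, i + 150), (i + 200, i + 353)],
                             id=f"a{i}") for i in range(500, 25_000, 1200)]
        for _ in range(20):
            pred = []
            for g in ann:
                ex = [list(e) for e in g.exons]
                if rng.random() < 0.5:
                    ex[0][0] += 3 * int(rng.integers(1, 5))  # start shift
                if rng.random() < 0.3:
                    ex[1][1] += 3 * int(rng.integers(1, 4))  # stop shift
                pred.append(GeneStructure("c", "+", [tuple(e) for e in ex],
                                          id="p" + g.id))
            rep = compare(pred, ann, genome)
            assert rep.sn("partial_gene") >= rep.sn("gene")
            assert rep.sp("partial_gene") >= rep.sp("gene")

    def test_nucleotide_level_invariant_to_exon_splitting(self):
        genome = _toy_genome()
        ann = [GeneStructure("c", "+", [(1000, 1300)], id="a")]
        whole = [GeneStructure("c", "+", [(1000, 1300)], id="w")]
        split = [GeneStructure("c", "+", [(1000, 1150)], id="s1"),
                 GeneStructure("c", "+", [(1150, 1300)], id="s2")]
        r1 = compare(whole, ann, genome)
        r2 = compare(split, ann, genome)
        assert r1.levels["nucleotide"] == r2.levels["nucleotide"]

    def test_prediction_outside_interval_excluded_from_sp(self):
        genome = _toy_genome()
        ann = [GeneStructure("c", "+", [(1000, 1300)], id="a")]
        pred = [GeneStructure("c", "+", [(1000, 1300)], id="p1"),
                GeneStructure("c", "+", [(5000, 5300)], id="p2")]  # far away
        rep = compare(pred, ann, genome)
        d = rep.levels["gene"]
        assert (d["tp"], d["predicted"]) == (1, 1)
        assert d["sp"] == pytest.approx(100.0)

    def test_unknown_contig_rejected(self):
        genome = _toy_genome()
        ann = [GeneStructure("c", "+", [(100, 400)], id="a")]
        pred = [GeneStructure("nope", "+", [(100, 400)], id="p")]
        with pytest.raises(ValueError, match="unknown contig"):
            compare(pred, ann, genome)

    def test_report_tsv(self, tmp_path):
        genome = _toy_genome()
        ann = [GeneStructure("c", "+", [(100, 400)], id="a")]
        rep = compare(ann, ann, genome)
        p = tmp_path / "rep.tsv"
        rep.to_tsv(p)
        lines = p.read_text().strip().split("\n")
        assert len(lines) == 1 + len(EVAL_LEVELS)
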