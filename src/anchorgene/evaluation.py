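"""Test-set construction and multi-level accuracy assessment.

Sensitivity (Sn = TP/annotated) is computed genome-wide against the test
genes; Specificity (Sp = TP/predicted) counts only predictions lying inside
the evaluation intervals — each test gene extended by 300 nt on both sides
— so that predictions far from any validated gene do not dilute precision.
Matching is exact-coordinate (and strand) at every level; the partial-gene
level repeats the gene level with the translation-initiation boundary
ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import GeneStructure, GenomeSequence, revcomp

__all__ = ["AccuracyReport", "build_test_set", "compare", "EVAL_LEVELS",
           "FLANK"]

FLANK = 300
EVAL_LEVELS = ("internal_exon", "intron", "donor", "acceptor", "initiation",
               "termination", "nucleotide", "gene", "partial_gene")
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class AccuracyReport:
    levels: dict = field(default_factory=dict)
    n_test_genes: int = 0
    n_predicted_genes: int = 0

    def sn(self, level):
        return self.levels[level]["sn"]

    def sp(self, level):
        return self.levels[level]["sp"]

    def f1(self, level):
        sn, sp = self.sn(level), self.sp(level)
        return 2 * sn * sp / (sn + sp) if sn + sp else 0.0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("level\ttp\tannotated\tpredicted\tsn\tsp\n")
            for lv in EVAL_LEVELS:
                d = self.levels[lv]
                fh.write(f"{lv}\t{d['tp']}\t{d['annotated']}\t{d['predicted']}\t"
                         f"{d['sn']:.1f}\t{d['sp']:.1f}\n")


def _set_level(report, level, tp, annotated, predicted):
    sn = 100.0 * tp / annotated if annotated else 0.0
    sp = 100.0 * tp / predicted if predicted else 0.0
    report.levels[level] = {"tp": tp, "annotated": annotated,
                            "predicted": predicted, "sn": sn, "sp": sp}


# ---------------------------------------------------------------------------
# Test-set filters


def build_test_set(annotation: list[GeneStructure], genome: GenomeSequence,
                   exclusions: set | None = None,
                   require_utr: bool = False) -> list[GeneStructure]:
    """Apply the test-set filters to an annotation.

    Excluded are genes whose exons overlap masked repeats (i) or other
    annotated genes including their UTR exons (ii); with very short exons
    (<6 nt) or introns (<20 nt) (iii); with very long introns (>10 000 nt,
    strict) (iv); with internal in-frame stops or non-GT-AG splice
    dinucleotides (v); with alternative isoforms (vi).  ``exclusions`` is
    the hook for externally computed protein-level filters (transposon /
    database-support screens); ``require_utr`` additionally demands
    annotated UTR on both sides of the CDS.
    """
    exclusions = exclusions or set()
    iso_count: dict[str, int] = {}
    for g in annotation:
        iso_count[g.gene_id] = iso_count.get(g.gene_id, 0) + 1

    def footprint(g):
        return g.mrna_exons if g.mrna_exons else g.exons

    by_contig: dict[str, list] = {}
    for g in annotation:
        by_contig.setdefault(g.contig_id, []).append(g)

    survivors = []
    for g in annotation:
        if g.id in exclusions or g.gene_id in exclusions:
            continue
        if iso_count[g.gene_id] > 1:                              # (vi)
            continue
        if g.contig_id not in genome.contigs:
            continue
        contig = genome[g.contig_id]
        seq, mask = contig.seq, contig.mask
        fp = footprint(g)
        if any(mask[a:b].any() for a, b in fp):                   # (i)
            continue
        overlap = False                                           # (ii)
        for other in by_contig[g.contig_id]:
            if other.gene_id == g.gene_id:
                continue
            for a, b in fp:
                for c, d in footprint(other):
                    if a < d and c < b:
                        overlap = True
                        break
                if overlap:
                    break
            if overlap:
                break
        if overlap:
            continue
        exon_lens = [b - a for a, b in g.exons] + [b - a for a, b in fp]
        intron_lens = [b - a for a, b in g.introns]
        if any(x < 6 for x in exon_lens) or any(x < 20 for x in intron_lens):
            continue                                              # (iii)
        if any(x > 10_000 for x in intron_lens):                  # (iv)
            continue
        cds = g.cds_sequence(seq)                                 # (v)
        codons = [cds[x:x + 3] for x in range(0, len(cds) - 3, 3)]
        if len(cds) % 3 != 0 or any(c in _STOPS for c in codons):
            continue
        bad_splice = False
        for a, b in g.introns:
            if g.strand == "+":
                dd, aa = seq[a:a + 2], seq[b - 2:b]
            else:
                dd, aa = revcomp(seq[b - 2:b]), revcomp(seq[a:a + 2])
            if dd != "GT" or aa != "AG":
                bad_splice = True
                break
        if bad_splice:
            continue
        if require_utr:
            if g.mrna_exons is None:
                continue
            lo, hi = g.mrna_exons[0][0], g.mrna_exons[-1][1]
            if lo >= g.exons[0][0] or hi <= g.exons[-1][1]:
                continue
        survivors.append(g)
    return survivors


# ---------------------------------------------------------------------------
# Element extraction


def _elements(genes):
    """Exact-coordinate element sets at each structural level."""
    el = {lv: set() for lv in ("internal_exon", "intron", "donor", "acceptor",
                               "initiation", "termination", "gene",
                               "partial_gene")}
    for g in genes:
        cid, st = g.contig_id, g.strand
        k = len(g.exons)
        for idx, (a, b) in enumerate(g.exons):
            first = idx == 0
            last = idx == k - 1
            if k > 1 and not first and not last:
                el["internal_exon"].add((cid, st, a, b))
        for a, b in g.introns:
            el["intron"].add((cid, st, a, b))
            d = a if st == "+" else b
            ac = b if st == "+" else a
            el["donor"].add((cid, st, d))
            el["acceptor"].add((cid, st, ac))
        el["initiation"].add((cid, st, g.start_pos))
        el["termination"].add((cid, st, g.stop_pos))
        el["gene"].add(g.coordinate_key())
        el["partial_gene"].add(g.partial_key())
    return el


def _span(item):
    """Genomic extent (cid, lo, hi) of an element key."""
    if len(item) == 3 and isinstance(item[2], tuple):  # gene/partial key
        cid, _, exons = item
        coords = [c for e in exons for c in e if c >= 0]
        return cid, min(coords), max(coords)
    if len(item) == 3:                                 # site
        return item[0], item[2], item[2] + 1
    return item[0], item[2], item[3]


def _inside(span, intervals):
    cid, lo, hi = span
    for a, b in intervals.get(cid, []):
        if a <= lo and hi <= b:
            return True
    return False


# ---------------------------------------------------------------------------


def compare(predictions: list[GeneStructure], test_genes: list[GeneStructure],
            genome: GenomeSequence) -> AccuracyReport:
    """Multi-level Sn/Sp of predictions against a filtered test set."""
    for g in predictions:
        if g.contig_id not in genome.contigs:
            raise ValueError(f"prediction on unknown contig {g.contig_id}")
    report = AccuracyReport(n_test_genes=len(test_genes),
                            n_predicted_genes=len(predictions))
    intervals: dict[str, list] = {}
    for g in test_genes:
        lo = max(0, g.exons[0][0] - FLANK)
        hi = min(len(genome[g.contig_id]), g.exons[-1][1] + FLANK)
        intervals.setdefault(g.contig_id, []).append((lo, hi))

    ann = _elements(test_genes)
    pred = _elements(predictions)
    for lv in ("internal_exon", "intron", "donor", "acceptor", "initiation",
               "termination", "gene", "partial_gene"):
        tp = len(ann[lv] & pred[lv])
        in_iv = [x for x in pred[lv] if _inside(_span(x), intervals)]
        _set_level(report, lv, tp, len(ann[lv]), len(in_iv))

    # nucleotide level, restricted to the evaluation intervals
    tp = ann_n = pred_n = 0
    for cid, ivs in intervals.items():
        n = len(genome[cid])
        iv_mask = np.zeros(n, dtype=bool)
        for a, b in ivs:
            iv_mask[a:b] = True
        a_mask = np.zeros(n, dtype=bool)
        for g in test_genes:
            if g.contig_id != cid:
                continue
            for a, b in g.exons:
                a_mask[a:b] = True
        p_mask = np.zeros(n, dtype=bool)
        for g in predictions:
            if g.contig_id != cid:
                continue
            for a, b in g.exons:
                p_mask[a:b] = True
        a_mask &= iv_mask
        p_mask &= iv_mask
        tp += int(np.sum(a_mask & p_mask))
        ann_n += int(np.sum(a_mask))
        pred_n += int(np.sum(p_mask))
    _set_level(report, "nucleotide", tp, ann_n, pred_n)
    return report
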