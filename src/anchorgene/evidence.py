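"""Junction filtering, splice-site anchoring and training-set assembly.

An *anchor splice site* is a predicted donor or acceptor whose coordinate
(and strand) coincides exactly with a boundary of a mapped intron — the
agreement of two independent methods, ab initio prediction and spliced
read alignment.  Training elements for re-estimation are selected around
anchors: exons with at least one anchored site, introns with both sites
anchored, intergenic stretches between two anchored border exons, plus the
long-exon exception (predicted exons above a length threshold enter
trimmed, anchored or not).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .decoder import Parse, viterbi_parse
from .io_formats import GeneStructure, GenomeSequence, JunctionEvidence, revcomp
from .model import HSMMParameters, site_window

__all__ = ["TrainingSet", "filter_high_confidence", "anchor_splice_sites",
           "select_training_elements", "constrain_parse_with_introns",
           "junction_dialect"]


def junction_dialect(junctions) -> str:
    kinds = {"score" if j.score is not None else "coverage" for j in junctions}
    if len(kinds) > 1:
        raise ValueError("junction set mixes score and coverage dialects")
    return kinds.pop() if kinds else "score"


def filter_high_confidence(junctions: list[JunctionEvidence],
                           mode: str) -> list[JunctionEvidence]:
    """High-confidence subset: strictly score > 0.5, or coverage > 3.

    Boundary values (score 0.5, coverage 3) are excluded.
    """
    if mode not in ("score", "coverage"):
        raise ValueError(f"unknown mode {mode}")
    out = []
    for j in junctions:
        if mode == "score":
            if j.score is None:
                raise ValueError("mode 'score' but junction carries coverage")
            if j.score > 0.5:
                out.append(j)
        else:
            if j.coverage is None:
                raise ValueError("mode 'coverage' but junction carries score")
            if j.coverage > 3:
                out.append(j)
    return out


def anchor_splice_sites(genes: list[GeneStructure],
                        junctions: list[JunctionEvidence]) -> list[GeneStructure]:
    """Fill per-intron anchored flags by exact coordinate-and-strand match.

    A donor/acceptor is anchored iff some junction on the same contig and
    strand has the corresponding intron boundary at exactly that
    coordinate; an intron is both-ends anchored iff one junction matches
    both boundaries.  Returns new GeneStructure objects; an extra
    ``both_anchored`` attribute marks single-junction double matches.
    """
    donor_set, acceptor_set, full_set = set(), set(), set()
    for j in junctions:
        d = j.start if j.strand == "+" else j.end
        a = j.end if j.strand == "+" else j.start
        donor_set.add((j.contig_id, j.strand, d))
        acceptor_set.add((j.contig_id, j.strand, a))
        full_set.add(j.key)
    out = []
    for g in genes:
        n_int = len(g.exons) - 1
        don = [False] * n_int
        acc = [False] * n_int
        both = [False] * n_int
        for gi, (a, b) in enumerate(g.introns):
            tx = gi if g.strand == "+" else n_int - 1 - gi
            d_coord = a if g.strand == "+" else b
            a_coord = b if g.strand == "+" else a
            don[tx] = (g.contig_id, g.strand, d_coord) in donor_set
            acc[tx] = (g.contig_id, g.strand, a_coord) in acceptor_set
            both[tx] = (g.contig_id, a, b, g.strand) in full_set
        ng = GeneStructure(g.contig_id, g.strand, list(g.exons), id=g.id,
                           gene_id=g.gene_id, donor_anchored=don,
                           acceptor_anchored=acc, mrna_exons=g.mrna_exons)
        ng.both_anchored = both
        out.append(ng)
    return out


@dataclass
class TrainingSet:
    """Labelled element collections feeding one round of re-estimation.

    ``coding_fragments`` are (sequence, frame_offset, provenance) with
    provenance 'anchored' xor 'long_exon' (or 'predicted' in unsupervised
    mode); sequences are in transcript orientation.
    """

    coding_fragments: list[tuple[str, int, str]] = field(default_factory=list)
    anchored_introns: list[tuple[str, int, int]] = field(default_factory=list)  # seq, len, phase
    intergenic_fragments: list[str] = field(default_factory=list)
    site_instances: dict = field(default_factory=dict)  # (kind, phase|None) -> [windows]
    exon_lengths: dict = field(default_factory=dict)    # role -> [lengths]
    complete_structures: list[GeneStructure] = field(default_factory=list)

    def counts(self) -> dict:
        c = {
            "coding_fragments": len(self.coding_fragments),
            "anchored_exon_fragments": sum(
                1 for f in self.coding_fragments if f[2] == "anchored"),
            "long_exon_fragments": sum(
                1 for f in self.coding_fragments if f[2] == "long_exon"),
            "anchored_introns": len(self.anchored_introns),
            "intergenic_fragments": len(self.intergenic_fragments),
            "complete_structures": len(self.complete_structures),
        }
        for (kind, ph), wins in sorted(self.site_instances.items(),
                                       key=lambda kv: (kv[0][0], str(kv[0][1]))):
            c[f"site_{kind}" + (f"_phase{ph}" if ph is not None else "")] = len(wins)
        return c


def _exon_roles(gene: GeneStructure) -> list[str]:
    """Role of each exon in transcript order."""
    k = len(gene.exons)
    if k == 1:
        return ["single_exon"]
    return ["initial_exon"] + ["internal_exon"] * (k - 2) + ["terminal_exon"]


def select_training_elements(anchored_genes: list[GeneStructure],
                             genome: GenomeSequence,
                             long_exon_min: int = 800, trim: int = 60,
                             windows=None, es_mode: bool = False) -> TrainingSet:
    """Assemble the training set from predictions with anchored flags.

    With ``es_mode`` the anchoring requirements are dropped (every predicted
    element is eligible) while the long-exon trimming rule is kept — the
    unsupervised degradation of the same selection.
    """
    ts = TrainingSet()
    for kind in ("donor", "acceptor"):
        for ph in (0, 1, 2):
            ts.site_instances[(kind, ph)] = []
    ts.site_instances[("start", None)] = []
    ts.site_instances[("stop", None)] = []

    by_contig: dict[str, list[GeneStructure]] = {}
    for g in anchored_genes:
        by_contig.setdefault(g.contig_id, []).append(g)

    for cid, genes in by_contig.items():
        if cid not in genome.contigs:
            continue
        seq = genome[cid].seq
        genes = sorted(genes, key=lambda g: g.exons[0][0])
        for g in genes:
            ts.complete_structures.append(g)
            roles = _exon_roles(g)
            tx_exons = g.exons_tx()
            n_int = len(g.exons) - 1
            phases = g.intron_phases()
            both = getattr(g, "both_anchored", [False] * n_int)
            cum = 0
            for k, ((a, b), role) in enumerate(zip(tx_exons, roles)):
                frag = seq[a:b] if g.strand == "+" else revcomp(seq[a:b])
                off = cum % 3
                length = b - a
                anchored = (
                    (k < n_int and g.donor_anchored[k])
                    or (k > 0 and g.acceptor_anchored[k - 1]))
                if es_mode:
                    if length > long_exon_min:
                        ts.coding_fragments.append(
                            (frag[trim:length - trim], (off + trim) % 3, "predicted"))
                    else:
                        ts.coding_fragments.append((frag, off, "predicted"))
                    ts.exon_lengths.setdefault(role, []).append(length)
                else:
                    if anchored:
                        ts.coding_fragments.append((frag, off, "anchored"))
                        ts.exon_lengths.setdefault(role, []).append(length)
                    elif length > long_exon_min:
                        ts.coding_fragments.append(
                            (frag[trim:length - trim], (off + trim) % 3, "long_exon"))
                cum += length
            # splice-site instances, binned by intron phase
            tx_introns = g.introns if g.strand == "+" else g.introns[::-1]
            for k, (a, b) in enumerate(tx_introns):
                ph = phases[k]
                d_anchor = (a if g.strand == "+" else b)
                a_anchor = (b if g.strand == "+" else a)
                if es_mode or g.donor_anchored[k]:
                    ts.site_instances[("donor", ph)].append(
                        site_window(seq, "donor", g.strand, d_anchor, windows))
                if es_mode or g.acceptor_anchored[k]:
                    ts.site_instances[("acceptor", ph)].append(
                        site_window(seq, "acceptor", g.strand, a_anchor, windows))
                intron_ok = es_mode or both[k]
                if intron_ok:
                    iseq = seq[a:b] if g.strand == "+" else revcomp(seq[a:b])
                    ts.anchored_introns.append((iseq, b - a, ph))
            # start/stop instances from anchored border exons
            if n_int == 0:
                init_anch = term_anch = es_mode
            else:
                init_anch = es_mode or g.donor_anchored[0]
                term_anch = es_mode or g.acceptor_anchored[n_int - 1]
            if init_anch:
                anchor = g.exons[0][0] if g.strand == "+" else g.exons[-1][1] - 1
                ts.site_instances[("start", None)].append(
                    site_window(seq, "start", g.strand, anchor, windows))
            if term_anch:
                anchor = g.exons[-1][1] if g.strand == "+" else g.exons[0][0]
                ts.site_instances[("stop", None)].append(
                    site_window(seq, "stop", g.strand, anchor, windows))
        # intergenic fragments between anchored border exons of adjacent genes
        for g1, g2 in zip(genes, genes[1:]):
            lo = g1.exons[-1][1]
            hi = g2.exons[0][0]
            if hi <= lo:
                continue
            if es_mode:
                ok = True
            else:
                ok = _right_border_anchored(g1) and _left_border_anchored(g2)
            if ok:
                ts.intergenic_fragments.append(seq[lo:hi])
    return ts


def _right_border_anchored(g: GeneStructure) -> bool:
    """Genomically rightmost exon is a border exon with its splice site anchored."""
    n_int = len(g.exons) - 1
    if n_int == 0:
        return False
    if g.strand == "+":   # rightmost exon = terminal
        return g.acceptor_anchored[n_int - 1]
    return g.donor_anchored[0]  # rightmost exon of '-' gene = initial


def _left_border_anchored(g: GeneStructure) -> bool:
    n_int = len(g.exons) - 1
    if n_int == 0:
        return False
    if g.strand == "+":   # leftmost exon = initial
        return g.donor_anchored[0]
    return g.acceptor_anchored[n_int - 1]  # leftmost exon of '-' gene = terminal


def constrain_parse_with_introns(params: HSMMParameters, contig,
                                 junctions: list[JunctionEvidence]) -> Parse:
    """Viterbi decoding constrained to contain the listed junctions as
    introns.  Jointly infeasible sets degrade to a maximal consistent
    subset; ``Parse.satisfied_constraints`` reports which junctions made it
    into the parse.  The returned score carries no constraint reward."""
    cons = [j for j in junctions if j.contig_id == contig.id]
    return viterbi_parse(params, contig, constraints=cons)
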