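"""Maximum-probability parsing of contigs under the gene-structure HSMM.

``score_parse`` is the normative definition of the scoring semantics: any
legal parse (a tiling of the contig into intergenic/exon/intron segments
obeying the gene grammar) gets the sum of segment emissions, segment
duration log-probabilities, boundary-signal scores and grammar transition
log-probabilities.  ``viterbi_parse`` maximises exactly that quantity with
a semi-Markov dynamic program over candidate signal positions;
``brute_force_parse`` enumerates every legal parse of a short contig and
serves as the independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _dp
from .io_formats import Contig, GeneStructure, revcomp
from .model import HSMMParameters, encode

__all__ = ["Segment", "Parse", "SequenceScorer", "score_parse",
           "viterbi_parse", "brute_force_parse", "parse_to_genes"]

NEG = _dp.NEG
LOG_UNIFORM = float(np.log(0.25))

EXON_KINDS = ("initial_exon", "internal_exon", "terminal_exon", "single_exon")
GENIC_KINDS = EXON_KINDS + ("intron",)

_STOP_CODES = ((3, 0, 0), (3, 0, 2), (3, 2, 0))      # TAA TAG TGA
_RSTOP_CODES = ((3, 3, 0), (1, 3, 0), (3, 1, 0))     # TTA CTA TCA


@dataclass(frozen=True)
class Segment:
    kind: str
    strand: str  # '+', '-' or '.' for intergenic
    start: int
    end: int
    phase: int = 0  # exon: transcript entry codon position; intron: intron phase

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Parse:
    contig_id: str
    segments: list[Segment]
    score: float
    satisfied_constraints: list = field(default_factory=list)

    def gene_runs(self) -> list[list[Segment]]:
        runs, cur = [], []
        for s in self.segments:
            if s.kind == "intergenic":
                if cur:
                    runs.append(cur)
                    cur = []
            else:
                cur.append(s)
        if cur:
            runs.append(cur)
        return runs


# ---------------------------------------------------------------------------
# Precomputation shared by scoring and decoding


def _emission_arrays(model, codes, mask, periodic):
    """Per-position log emission; uniform where base/context is masked, N
    or truncated by the sequence start."""
    n = codes.shape[0]
    k = model.order
    P = model.periodicity if periodic else 1
    out = np.full((P, n), LOG_UNIFORM)
    if n == 0:
        return out
    valid = (codes != 4) & ~mask
    ctx = np.zeros(n, dtype=np.int64)
    ctx_ok = valid.copy()
    if k > 0:
        ctx_ok = np.ones(n, dtype=bool)
        ctx_ok[:k] = False
        acc = np.zeros(n - k, dtype=np.int64)
        for j in range(k):
            c = codes[j:n - k + j]
            acc = acc * 4 + np.where(c == 4, 0, c)
            ctx_ok[k:] &= valid[j:n - k + j]
        ctx[k:] = acc
    ok = valid & ctx_ok
    idx = np.flatnonzero(ok)
    for f in range(P):
        out[f, idx] = model.logp[f % model.periodicity, ctx[idx], codes[idx]]
    return out


def _dur_vec(dur):
    v = np.where(np.isfinite(dur.logpmf), dur.logpmf, NEG)
    return np.ascontiguousarray(v, dtype=np.float64)


class SequenceScorer:
    """Per-contig arrays under one parameter set: phased coding and
    non-coding emission prefix sums, duration tables, candidate signal
    positions with batch site scores, masking barriers and in-frame stop
    clips.  Both ``score_parse`` and the Viterbi kernels read these, so the
    two paths share every numeric ingredient."""

    def __init__(self, params: HSMMParameters, contig: Contig):
        self.params = params
        self.contig = contig
        seq, mask = contig.seq, np.asarray(contig.mask, dtype=bool)
        n = len(seq)
        self.n = n
        codes = encode(seq)
        self.codes = codes
        self.mask = mask

        e_fwd = _emission_arrays(params.coding, codes, mask, periodic=True)
        nc_fwd = _emission_arrays(params.noncoding, codes, mask, periodic=False)[0]
        rc_codes = np.where(codes == 4, 4, 3 - codes)[::-1].copy()
        rc_mask = mask[::-1].copy()
        e_rc = _emission_arrays(params.coding, rc_codes, rc_mask, periodic=True)
        nc_rev = _emission_arrays(params.noncoding, rc_codes, rc_mask, periodic=False)[0][::-1].copy()
        e_rev = e_rc[:, ::-1]

        pos = np.arange(n)
        self.cf = np.zeros((3, n + 1))
        self.cr = np.zeros((3, n + 1))
        for g in range(3):
            self.cf[g, 1:] = np.cumsum(e_fwd[(pos + g) % 3, pos])
            self.cr[g, 1:] = np.cumsum(e_rev[(g - pos) % 3, pos])
        self.cnf = np.concatenate([[0.0], np.cumsum(nc_fwd)])
        self.cnr = np.concatenate([[0.0], np.cumsum(nc_rev)])

        # durations
        self.dur = {k: _dur_vec(params.durations[k]) for k in params.durations}
        self.dmin = {k: params.durations[k].min_len for k in params.durations}
        self.dmax = {k: params.durations[k].l_max for k in params.durations}
        ig = params.durations["intergenic"]
        body = np.exp(np.where(np.isfinite(ig.logpmf), ig.logpmf, -np.inf))
        rev_tail = np.cumsum(body[::-1])[::-1]
        sf = rev_tail + ig.tail_mass
        with np.errstate(divide="ignore"):
            self.ig_sf = np.where(
                np.arange(ig.l_max + 1) <= ig.min_len, 0.0,
                np.log(np.maximum(sf, 1e-300)))
        self.ig_tail_logmass = float(np.log(ig.tail_mass)) if ig.tail_mass > 0 else NEG
        self.ig_log_r = float(np.log(ig.tail_rate)) if ig.tail_rate > 0 else NEG
        self.ig_log_1mr = float(np.log1p(-ig.tail_rate)) if 0 < ig.tail_rate < 1 else 0.0

        # masking barriers: genic segment [i, j) legal iff i >= bar_lo[j]
        gap = params.mask_gap
        self.bar_lo = np.zeros(n + 1, dtype=np.int64)
        d = np.diff(mask.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if n and mask[0]:
            starts = [0] + starts
        if n and mask[-1]:
            ends = ends + [n]
        for a, b in zip(starts, ends):
            if b - a > gap:
                self.bar_lo[a + 1] = max(self.bar_lo[a + 1], b)
        np.maximum.accumulate(self.bar_lo, out=self.bar_lo)

        # aligned in-frame stop clips per residue class
        self.last_stop_f = self._stop_clip(codes, _STOP_CODES)
        self.last_stop_r = self._stop_clip(codes, _RSTOP_CODES)

        # candidate signal positions (motif present and unmasked)
        um = ~mask
        self.Sf = self._motif3(codes, um, (0, 3, 2))
        self.Lr = np.sort(np.concatenate(
            [self._motif3(codes, um, c) for c in _RSTOP_CODES]))
        self.Rr = self._motif3(codes, um, (1, 0, 3)) + 3
        t_list = [self._motif3(codes, um, c) + 3 for c in _STOP_CODES]
        self.Tf = np.sort(np.concatenate(t_list))
        self.Df = self._motif2(codes, um, (2, 3))
        self.Af = self._motif2(codes, um, (0, 2)) + 2
        self.Dr = self._motif2(codes, um, (1, 3))
        self.Ar = self._motif2(codes, um, (0, 1)) + 2
        self.Af = self.Af[self.Af <= n - 1]
        self.Ar = self.Ar[self.Ar <= n - 1]

        self._site_scores()

    @staticmethod
    def _motif3(codes, um, pat):
        n = codes.shape[0]
        if n < 3:
            return np.zeros(0, dtype=np.int64)
        hit = (codes[:-2] == pat[0]) & (codes[1:-1] == pat[1]) & (codes[2:] == pat[2])
        hit &= um[:-2] & um[1:-1] & um[2:]
        return np.flatnonzero(hit).astype(np.int64)

    @staticmethod
    def _motif2(codes, um, pat):
        n = codes.shape[0]
        if n < 2:
            return np.zeros(0, dtype=np.int64)
        hit = (codes[:-1] == pat[0]) & (codes[1:] == pat[1]) & um[:-1] & um[1:]
        return np.flatnonzero(hit).astype(np.int64)

    def _stop_clip(self, codes, patterns):
        """last_stop[m][p] = max aligned codon start y (y%3==m, y+3<=p), -1 if none."""
        n = codes.shape[0]
        out = np.full((3, n + 1), -1, dtype=np.int64)
        if n < 3:
            return out
        hit = np.zeros(n - 2, dtype=bool)
        for pat in patterns:
            hit |= (codes[:-2] == pat[0]) & (codes[1:-1] == pat[1]) & (codes[2:] == pat[2])
        ys = np.flatnonzero(hit)
        for m in range(3):
            sel = ys[ys % 3 == m]
            row = out[m]
            row[sel + 3] = sel
            np.maximum.accumulate(row, out=row)
        return out

    def _gather(self, anchors, lo_off, length, rc=False):
        pad = 40
        padded = np.full(self.n + 2 * pad, 4, dtype=np.int8)
        padded[pad:pad + self.n] = self.codes
        idx = (anchors[:, None] + lo_off + pad) + np.arange(length)[None, :]
        mat = padded[idx]
        if rc:
            mat = np.where(mat == 4, 4, 3 - mat)[:, ::-1]
        return np.ascontiguousarray(mat)

    def _rng_sum(self, arr, lo, hi, g=None):
        """Vectorised prefix-range sum with uniform fill outside the contig."""
        lo = np.asarray(lo)
        hi = np.asarray(hi)
        lo_c = np.clip(lo, 0, self.n)
        hi_c = np.clip(hi, 0, self.n)
        s = arr[g, hi_c] - arr[g, lo_c] if g is not None else arr[hi_c] - arr[lo_c]
        return s + LOG_UNIFORM * ((lo_c - lo) + (hi - hi_c))

    def _site_scores(self):
        """Per-candidate site scores as log-odds: the positional weight model
        over the window minus the chain emission the window replaces (coding
        part in the adjacent exon's frame, non-coding part on the intron or
        intergenic side).  With this convention every base is effectively
        emitted exactly once, by its signal model where one applies."""
        p = self.params
        w = p.windows
        da, db = w["donor"]
        aa, ab = w["acceptor"]
        sa, sb = w["start"]
        ta, tb = w["stop"]
        Ld, La, Ls, Lt = da + db, aa + ab, sa + 3 + sb, ta + tb

        def phased(kind, mat):
            out = np.zeros((3, mat.shape[0]))
            for ph in range(3):
                out[ph] = p.site_model(kind, ph).score_batch(mat)
            return out

        s, t = self.Sf, self.Tf
        d, e = self.Df, self.Af
        self.sS = (p.site_model("start").score_batch(self._gather(s, -sa, Ls))
                   - self._rng_sum(self.cnf, s - sa, s)
                   - self._rng_sum(self.cf, s, s + 3 + sb, g=(-s) % 3))
        self.sT = (p.site_model("stop").score_batch(self._gather(t, -ta, Lt))
                   - self._rng_sum(self.cf, t - ta, t, g=(-t) % 3)
                   - self._rng_sum(self.cnf, t, t + tb))
        self.sD = phased("donor", self._gather(d, -da, Ld))
        self.sA = phased("acceptor", self._gather(e, -aa, La))
        for ph in range(3):
            self.sD[ph] -= (self._rng_sum(self.cf, d - da, d, g=(ph - d) % 3)
                            + self._rng_sum(self.cnf, d, d + db))
            self.sA[ph] -= (self._rng_sum(self.cnf, e - aa, e)
                            + self._rng_sum(self.cf, e, e + ab, g=(ph - e) % 3))
        # reverse strand: windows mirrored and reverse-complemented; the
        # intergenic-facing parts replace forward non-coding emission, the
        # intron-facing parts reverse non-coding, exon parts phased reverse
        L, R = self.Lr, self.Rr
        dr, er = self.Dr, self.Ar
        self.sL = (p.site_model("stop").score_batch(self._gather(L, -tb, Lt, rc=True))
                   - self._rng_sum(self.cnf, L - tb, L)
                   - self._rng_sum(self.cr, L, L + ta, g=(L - 1) % 3))
        self.sR = (p.site_model("start").score_batch(
                       self._gather(R, -(3 + sb), Ls, rc=True))
                   - self._rng_sum(self.cr, R - 3 - sb, R, g=(R - 1) % 3)
                   - self._rng_sum(self.cnf, R, R + sa))
        self.sDr = phased("acceptor", self._gather(dr, -ab, La, rc=True))
        self.sAr = phased("donor", self._gather(er, -db, Ld, rc=True))
        for ph in range(3):
            self.sDr[ph] -= (self._rng_sum(self.cr, dr - ab, dr, g=(ph + dr - 1) % 3)
                             + self._rng_sum(self.cnr, dr, dr + aa))
            self.sAr[ph] -= (self._rng_sum(self.cnr, er - db, er)
                             + self._rng_sum(self.cr, er, er + da, g=(er + ph - 1) % 3))

    def site_value(self, kind, strand, anchor, phase=None):
        """Exact per-candidate site log-odds as used by the decoder; None when
        the anchor is not a candidate (non-canonical or masked motif)."""
        table = {("start", "+"): (self.Sf, self.sS),
                 ("stop", "+"): (self.Tf, self.sT),
                 ("donor", "+"): (self.Df, self.sD),
                 ("acceptor", "+"): (self.Af, self.sA),
                 ("start", "-"): (self.Rr, self.sR),
                 ("stop", "-"): (self.Lr, self.sL),
                 ("donor", "-"): (self.Ar, self.sAr),
                 ("acceptor", "-"): (self.Dr, self.sDr)}
        cands, vals = table[(kind, strand)]
        i = int(np.searchsorted(cands, anchor))
        if i >= len(cands) or cands[i] != anchor:
            return None
        return float(vals[phase, i]) if vals.ndim == 2 else float(vals[i])

    # -- pieces reused by score_parse ------------------------------------

    def exon_emission(self, i, j, strand, entry_cp):
        """Sum of coding emissions over [i, j).  ``entry_cp`` is the codon
        position of the transcript-first base of the segment (base i on
        '+', base j-1 on '-')."""
        if strand == "+":
            g = (entry_cp - i) % 3
            return float(self.cf[g, j] - self.cf[g, i])
        g = (entry_cp + j - 1) % 3
        return float(self.cr[g, j] - self.cr[g, i])

    def noncoding_emission(self, i, j, strand):
        c = self.cnf if strand != "-" else self.cnr
        return float(c[j] - c[i])

    def ig_survival(self, d):
        if d <= self.dmax["intergenic"]:
            return float(self.ig_sf[d])
        if self.ig_log_r <= NEG / 2:
            return NEG
        return self.ig_tail_logmass + (d - self.dmax["intergenic"] - 1) * self.ig_log_r

    def ig_logpmf(self, d):
        if d <= self.dmax["intergenic"]:
            return float(self.dur["intergenic"][d])
        if self.ig_log_r <= NEG / 2 or self.ig_tail_logmass <= NEG / 2:
            return NEG
        return (self.ig_tail_logmass + self.ig_log_1mr
                + (d - self.dmax["intergenic"] - 1) * self.ig_log_r)

    def genic_logpmf(self, kind, d):
        if d < self.dmin[kind] or d > self.dmax[kind]:
            return NEG
        return float(self.dur[kind][d])


# ---------------------------------------------------------------------------
# Normative parse scoring


def _run_to_exons(run):
    """Validate one gene run's segment pattern; return exon segments."""
    strand = run[0].strand
    if any(s.strand != strand for s in run):
        return None
    kinds = [s.kind for s in run]
    if kinds == ["single_exon"]:
        return [run[0]]
    if len(kinds) < 3 or len(kinds) % 2 == 0:
        return None
    if strand == "+":
        want_first, want_last = "initial_exon", "terminal_exon"
    else:
        want_first, want_last = "terminal_exon", "initial_exon"
    if kinds[0] != want_first or kinds[-1] != want_last:
        return None
    for x, k in enumerate(kinds):
        if x % 2 == 1:
            if k != "intron":
                return None
        elif x not in (0, len(kinds) - 1) and k != "internal_exon":
            return None
    return [s for s in run if s.kind != "intron"]


def score_parse(params: HSMMParameters, contig: Contig, segments,
                scorer: SequenceScorer | None = None) -> float:
    """Total log score of a parse; ``-inf``-like NEG when illegal.

    Legality: the segments tile the contig, gene runs follow the grammar,
    CDS length is divisible by 3 with no internal in-frame stop (including
    codons split by introns), signals are canonical and unmasked when
    ``canonical_only``, genic segments respect duration bounds and do not
    overlap long masked runs.
    """
    if scorer is None:
        scorer = SequenceScorer(params, contig)
    n = scorer.n
    segs = sorted(segments, key=lambda s: s.start)
    if not segs and n > 0:
        return NEG
    # tiling
    at = 0
    for s in segs:
        if s.start != at or s.end <= s.start or s.end > n:
            return NEG
        at = s.end
    if at != n:
        return NEG
    for a, b in zip(segs, segs[1:]):
        if a.kind == "intergenic" and b.kind == "intergenic":
            return NEG

    total = 0.0
    t = params.transitions
    lp_single = np.log(t["p_single"])
    lp_multi = np.log1p(-t["p_single"])
    lp_cont = np.log(t["p_cont"])
    lp_term = np.log1p(-t["p_cont"])
    lp_str = {"+": np.log(t["p_strand_fwd"]), "-": np.log1p(-t["p_strand_fwd"])}
    seq = contig.seq
    mask = scorer.mask

    # intergenic segments
    for x, s in enumerate(segs):
        if s.kind != "intergenic":
            continue
        total += scorer.noncoding_emission(s.start, s.end, "+")
        if s.start == 0:
            total += scorer.ig_survival(s.length)
        elif s.end == n:
            total += scorer.ig_survival(s.length)
        else:
            total += scorer.ig_logpmf(s.length)

    # gene runs
    runs = Parse(contig.id, segs, 0.0).gene_runs()
    for run in runs:
        exon_segs = _run_to_exons(run)
        if exon_segs is None:
            return NEG
        strand = run[0].strand
        exons = [(s.start, s.end) for s in sorted(exon_segs, key=lambda s: s.start)]
        intron_segs = [s for s in run if s.kind == "intron"]
        cds_len = sum(b - a for a, b in exons)
        if cds_len % 3 != 0:
            return NEG
        cds = "".join(seq[a:b] for a, b in exons)
        if strand == "-":
            cds = revcomp(cds)
        if params.canonical_only:
            if cds[:3] != "ATG" or cds[-3:] not in ("TAA", "TAG", "TGA"):
                return NEG
        codons = [cds[x:x + 3] for x in range(0, len(cds) - 3, 3)]
        if any(c in ("TAA", "TAG", "TGA") for c in codons):
            return NEG
        # signal motifs must be unmasked; introns canonical
        if strand == "+":
            s0, t1 = exons[0][0], exons[-1][1]
            if mask[s0:s0 + 3].any() or mask[t1 - 3:t1].any():
                return NEG
        else:
            L, R = exons[0][0], exons[-1][1]
            if mask[L:L + 3].any() or mask[R - 3:R].any():
                return NEG
        for a, b in ((s.start, s.end) for s in intron_segs):
            if params.canonical_only:
                if strand == "+" and (seq[a:a + 2] != "GT" or seq[b - 2:b] != "AG"):
                    return NEG
                if strand == "-" and (seq[a:a + 2] != "CT" or seq[b - 2:b] != "AC"):
                    return NEG
            if mask[a:a + 2].any() or mask[b - 2:b].any():
                return NEG

        # durations, barriers, emissions
        for s in run:
            if s.start < scorer.bar_lo[s.end]:
                return NEG
            if s.kind == "intron":
                lp = scorer.genic_logpmf("intron", s.length)
                if lp <= NEG / 2:
                    return NEG
                total += lp + scorer.noncoding_emission(s.start, s.end, strand)
            else:
                lp = scorer.genic_logpmf(s.kind, s.length)
                if lp <= NEG / 2:
                    return NEG
                total += lp

        tx_exons = exons if strand == "+" else exons[::-1]
        cum = 0
        phases = []
        for a, b in tx_exons:
            cp = cum % 3
            if strand == "+":
                total += scorer.exon_emission(a, b, "+", cp)
            else:
                total += scorer.exon_emission(a, b, "-", cp)
            cum += b - a
            phases.append(cum % 3)
        # sites: exact per-candidate log-odds shared with the decoder
        if strand == "+":
            site_terms = [("start", "+", exons[0][0], None),
                          ("stop", "+", exons[-1][1], None)]
        else:
            site_terms = [("start", "-", exons[-1][1], None),
                          ("stop", "-", exons[0][0], None)]
        tx_introns = [(s.start, s.end) for s in intron_segs]
        if strand == "-":
            tx_introns = tx_introns[::-1]
        for k_i, (a, b) in enumerate(tx_introns):
            ph = phases[k_i]
            if strand == "+":
                site_terms += [("donor", "+", a, ph), ("acceptor", "+", b, ph)]
            else:
                site_terms += [("donor", "-", b, ph), ("acceptor", "-", a, ph)]
        for kind, st, anchor, ph in site_terms:
            v = scorer.site_value(kind, st, anchor, ph)
            if v is None:
                return NEG
            total += v
        # transitions
        total += lp_str[strand]
        n_int = len(intron_segs)
        if n_int == 0:
            total += lp_single
        else:
            total += lp_multi + (n_int - 1) * lp_cont + lp_term
    return float(total)


# ---------------------------------------------------------------------------
# Viterbi decoding


def _empty_int(x=0):
    return np.zeros(x, dtype=np.int64)


def viterbi_parse(params: HSMMParameters, contig: Contig,
                  strand_mode: str = "both", constraints=None,
                  scorer: SequenceScorer | None = None) -> Parse:
    """Highest-scoring parse of a contig.

    ``strand_mode='forward_only'`` disables the reverse-strand shadow
    states.  ``constraints`` (a list of JunctionEvidence) forces listed
    junctions to appear as introns where jointly feasible, by reward; the
    returned score is always re-derived with ``score_parse`` so rewards
    never leak into reported scores.
    """
    if strand_mode not in ("both", "forward_only"):
        raise ValueError(strand_mode)
    if len(contig) == 0:
        return Parse(contig.id, [], 0.0)
    sc = scorer if scorer is not None else SequenceScorer(params, contig)
    n = sc.n
    t = params.transitions

    fpar = np.array([
        np.log(t["p_single"]), np.log1p(-t["p_single"]),
        np.log(t["p_cont"]), np.log1p(-t["p_cont"]),
        np.log(t["p_strand_fwd"]), np.log1p(-t["p_strand_fwd"]),
        sc.ig_tail_logmass, sc.ig_log_r, sc.ig_log_1mr, 1.0e9])
    ipar = np.array([
        n, sc.dmin["intron"], sc.dmax["intron"],
        sc.dmin["initial_exon"], sc.dmax["initial_exon"],
        sc.dmin["internal_exon"], sc.dmax["internal_exon"],
        sc.dmin["terminal_exon"], sc.dmax["terminal_exon"],
        sc.dmin["single_exon"], sc.dmax["single_exon"],
        sc.dmin["intergenic"], sc.dmax["intergenic"]], dtype=np.int64)

    Sf, Df, Af, Tf = sc.Sf, sc.Df, sc.Af, sc.Tf
    Lr, Dr, Ar, Rr = sc.Lr, sc.Dr, sc.Ar, sc.Rr
    sS, sD, sA, sT = sc.sS, sc.sD, sc.sA, sc.sT
    sL, sDr, sAr, sR = sc.sL, sc.sDr, sc.sAr, sc.sR
    if strand_mode == "forward_only":
        Lr = Dr = Ar = Rr = _empty_int()
        sL = np.zeros(0)
        sR = np.zeros(0)
        sDr = np.zeros((3, 0))
        sAr = np.zeros((3, 0))

    conSf = conEf = conSr = conEr = _empty_int()
    if constraints:
        fw = sorted((j.start, j.end) for j in constraints if j.strand == "+")
        rv = sorted((j.start, j.end) for j in constraints if j.strand == "-")
        fw = sorted(fw, key=lambda x: x[1])
        rv = sorted(rv, key=lambda x: x[1])
        if fw:
            conSf = np.array([a for a, _ in fw], dtype=np.int64)
            conEf = np.array([b for _, b in fw], dtype=np.int64)
        if rv:
            conSr = np.array([a for a, _ in rv], dtype=np.int64)
            conEr = np.array([b for _, b in rv], dtype=np.int64)

    ns, nd, na, nt = len(Sf), len(Df), len(Af), len(Tf)
    nl, ndr, nar, nr = len(Lr), len(Dr), len(Ar), len(Rr)

    def f1(x):
        return np.full(x, NEG)

    def f3(x):
        return np.full((3, x), NEG)

    vStart, cStart, bStart = f1(ns), np.zeros(ns, np.int32), np.full(ns, -1, np.int32)
    vIF = f3(nd)
    cIF = np.zeros((3, nd), np.int32)
    bIFt = np.full((3, nd), -1, np.int8)
    bIFi = np.full((3, nd), -1, np.int32)
    bIFp = np.zeros((3, nd), np.int8)
    vAF = f3(na)
    cAF = np.zeros((3, na), np.int32)
    bAF = np.full((3, na), -1, np.int32)
    vT, cT = f1(nt), np.zeros(nt, np.int32)
    bTt = np.full(nt, -1, np.int8)
    bTi = np.full(nt, -1, np.int32)
    bTp = np.zeros(nt, np.int8)
    vRS, cRS, bRS = f1(nl), np.zeros(nl, np.int32), np.full(nl, -1, np.int32)
    vIR = f3(ndr)
    cIR = np.zeros((3, ndr), np.int32)
    bIRt = np.full((3, ndr), -1, np.int8)
    bIRi = np.full((3, ndr), -1, np.int32)
    bIRq = np.zeros((3, ndr), np.int8)
    vAR = f3(nar)
    cAR = np.zeros((3, nar), np.int32)
    bAR = np.full((3, nar), -1, np.int32)
    vR, cR = f1(nr), np.zeros(nr, np.int32)
    bRt = np.full(nr, -1, np.int8)
    bRi = np.full(nr, -1, np.int32)
    bRq = np.zeros(nr, np.int8)
    n_end_max = nt + nr + 1
    end_pos = np.zeros(n_end_max, np.int64)
    end_val = np.zeros(n_end_max)
    end_cnt = np.zeros(n_end_max, np.int32)
    end_kind = np.zeros(n_end_max, np.int8)
    end_idx = np.full(n_end_max, -1, np.int32)

    m_end = _dp.sweep(
        ipar, fpar, sc.codes,
        sc.cf, sc.cr, sc.cnf, sc.cnr, sc.bar_lo, sc.last_stop_f, sc.last_stop_r,
        sc.dur["intron"], sc.dur["initial_exon"], sc.dur["internal_exon"],
        sc.dur["terminal_exon"], sc.dur["single_exon"], sc.dur["intergenic"],
        sc.ig_sf,
        Sf, Df, Af, Tf, Lr, Dr, Ar, Rr,
        sS, sD, sA, sT, sL, sDr, sAr, sR,
        conSf, conEf, conSr, conEr,
        vStart, cStart, bStart,
        vIF, cIF, bIFt, bIFi, bIFp,
        vAF, cAF, bAF,
        vT, cT, bTt, bTi, bTp,
        vRS, cRS, bRS,
        vIR, cIR, bIRt, bIRi, bIRq,
        vAR, cAR, bAR,
        vR, cR, bRt, bRi, bRq,
        end_pos, end_val, end_cnt, end_kind, end_idx)

    # final selection: trailing intergenic by survival for every gene end
    # (the origin sentinel yields the all-intergenic parse)
    best = NEG
    bcnt = 0
    bk = 0
    for k in range(m_end):
        tpos = int(end_pos[k])
        v = end_val[k] + (sc.cnf[n] - sc.cnf[tpos]) + sc.ig_survival(n - tpos)
        c = int(end_cnt[k]) + (1 if tpos < n else 0)
        if v > best or (v == best and c < bcnt):
            best = v
            bcnt = c
            bk = k

    segs: list[Segment] = []
    k = bk
    if end_pos[k] < n:
        segs.append(Segment("intergenic", ".", int(end_pos[k]), n))
    while k != 0:
        if end_kind[k] == 1:
            ti = int(end_idx[k])
            tpos = int(Tf[ti])
            if bTt[ti] == 0:
                si = int(bTi[ti])
                s = int(Sf[si])
                segs.append(Segment("single_exon", "+", s, tpos, 0))
                gs = s
                k2 = int(bStart[si])
            else:
                ai, p = int(bTi[ti]), int(bTp[ti])
                e = int(Af[ai])
                segs.append(Segment("terminal_exon", "+", e, tpos, p))
                while True:
                    di = int(bAF[p, ai])
                    dpos = int(Df[di])
                    segs.append(Segment("intron", "+", dpos, e, p))
                    if bIFt[p, di] == 0:
                        si = int(bIFi[p, di])
                        s = int(Sf[si])
                        segs.append(Segment("initial_exon", "+", s, dpos, 0))
                        gs = s
                        k2 = int(bStart[si])
                        break
                    ai2, p2 = int(bIFi[p, di]), int(bIFp[p, di])
                    e2 = int(Af[ai2])
                    segs.append(Segment("internal_exon", "+", e2, dpos, p2))
                    ai, p, e = ai2, p2, e2
        else:
            ri = int(end_idx[k])
            R = int(Rr[ri])
            if bRt[ri] == 0:
                li = int(bRi[ri])
                L = int(Lr[li])
                segs.append(Segment("single_exon", "-", L, R, 0))
                gs = L
                k2 = int(bRS[li])
            else:
                ari, q = int(bRi[ri]), int(bRq[ri])
                e = int(Ar[ari])
                segs.append(Segment("initial_exon", "-", e, R, 0))
                while True:
                    dri = int(bAR[q, ari])
                    dpos = int(Dr[dri])
                    segs.append(Segment("intron", "-", dpos, e, (3 - q) % 3))
                    if bIRt[q, dri] == 0:
                        li = int(bIRi[q, dri])
                        L = int(Lr[li])
                        segs.append(Segment("terminal_exon", "-", L, dpos, (3 - q) % 3))
                        gs = L
                        k2 = int(bRS[li])
                        break
                    ari2, q2 = int(bIRi[q, dri]), int(bIRq[q, dri])
                    e2 = int(Ar[ari2])
                    segs.append(Segment("internal_exon", "-", e2, dpos, (3 - q) % 3))
                    ari, q, e = ari2, q2, e2
        if end_pos[k2] < gs:
            segs.append(Segment("intergenic", ".", int(end_pos[k2]), gs))
        k = k2
    segs.reverse()

    score = score_parse(params, contig, segs, scorer=sc)
    parse = Parse(contig.id, segs, score)
    if constraints:
        introns = {(s.start, s.end, s.strand) for s in segs if s.kind == "intron"}
        parse.satisfied_constraints = [
            j for j in constraints if (j.start, j.end, j.strand) in introns]
    return parse


# ---------------------------------------------------------------------------
# Exhaustive oracle


def brute_force_parse(params: HSMMParameters, contig: Contig,
                      max_len: int = 150) -> Parse:
    """Enumerate every grammar-legal segmentation of a short contig and
    return the arg-max under ``score_parse``, with the same tie-break rule
    as the dynamic program (score, then fewer segments, then earliest
    boundaries)."""
    n = len(contig)
    if n > max_len:
        raise ValueError(f"contig length {n} exceeds max_len {max_len}")
    scorer = SequenceScorer(params, contig)
    genes = _enumerate_genes(params, contig)
    genes.sort(key=lambda g: (g[0][0].start, g[0][-1].end))
    min_ig = params.durations["intergenic"].min_len

    best = [None, NEG, 0, None]

    def consider(segments):
        sc = score_parse(params, contig, segments, scorer=scorer)
        if sc <= NEG / 2:
            return
        nseg = len(segments)
        bounds = tuple((s.start, s.end, s.kind, s.strand) for s in
                       sorted(segments, key=lambda x: x.start))
        if (sc > best[1]
                or (sc == best[1] and nseg < best[2])
                or (sc == best[1] and nseg == best[2] and bounds < best[3])):
            best[0], best[1], best[2], best[3] = list(segments), sc, nseg, bounds

    def build(chosen):
        segs = []
        at = 0
        for run in chosen:
            gs = run[0].start
            if gs > at:
                segs.append(Segment("intergenic", ".", at, gs))
            segs.extend(run)
            at = run[-1].end
        if at < n:
            segs.append(Segment("intergenic", ".", at, n))
        consider(segs)

    def place(start_idx, at, chosen):
        build(chosen)
        for gi in range(start_idx, len(genes)):
            run = genes[gi][0]
            gs = run[0].start
            if gs < at:
                continue
            gap = gs - at
            if at > 0 and 0 < gap < min_ig:
                continue
            if at > 0 and gap == 0:
                continue
            chosen.append(run)
            place(gi + 1, run[-1].end, chosen)
            chosen.pop()

    place(0, 0, [])
    if best[0] is None:
        segs = [Segment("intergenic", ".", 0, n)] if n else []
        return Parse(contig.id, segs, score_parse(params, contig, segs, scorer=scorer))
    return Parse(contig.id, sorted(best[0], key=lambda s: s.start), best[1])


def _enumerate_genes(params, contig):
    """All candidate gene segment-runs on both strands (legality is decided
    later by score_parse; enumeration only respects candidate motifs,
    duration windows and segment ordering)."""
    out = []
    n = len(contig)
    for strand in ("+", "-"):
        if strand == "+":
            c = contig
        else:
            c = Contig(contig.id, revcomp(contig.seq),
                       np.asarray(contig.mask, bool)[::-1].copy())
        sc = SequenceScorer(params, c)
        runs = _enumerate_forward(params, sc)
        if strand == "+":
            out.extend([(r,) for r in runs])
        else:
            for r in runs:
                mapped = []
                for s in reversed(r):
                    mapped.append(Segment(s.kind, "-", n - s.end, n - s.start, s.phase))
                out.append((mapped,))
    return out


def _enumerate_forward(params, sc):
    """Forward-strand gene runs on the given (possibly reverse-complemented)
    scorer's sequence."""
    runs = []
    mins, maxs = sc.dmin, sc.dmax
    Ss, Ds, As, Ts = sc.Sf, sc.Df, sc.Af, sc.Tf
    max_exons = 8

    def extend(exon_start, kindnext, segs):
        if len(segs) > 2 * max_exons:
            return
        first = not segs
        # close with a stop (single or terminal exon)
        kind_end = "single_exon" if first else "terminal_exon"
        for t in Ts:
            d = t - exon_start
            if d < mins[kind_end] or d > maxs[kind_end]:
                continue
            runs.append(segs + [Segment(kind_end, "+", exon_start, int(t), 0)])
        # close at a donor and open an intron
        kind_ex = "initial_exon" if first else "internal_exon"
        for dpos in Ds:
            dd = dpos - exon_start
            if dd < mins[kind_ex] or dd > maxs[kind_ex]:
                continue
            ex = Segment(kind_ex, "+", exon_start, int(dpos), 0)
            for e in As:
                di = e - dpos
                if di < mins["intron"] or di > maxs["intron"]:
                    continue
                extend(int(e), None,
                       segs + [ex, Segment("intron", "+", int(dpos), int(e), 0)])

    for s in Ss:
        extend(int(s), None, [])
    return runs


# ---------------------------------------------------------------------------


def parse_to_genes(parse: Parse) -> list[GeneStructure]:
    """One GeneStructure per maximal gene run, ids assigned in genomic order."""
    genes = []
    for i, run in enumerate(parse.gene_runs(), 1):
        strand = run[0].strand
        exons = [(s.start, s.end) for s in run if s.kind != "intron"]
        gid = f"{parse.contig_id}_g{i}"
        genes.append(GeneStructure(parse.contig_id, strand, exons, id=gid))
    return genes
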