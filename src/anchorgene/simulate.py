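"""Synthetic genomes with planted gene structures and noisy junction evidence.

The generator samples a state path from the gene grammar under a known
HSMMParameters set, emits bases from the corresponding Markov chains,
plants signal windows from the site models (with canonical GT/AG, ATG and
stop consensus forced) and inserts soft-masked repeat runs into intergenic
regions.  Junction evidence is derived from the planted introns with a
configurable detection rate plus false junctions placed on GT..AG-bearing
non-intron loci, so that they are not trivially filterable by motif.

Two named profiles ship with the package: ``compact`` emulates a
fruit-fly-like gene-dense genome (short introns, moderate intergenic
regions, light repeat content); ``large`` emulates a repeat-heavy mosquito-
like regime with long intergenic regions and ~40% of intergenic sequence
masked, where purely unsupervised training is expected to struggle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .io_formats import Contig, GeneStructure, GenomeSequence, JunctionEvidence, revcomp
from .model import (DEFAULT_WINDOWS, DurationModel, HSMMParameters,
                    MarkovChainModel, SiteModel)

__all__ = ["SimulationProfile", "simulate_genome", "simulate_junctions",
           "compact_profile", "large_profile", "make_true_params"]

_BASES = "ACGT"
_STOP_DIST = {"TAA": 0.45, "TAG": 0.30, "TGA": 0.25}


# ---------------------------------------------------------------------------
# Generating parameter sets


def _positive(p: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Mix with uniform so log probabilities stay finite for decoding."""
    p = np.asarray(p, dtype=float)
    p = p / p.sum(axis=-1, keepdims=True)
    p = (1 - eps) * p + eps * 0.25
    return p / p.sum(axis=-1, keepdims=True)


def _codon_usage(p1, p2, p3) -> np.ndarray:
    """(4,4,4) codon frequencies = product composition, stops removed."""
    u = np.einsum("i,j,k->ijk", p1, p2, p3)
    for c in ((3, 0, 0), (3, 0, 2), (3, 2, 0)):  # TAA TAG TGA
        u[c] = 0.0
    return u / u.sum()

def _coding_chain(usage: np.ndarray) -> MarkovChainModel:
    """Order-2 three-periodic chain whose stationary codon statistics match
    the usage table (adjacent codons independent)."""
    logp = np.zeros((3, 16, 4))
    p1 = usage.sum(axis=(1, 2))
    p2_given_1 = usage.sum(axis=2) / np.maximum(usage.sum(axis=(1, 2))[:, None], 1e-12)
    p3_given_12 = usage / np.maximum(usage.sum(axis=2)[:, :, None], 1e-12)
    for ctx in range(16):
        b_prev, b_cur = divmod(ctx, 4)
        logp[0, ctx] = np.log(_positive(p1))
        logp[1, ctx] = np.log(_positive(p2_given_1[b_cur]))
        logp[2, ctx] = np.log(_positive(p3_given_12[b_prev, b_cur]))
    return MarkovChainModel(2, 3, logp)


def _noncoding_chain(at_rich: float = 0.60) -> MarkovChainModel:
    """Order-2 homogeneous background with CpG depletion."""
    base = np.array([at_rich / 2, (1 - at_rich) / 2, (1 - at_rich) / 2, at_rich / 2])
    logp = np.zeros((1, 16, 4))
    for ctx in range(16):
        prev = ctx % 4
        p = base.copy()
        if prev == 1:          # context ...C -> deplete G (CpG)
            p[2] *= 0.45
        if prev == 3:          # ...T -> slight A enrichment (TA-rich spacers)
            p[0] *= 1.2
        logp[0, ctx] = np.log(_positive(p))
    return MarkovChainModel(2, 1, logp)


def _pwm(rows) -> np.ndarray:
    return np.log(_positive(np.asarray(rows, dtype=float)))


def _true_sites() -> dict[str, SiteModel]:
    """Hand-specified realistic signal models (consensus MAG|GTAAGT donor,
    pyrimidine-tract acceptor, Kozak-like start context)."""
    w = DEFAULT_WINDOWS
    donor = _pwm([
        [.30, .15, .35, .20], [.55, .10, .20, .15], [.10, .05, .75, .10],  # exonic MAG
        [.00, .00, 1.0, .00], [.00, .00, .00, 1.0],                        # GT
        [.55, .05, .30, .10], [.70, .08, .12, .10], [.10, .08, .70, .12],
        [.18, .12, .20, .50]])
    py = [.08, .35, .07, .50]
    acceptor = _pwm(
        [[.22, .25, .13, .40]] * 6 + [py] * 8 +
        [[.10, .35, .05, .50], [.25, .30, .05, .40],
         [1.0, .00, .00, .00], [.00, .00, 1.0, .00],                        # AG
         [.28, .18, .40, .14], [.25, .22, .28, .25], [.24, .26, .25, .25]])
    start = _pwm(
        [[.30, .20, .25, .25], [.35, .20, .20, .25], [.45, .15, .25, .15],
         [.40, .25, .20, .15], [.30, .30, .25, .15], [.22, .33, .25, .20],
         [1.0, .00, .00, .00], [.00, .00, .00, 1.0], [.00, .00, 1.0, .00],  # ATG
         [.25, .20, .40, .15], [.30, .25, .25, .20], [.20, .30, .30, .20]])
    stop = _pwm(
        [[.00, .00, .00, 1.0], [.75, .00, .25, .00], [.60, .00, .40, .00],  # stop codon
         [.30, .20, .25, .25], [.35, .15, .25, .25], [.30, .20, .25, .25],
         [.25, .25, .25, .25], [.25, .25, .25, .25], [.25, .25, .25, .25]])
    return {
        "donor": SiteModel("donor", w["donor"], 0, donor),
        "acceptor": SiteModel("acceptor", w["acceptor"], 0, acceptor),
        "start": SiteModel("start", w["start"], 0, start),
        "stop": SiteModel("stop", w["stop"], 0, stop),
    }


def _gamma_duration(kind, mean, sd, l_max, min_len) -> DurationModel:
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    d = np.arange(l_max + 1, dtype=float)
    pdf = stats.gamma.pdf(d, a=shape, scale=scale)
    pdf[:min_len] = 0.0
    tail_mass = float(stats.gamma.sf(l_max, a=shape, scale=scale))
    tail_mass = min(max(tail_mass, 1e-9), 0.2)
    pdf = pdf / pdf.sum() * (1.0 - tail_mass)
    with np.errstate(divide="ignore"):
        logpmf = np.log(np.maximum(pdf, 1e-300))
    logpmf[:min_len] = -np.inf
    tail_rate = 1.0 - 1.0 / max(sd, 2.0)
    return DurationModel(kind, min_len, l_max, logpmf, tail_mass, tail_rate)


def make_true_params(regime: str = "compact") -> HSMMParameters:
    """Generating model for the named simulation regime."""
    usage = _codon_usage(
        p1=np.array([.28, .18, .32, .22]),
        p2=np.array([.30, .22, .18, .30]),
        p3=np.array([.22, .28, .26, .24]))
    coding = _coding_chain(usage)
    noncoding = _noncoding_chain(0.60)
    if regime == "compact":
        durations = {
            "initial_exon": _gamma_duration("initial_exon", 300, 150, 5000, 30),
            "internal_exon": _gamma_duration("internal_exon", 350, 175, 5000, 30),
            "terminal_exon": _gamma_duration("terminal_exon", 450, 200, 5000, 30),
            "single_exon": _gamma_duration("single_exon", 1200, 400, 5000, 300),
            "intron": _gamma_duration("intron", 150, 75, 10_000, 40),
            "intergenic": _gamma_duration("intergenic", 4200, 2500, 20_000, 200),
        }
    elif regime == "large":
        durations = {
            "initial_exon": _gamma_duration("initial_exon", 300, 150, 5000, 30),
            "internal_exon": _gamma_duration("internal_exon", 350, 175, 5000, 30),
            "terminal_exon": _gamma_duration("terminal_exon", 450, 200, 5000, 30),
            "single_exon": _gamma_duration("single_exon", 1200, 400, 5000, 300),
            "intron": _gamma_duration("intron", 400, 300, 10_000, 40),
            "intergenic": _gamma_duration("intergenic", 12_000, 6000, 20_000, 400),
        }
    else:
        raise ValueError(f"unknown regime {regime}")
    return HSMMParameters(
        coding=coding, noncoding=noncoding, sites=_true_sites(),
        durations=durations,
        transitions={"p_single": 0.2, "p_cont": 2 / 3, "p_strand_fwd": 0.5},
        provenance={"all": "synthetic-truth"})


@dataclass
class SimulationProfile:
    name: str
    genome_length: int
    gene_count: int            # indicative target under the duration means
    params: HSMMParameters
    repeat_fraction: float = 0.0       # of intergenic sequence, soft-masked
    repeat_len_mean: float = 400.0
    gene_probability: float = 1.0      # gene follows an intergenic stretch
    detection_rate: float = 0.8
    fp_rate: float = 0.1
    support: str = "score"             # score | coverage
    seed: int = 0

    def __post_init__(self):
        for r in (self.repeat_fraction, self.gene_probability,
                  self.detection_rate, self.fp_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")


def compact_profile(**kw) -> SimulationProfile:
    return SimulationProfile(
        name="compact", genome_length=2_000_000, gene_count=300,
        params=make_true_params("compact"), repeat_fraction=0.05,
        repeat_len_mean=400.0, detection_rate=0.8, fp_rate=0.1,
        support="score", **kw)


def large_profile(**kw) -> SimulationProfile:
    return SimulationProfile(
        name="large", genome_length=500_000, gene_count=33,
        params=make_true_params("large"), repeat_fraction=0.40,
        repeat_len_mean=1500.0, detection_rate=0.8, fp_rate=0.1,
        support="coverage", **kw)


# ---------------------------------------------------------------------------
# Sequence sampling


class _ChainSampler:
    def __init__(self, model: MarkovChainModel, rng):
        self.k = model.order
        self.P = model.periodicity
        self.cum = np.cumsum(np.exp(model.logp), axis=2)
        self.rng = rng
        self.nctx = 4 ** self.k

    def sample(self, length: int, frame_offset: int = 0, context: str = "") -> str:
        ctx = 0
        for ch in context[-self.k:] if self.k else "":
            ctx = (ctx * 4 + _BASES.index(ch)) % self.nctx
        u = self.rng.random(length)
        out = []
        for i in range(length):
            f = (frame_offset + i) % self.P
            row = self.cum[f, ctx]
            b = int(np.searchsorted(row, u[i] * row[-1]))
            b = min(b, 3)
            out.append(_BASES[b])
            if self.k:
                ctx = (ctx * 4 + b) % self.nctx
        return "".join(out)


def _sample_pwm(site: SiteModel, rng, lo=None, hi=None) -> str:
    p = np.exp(site.logp)
    lo = 0 if lo is None else lo
    hi = site.length if hi is None else hi
    out = []
    for i in range(lo, hi):
        out.append(_BASES[rng.choice(4, p=p[i] / p[i].sum())])
    return "".join(out)


def _force(s: str, at: int, motif: str) -> str:
    return s[:at] + motif + s[at + len(motif):]


def _sample_cds(rng, sampler: _ChainSampler, length: int) -> str:
    """Stop-free CDS of the given length (multiple of 3): ATG ... stop."""
    assert length % 3 == 0 and length >= 9
    codons = ["ATG"]
    ctx = "TG"
    for _ in range(length // 3 - 2):
        for _try in range(60):
            c = sampler.sample(3, frame_offset=0, context=ctx)
            if c not in ("TAA", "TAG", "TGA"):
                break
        codons.append(c)
        ctx = c[1:]
    stops, probs = zip(*_STOP_DIST.items())
    codons.append(stops[rng.choice(len(stops), p=np.array(probs) / sum(probs))])
    return "".join(codons)


def _build_gene(rng, params: HSMMParameters, strand: str):
    """One gene block in genomic orientation: (block_seq, exon_offsets,
    flank_up_len).  The block includes 6 nt of signal context on each side
    (part of the neighbouring intergenic sequence)."""
    t = params.transitions
    cod = _ChainSampler(params.coding, rng)
    ncs = _ChainSampler(params.noncoding, rng)
    d_site = params.sites["donor"]
    a_site = params.sites["acceptor"]
    s_site = params.sites["start"]
    t_site = params.sites["stop"]
    da, db = d_site.window
    aa, ab = a_site.window

    for _attempt in range(80):
        if rng.random() < t["p_single"]:
            roles = ["single_exon"]
        else:
            n_int = int(rng.geometric(1.0 - t["p_cont"]))
            roles = (["initial_exon"] + ["internal_exon"] * (n_int - 1)
                     + ["terminal_exon"])
        ex_lens = [int(params.durations[r].sample(rng)[0]) for r in roles]
        rem = (3 - sum(ex_lens) % 3) % 3
        ex_lens[-1] += rem
        total = sum(ex_lens)
        if total < 9:
            continue
        in_lens = [int(params.durations["intron"].sample(rng)[0])
                   for _ in range(len(roles) - 1)]
        in_lens = [max(x, da + db + aa + ab + 4) for x in in_lens]

        cds = _sample_cds(rng, cod, total)
        exs = []
        off = 0
        for L in ex_lens:
            exs.append(cds[off:off + L])
            off += L
        # plant donor/acceptor windows (exonic parts overwrite exon edges)
        introns = []
        for i, Li in enumerate(in_lens):
            don = _force(_sample_pwm(d_site, rng), da, "GT")
            acc = _force(_sample_pwm(a_site, rng), aa - 2, "AG")
            exs[i] = exs[i][:-da] + don[:da]
            mid = ncs.sample(Li - db - aa)
            introns.append(don[da:] + mid + acc[:aa])
            exs[i + 1] = acc[aa:] + exs[i + 1][ab:]
        pieces = []
        for i, e in enumerate(exs):
            pieces.append(e)
            if i < len(introns):
                pieces.append(introns[i])
        # re-derive CDS after overlays and validate
        cds2 = "".join(exs)
        codons = [cds2[x:x + 3] for x in range(0, len(cds2), 3)]
        if cds2[:3] != "ATG" or codons[-1] not in _STOP_DIST:
            continue
        if any(c in _STOP_DIST for c in codons[:-1]):
            continue
        up = _sample_pwm(s_site, rng, 0, 6)
        down = _sample_pwm(t_site, rng, 3, 9)
        body = "".join(pieces)
        block = up + body + down
        # exon offsets within the block (genomic-forward orientation so far)
        at = 6
        offs = []
        for idx, piece in enumerate(pieces):
            if idx % 2 == 0:
                offs.append((at, at + len(piece)))
            at += len(piece)
        if strand == "-":
            B = len(block)
            block = revcomp(block)
            offs = [(B - b, B - a) for a, b in offs][::-1]
        return block, offs
    raise RuntimeError("gene simulation failed to produce a valid structure")


def _mask_intergenic(rng, length: int, fraction: float, mean_len: float,
                     margin: int = 30):
    """Masked-run intervals inside an intergenic stretch of given length."""
    runs = []
    if fraction <= 0 or length < 2 * margin + 120:
        return runs
    target = fraction * length
    masked = 0
    for _ in range(200):
        if masked >= target:
            break
        run = int(min(max(rng.exponential(mean_len), 100), length - 2 * margin))
        a = int(rng.integers(margin, max(length - margin - run, margin) + 1))
        runs.append((a, a + run))
        masked += run
    return runs


def simulate_genome(profile: SimulationProfile, seed: int | None = None,
                    contig_id: str = "chr1"):
    """Sample one contig and its true annotation from the profile."""
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    params = profile.params
    n_target = profile.genome_length
    min_ig = params.durations["intergenic"].min_len
    chunks: list[str] = []
    mask_ivs: list[tuple[int, int]] = []
    genes: list[GeneStructure] = []
    ncs = _ChainSampler(params.noncoding, rng)
    pos = 0
    gi = 0
    while pos < n_target:
        lg = int(params.durations["intergenic"].sample(rng)[0])
        lg = max(lg, min_ig + 12)
        lg = min(lg, n_target - pos) if pos + lg > n_target else lg
        ig_seq = ncs.sample(lg)
        for a, b in _mask_intergenic(rng, lg, profile.repeat_fraction,
                                     profile.repeat_len_mean):
            mask_ivs.append((pos + a, min(pos + b, pos + lg)))
        chunks.append(ig_seq)
        pos += lg
        if pos >= n_target or rng.random() >= profile.gene_probability:
            continue
        strand = "+" if rng.random() < params.transitions["p_strand_fwd"] else "-"
        block, offs = _build_gene(rng, params, strand)
        if pos + len(block) + min_ig > n_target:
            continue
        exons = [(pos + a, pos + b) for a, b in offs]
        gi += 1
        genes.append(GeneStructure(contig_id, strand, exons,
                                   id=f"{contig_id}_t{gi}", gene_id=f"{contig_id}_g{gi}"))
        chunks.append(block)
        pos += len(block)
    seq = "".join(chunks)[:max(n_target, 0)]
    mask = np.zeros(len(seq), dtype=bool)
    for a, b in mask_ivs:
        mask[a:min(b, len(seq))] = True
    genome = GenomeSequence()
    genome.add(Contig(contig_id, seq, mask))
    genes = [g for g in genes if g.exons[-1][1] <= len(seq)]
    return genome, genes


# ---------------------------------------------------------------------------
# Junction evidence


def _support(rng, profile, true_intron: bool):
    if profile.support == "score":
        if true_intron:
            s = float(np.clip(rng.beta(5.0, 1.5), 0.01, 0.99))
        else:
            s = float(np.clip(rng.beta(1.5, 4.0), 0.01, 0.99))
        return {"score": s}
    cov = 1 + int(rng.poisson(8.0 if true_intron else 1.0))
    return {"coverage": cov}


def simulate_junctions(truth: list[GeneStructure], profile: SimulationProfile,
                       genome: GenomeSequence, seed: int | None = None
                       ) -> list[JunctionEvidence]:
    """Evidence for the planted introns at the profile's detection rate,
    plus false junctions on random GT..AG (or CT..AC) loci."""
    rng = np.random.default_rng(
        (profile.seed if seed is None else seed) + 777)
    true_keys = set()
    out = []
    for g in truth:
        for a, b in g.introns:
            true_keys.add((g.contig_id, a, b, g.strand))
            if rng.random() < profile.detection_rate:
                out.append(JunctionEvidence(g.contig_id, a, b, g.strand,
                                            **_support(rng, profile, True)))
    n_fp = int(round(profile.fp_rate * len(out)))
    dur = profile.params.durations["intron"]
    emitted = {j.key for j in out}
    for c in genome:
        seq = c.seq
        n = len(seq)
        made = 0
        tries = 0
        while made < n_fp and tries < n_fp * 200 + 200:
            tries += 1
            strand = "+" if rng.random() < 0.5 else "-"
            start_motif, end_motif = (("GT", "AG") if strand == "+"
                                      else ("CT", "AC"))
            p = int(rng.integers(0, max(n - 100, 1)))
            if seq[p:p + 2] != start_motif:
                continue
            want = int(dur.sample(rng)[0])
            lo = max(p + dur.min_len, p + 26)
            hi = min(p + want + 60, n)
            e_found = -1
            for e in range(min(p + want, hi), lo, -1):
                if seq[e - 2:e] == end_motif:
                    e_found = e
                    break
            if e_found < 0:
                continue
            key = (c.id, p, e_found, strand)
            if key in true_keys or key in emitted:
                continue
            emitted.add(key)
            out.append(JunctionEvidence(c.id, p, e_found, strand,
                                        **_support(rng, profile, False)))
            made += 1
        break  # single-contig genomes; FP budget spent on the first contig
    return out
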