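"""The generative hidden semi-Markov model and its estimation primitives.

The genome is modelled as an alternation of intergenic regions and genes;
genes are chains of coding exons separated by introns.  Hidden states emit
variable-length segments: coding segments from a three-periodic Markov
chain, introns and intergenic regions from a homogeneous non-coding chain,
with explicit duration distributions per element kind.  Boundary signals
(donor, acceptor, translation initiation and termination) carry positional
weight models over fixed windows; donor/acceptor models may be split into
three phased sub-models once enough training instances per intron phase
accumulate.

All probabilities live in natural-log space; every estimated distribution
uses additive pseudocounts so it stays strictly positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .io_formats import GenomeSequence, JunctionEvidence, revcomp

__all__ = [
    "MarkovChainModel",
    "SiteModel",
    "DurationModel",
    "HSMMParameters",
    "estimate_markov",
    "estimate_site_model",
    "estimate_duration",
    "score_coding",
    "score_noncoding",
    "score_site",
    "heuristic_init",
    "DEFAULT_WINDOWS",
    "ELEMENT_KINDS",
    "encode",
]

LOG_UNIFORM = float(np.log(0.25))
ELEMENT_KINDS = ("initial_exon", "internal_exon", "terminal_exon",
                 "single_exon", "intron", "intergenic")

# (a, b) is window geometry around the signal anchor; see site_window().
DEFAULT_WINDOWS = {
    "donor": (3, 6),       # exonic, intronic
    "acceptor": (18, 3),   # intronic, exonic
    "start": (6, 3),       # upstream, downstream-of-ATG
    "stop": (3, 6),        # codon, downstream
}

DEFAULT_LMAX = {"initial_exon": 5000, "internal_exon": 5000, "terminal_exon": 5000,
                "single_exon": 5000, "intron": 10_000, "intergenic": 20_000}
DEFAULT_MIN = {"initial_exon": 6, "internal_exon": 15, "terminal_exon": 6,
               "single_exon": 60, "intron": 30, "intergenic": 50}

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Map an uppercase sequence to int8 codes A=0 C=1 G=2 T=3, other=4."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def window_len(kind: str, windows=None) -> int:
    a, b = (windows or DEFAULT_WINDOWS)[kind]
    if kind == "donor" or kind == "acceptor":
        return a + b
    if kind == "start":
        return a + 3 + b
    return a + b  # stop: codon + downstream


def site_window(seq: str, kind: str, strand: str, anchor: int, windows=None) -> str:
    """Extract the signal window in transcript orientation, N-padded at edges.

    Anchor semantics (all 0-based genomic):
      donor    '+': first intron base;          '-': intron end (exclusive)
      acceptor '+': first exon base after intron; '-': intron start
      start    '+': the A of ATG;               '-': genomic pos of the A
      stop     '+': CDS end (exclusive);        '-': CDS genomic start
    """
    w = windows or DEFAULT_WINDOWS
    a, b = w[kind]
    if kind == "donor":
        lo, hi = (anchor - a, anchor + b) if strand == "+" else (anchor - b, anchor + a)
    elif kind == "acceptor":
        lo, hi = (anchor - a, anchor + b) if strand == "+" else (anchor - b, anchor + a)
    elif kind == "start":
        lo, hi = (anchor - a, anchor + 3 + b) if strand == "+" else (anchor - 2 - b, anchor + 1 + a)
    elif kind == "stop":
        lo, hi = (anchor - a, anchor + b) if strand == "+" else (anchor - b, anchor + a)
    else:
        raise ValueError(kind)
    n = len(seq)
    chunk = "".join(seq[i] if 0 <= i < n else "N" for i in range(lo, hi))
    return chunk if strand == "+" else revcomp(chunk)


# ---------------------------------------------------------------------------
# Markov chain emission models


@dataclass
class MarkovChainModel:
    """Fixed-order Markov chain, homogeneous or three-periodic.

    ``logp`` has shape (periodicity, 4**order, 4): conditional log
    probabilities of the next base given the preceding ``order`` bases and,
    for periodicity 3, the codon position of the emitted base.
    """

    order: int
    periodicity: int
    logp: np.ndarray

    def __post_init__(self) -> None:
        expect = (self.periodicity, 4 ** self.order, 4)
        if self.logp.shape != expect:
            raise ValueError(f"logp shape {self.logp.shape} != {expect}")

    @classmethod
    def uniform(cls, order: int, periodicity: int) -> "MarkovChainModel":
        return cls(order, periodicity,
                   np.full((periodicity, 4 ** order, 4), LOG_UNIFORM))

    def prob_tables(self) -> np.ndarray:
        return np.exp(self.logp)

    def score(self, seq: str, frame_offset: int = 0, context: str = "") -> float:
        """Log probability of ``seq``; ``frame_offset`` is the codon position
        of its first base.  Positions whose full context (within
        ``context + seq``) is unavailable or contains non-ACGT symbols are
        scored as uniform 0.25, as are N bases."""
        full = encode(context + seq)
        c0 = len(context)
        k = self.order
        total = 0.0
        for i in range(c0, len(full)):
            b = full[i]
            if b == 4 or i < k or np.any(full[i - k:i] == 4):
                total += LOG_UNIFORM
                continue
            ctx = 0
            for j in range(i - k, i):
                ctx = ctx * 4 + int(full[j])
            f = (frame_offset + (i - c0)) % self.periodicity
            total += float(self.logp[f, ctx, b])
        return total


def estimate_markov(seqs, order: int, periodicity: int = 1,
                    pseudocount: float = 1.0) -> MarkovChainModel:
    """Maximum-likelihood Markov chain with additive pseudocounts.

    ``seqs`` is an iterable of ``(sequence, frame_offset)`` pairs (the frame
    offset is the codon position of the first base; ignored for
    periodicity 1).  Counting honours each sequence's frame and skips any
    window containing a non-ACGT symbol.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    counts = np.zeros((periodicity, 4 ** order, 4))
    any_data = False
    for item in seqs:
        seq, off = item if isinstance(item, tuple) else (item, 0)
        codes = encode(seq)
        n = len(codes)
        if n <= order:
            continue
        any_data = True
        ctx = np.zeros(n - order, dtype=np.int64)
        ok = codes[order:] != 4
        for j in range(order):
            c = codes[j:n - order + j]
            ctx = ctx * 4 + np.where(c == 4, 0, c)
            ok &= c != 4
        pos = np.arange(order, n)
        frames = (off + pos) % periodicity
        b = codes[order:]
        np.add.at(counts, (frames[ok], ctx[ok], b[ok]), 1.0)
    if not any_data:
        warnings.warn("estimate_markov: empty input, returning uniform model")
        return MarkovChainModel.uniform(order, periodicity)
    counts += pseudocount
    if pseudocount == 0:
        counts[counts.sum(axis=2) == 0] = 0.25  # keep rows normalisable
    with np.errstate(divide="ignore"):
        logp = np.log(counts / counts.sum(axis=2, keepdims=True))
    return MarkovChainModel(order, periodicity, logp)


def score_coding(model: MarkovChainModel, seq: str, frame_offset: int = 0,
                 context: str = "") -> float:
    """Log probability of a coding fragment under the three-periodic chain."""
    return model.score(seq, frame_offset=frame_offset, context=context)


def score_noncoding(model: MarkovChainModel, seq: str, context: str = "") -> float:
    return model.score(seq, context=context)


# ---------------------------------------------------------------------------
# Site (signal) models


@dataclass
class SiteModel:
    """Positional weight model over a fixed window around one signal kind.

    order 0 is a plain PWM (``logp`` shape (L, 4)); order 1 is a weight
    array model conditioning each position on its predecessor (``logp``
    shape (L, 4, 4), position 0 uses the marginal ``logp0``).
    """

    site_kind: str
    window: tuple[int, int]
    order: int
    logp: np.ndarray
    logp0: np.ndarray | None = None  # order-1 only: marginal at position 0
    phase_variant: str = "frameless"

    @property
    def length(self) -> int:
        return self.logp.shape[0]

    @classmethod
    def uniform(cls, kind: str, windows=None, order: int = 0,
                phase_variant: str = "frameless") -> "SiteModel":
        L = window_len(kind, windows)
        w = (windows or DEFAULT_WINDOWS)[kind]
        if order == 0:
            return cls(kind, w, 0, np.full((L, 4), LOG_UNIFORM),
                       phase_variant=phase_variant)
        return cls(kind, w, 1, np.full((L, 4, 4), LOG_UNIFORM),
                   logp0=np.full(4, LOG_UNIFORM), phase_variant=phase_variant)

    def score(self, window: str) -> float:
        codes = encode(window)
        if len(codes) != self.length:
            raise ValueError(
                f"{self.site_kind}: window length {len(codes)} != model {self.length}")
        tot = 0.0
        if self.order == 0:
            for i, b in enumerate(codes):
                tot += LOG_UNIFORM if b == 4 else float(self.logp[i, b])
        else:
            b0 = codes[0]
            tot += LOG_UNIFORM if b0 == 4 else float(self.logp0[b0])
            for i in range(1, len(codes)):
                a, b = codes[i - 1], codes[i]
                tot += LOG_UNIFORM if (a == 4 or b == 4) else float(self.logp[i, a, b])
        return tot

    def score_batch(self, wins: np.ndarray) -> np.ndarray:
        """Vectorised scoring of an (n, L) int8 code matrix."""
        n, L = wins.shape
        if L != self.length:
            raise ValueError("window length mismatch")
        out = np.zeros(n)
        if self.order == 0:
            table = np.hstack([self.logp, np.full((L, 1), LOG_UNIFORM)])
            for i in range(L):
                out += table[i, wins[:, i]]
        else:
            t0 = np.append(self.logp0, LOG_UNIFORM)
            out += t0[wins[:, 0]]
            for i in range(1, L):
                tab = np.full((5, 5), LOG_UNIFORM)
                tab[:4, :4] = self.logp[i]
                out += tab[wins[:, i - 1], wins[:, i]]
        return out


def estimate_site_model(instances, kind: str, phase_variant: str = "frameless",
                        order: int = 0, pseudocount: float = 1.0,
                        windows=None) -> SiteModel:
    """Per-position (order 0) or first-order conditional frequencies from
    aligned signal windows."""
    instances = list(instances)
    w = (windows or DEFAULT_WINDOWS)[kind]
    L = window_len(kind, windows)
    if not instances:
        warnings.warn(f"estimate_site_model({kind}): no instances, uniform model")
        return SiteModel.uniform(kind, windows, order, phase_variant)
    lens = {len(s) for s in instances}
    if lens != {L}:
        raise ValueError(f"{kind}: windows of unequal/wrong length {sorted(lens)} != {L}")
    mat = np.stack([encode(s) for s in instances])
    if order == 0:
        counts = np.full((L, 4), pseudocount, dtype=float)
        for b in range(4):
            counts[:, b] += (mat == b).sum(axis=0)
        if pseudocount == 0:
            counts[counts.sum(axis=1) == 0] = 0.25
        logp = np.log(counts / counts.sum(axis=1, keepdims=True))
        return SiteModel(kind, w, 0, logp, phase_variant=phase_variant)
    c0 = np.full(4, pseudocount, dtype=float)
    for b in range(4):
        c0[b] += (mat[:, 0] == b).sum()
    counts = np.full((L, 4, 4), pseudocount, dtype=float)
    for i in range(1, L):
        prev, cur = mat[:, i - 1], mat[:, i]
        ok = (prev != 4) & (cur != 4)
        np.add.at(counts[i], (prev[ok], cur[ok]), 1.0)
    logp = np.log(counts / np.maximum(counts.sum(axis=2, keepdims=True), 1e-300))
    logp0 = np.log(c0 / c0.sum())
    return SiteModel(kind, w, 1, logp, logp0=logp0, phase_variant=phase_variant)


def score_site(site_model: SiteModel, window: str) -> float:
    return site_model.score(window)


# ---------------------------------------------------------------------------
# Duration models


@dataclass
class DurationModel:
    """Length distribution of one element kind.

    Smoothed empirical histogram on ``min_len..l_max`` carrying mass
    ``1 - tail_mass``; a geometric tail beyond ``l_max`` carries
    ``tail_mass`` with excess-success rate ``tail_rate``:
    ``P(d) = tail_mass * (1 - r) * r**(d - l_max - 1)`` for ``d > l_max``.
    """

    element_kind: str
    min_len: int
    l_max: int
    logpmf: np.ndarray  # length l_max + 1, index = duration, -inf below min_len
    tail_mass: float
    tail_rate: float

    def __post_init__(self) -> None:
        if self.logpmf.shape != (self.l_max + 1,):
            raise ValueError("logpmf must have length l_max + 1")

    def log_prob(self, d: int) -> float:
        """Log pmf including the geometric tail."""
        if d <= self.l_max:
            return float(self.logpmf[d]) if d >= self.min_len else -np.inf
        if self.tail_mass <= 0 or self.tail_rate <= 0:
            return -np.inf
        return (np.log(self.tail_mass) + np.log1p(-self.tail_rate)
                + (d - self.l_max - 1) * np.log(self.tail_rate))

    def log_sf(self, d: int) -> float:
        """Log P(D >= d) -- used for contig-edge segments."""
        if d <= self.min_len:
            return 0.0
        body = np.exp(self.logpmf[max(self.min_len, 0):self.l_max + 1])
        if d <= self.l_max:
            s = body[d - self.min_len:].sum() + self.tail_mass
            return float(np.log(max(s, 1e-300)))
        if self.tail_mass <= 0 or self.tail_rate <= 0:
            return -np.inf
        return float(np.log(self.tail_mass) + (d - self.l_max - 1) * np.log(self.tail_rate))

    def mean(self) -> float:
        d = np.arange(self.min_len, self.l_max + 1)
        p = np.exp(self.logpmf[self.min_len:])
        m = float((d * p).sum())
        if self.tail_mass > 0 and self.tail_rate < 1:
            m += self.tail_mass * (self.l_max + 1 / (1 - self.tail_rate))
        return m

    def total_mass(self) -> float:
        return float(np.exp(self.logpmf[self.min_len:]).sum() + self.tail_mass)

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw lengths from the full distribution (body plus tail)."""
        body = np.exp(self.logpmf[self.min_len:])
        body_total = body.sum()
        out = np.empty(size, dtype=np.int64)
        pick_tail = rng.random(size) >= body_total / (body_total + self.tail_mass)
        n_body = int(np.sum(~pick_tail))
        if n_body:
            out[~pick_tail] = self.min_len + rng.choice(
                body.shape[0], size=n_body, p=body / body_total)
        n_tail = size - n_body
        if n_tail:
            out[pick_tail] = self.l_max + rng.geometric(
                max(1.0 - self.tail_rate, 1e-9), size=n_tail)
        return out


def estimate_duration(lengths, kind: str, smoothing_bandwidth: float = 5.0,
                      l_max: int | None = None, min_floor: int | None = None,
                      pseudocount: float = 0.1) -> DurationModel:
    """Kernel-smoothed histogram on 1..l_max with a geometric tail fitted to
    the mean excess beyond l_max.  The minimum length is the smaller of the
    configured floor and the shortest observation."""
    from scipy.ndimage import gaussian_filter1d

    l_max = l_max if l_max is not None else DEFAULT_LMAX[kind]
    floor = min_floor if min_floor is not None else DEFAULT_MIN[kind]
    lengths = np.asarray(list(lengths), dtype=np.int64)
    if lengths.size == 0:
        warnings.warn(f"estimate_duration({kind}): empty input, uniform model")
        pmf = np.full(l_max + 1, -np.inf)
        m = max(floor, 1)
        pmf[m:] = np.log(1.0 / (l_max + 1 - m))
        return DurationModel(kind, m, l_max, pmf, 0.0, 0.0)
    if np.any(lengths <= 0):
        raise ValueError("durations must be positive")
    min_len = int(min(floor, lengths.min()))
    body = lengths[lengths <= l_max]
    excess = lengths[lengths > l_max] - l_max
    hist = np.zeros(l_max + 1)
    np.add.at(hist, body, 1.0)
    if smoothing_bandwidth > 0:
        hist = gaussian_filter1d(hist, smoothing_bandwidth, mode="constant")
    hist[:min_len] = 0.0
    hist[min_len:] += pseudocount / (l_max + 1 - min_len)
    n = lengths.size
    tail_mass = excess.size / n
    body_mass = 1.0 - tail_mass
    hist *= body_mass / hist.sum()
    mean_excess = float(excess.mean()) if excess.size else max(float(lengths.mean()), 2.0)
    tail_rate = max(0.0, 1.0 - 1.0 / max(mean_excess, 1.0 + 1e-9))
    with np.errstate(divide="ignore"):
        logpmf = np.log(hist)
    logpmf[:min_len] = -np.inf
    return DurationModel(kind, min_len, l_max, logpmf, float(tail_mass), float(tail_rate))


def geometric_duration(kind: str, mean: float, l_max: int | None = None,
                       min_floor: int | None = None) -> DurationModel:
    """Uninformed prior: discretised exponential with the given mean."""
    l_max = l_max if l_max is not None else DEFAULT_LMAX[kind]
    m = min_floor if min_floor is not None else DEFAULT_MIN[kind]
    d = np.arange(l_max + 1, dtype=float)
    r = 1.0 - 1.0 / max(mean, m + 1.0)
    w = np.where(d >= m, (d - m) * np.log(r), -np.inf)
    tail_mass = float(np.exp((l_max + 1 - m) * np.log(r)))
    body = np.exp(w)
    body *= (1.0 - tail_mass) / body.sum()
    with np.errstate(divide="ignore"):
        logpmf = np.log(body)
    return DurationModel(kind, m, l_max, logpmf, tail_mass, r)


# ---------------------------------------------------------------------------
# Full parameter set


@dataclass
class HSMMParameters:
    """Complete generative model of the gene-structure HSMM."""

    coding: MarkovChainModel
    noncoding: MarkovChainModel
    sites: dict[str, SiteModel]
    durations: dict[str, DurationModel]
    transitions: dict[str, float]
    windows: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS))
    canonical_only: bool = True
    mask_gap: int = 50
    iteration_index: int = 0
    provenance: dict[str, str] = field(default_factory=dict)

    def site_model(self, kind: str, phase: int | None = None) -> SiteModel:
        """Phased sub-model when available, else the frameless model."""
        if phase is not None:
            key = f"{kind}_phase{phase}"
            if key in self.sites:
                return self.sites[key]
        return self.sites[kind]

    def transition_distributions(self) -> list[dict[str, float]]:
        t = self.transitions
        return [
            {"single": t["p_single"], "multi": 1.0 - t["p_single"]},
            {"internal": t["p_cont"], "terminal": 1.0 - t["p_cont"]},
            {"forward": t["p_strand_fwd"], "reverse": 1.0 - t["p_strand_fwd"]},
        ]

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        def mc(m):
            return {"order": m.order, "periodicity": m.periodicity,
                    "logp": m.logp.tolist()}

        doc = {
            "format": "anchorgene-model",
            "version": 1,
            "iteration_index": self.iteration_index,
            "canonical_only": self.canonical_only,
            "mask_gap": self.mask_gap,
            "provenance": dict(self.provenance),
            "windows": {k: list(v) for k, v in self.windows.items()},
            "transitions": {k: float(v) for k, v in self.transitions.items()},
            "coding": mc(self.coding),
            "noncoding": mc(self.noncoding),
            "sites": {
                key: {
                    "site_kind": s.site_kind, "window": list(s.window),
                    "order": s.order, "phase_variant": s.phase_variant,
                    "logp": s.logp.tolist(),
                    "logp0": None if s.logp0 is None else s.logp0.tolist(),
                } for key, s in self.sites.items()},
            "durations": {
                k: {"min_len": d.min_len, "l_max": d.l_max,
                    "tail_mass": d.tail_mass, "tail_rate": d.tail_rate,
                    "logpmf": np.where(np.isfinite(d.logpmf), d.logpmf, None).tolist()}
                for k, d in self.durations.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, default_flow_style=None)

    @classmethod
    def load(cls, path) -> "HSMMParameters":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if doc.get("format") != "anchorgene-model":
            raise ValueError(f"{path}: not an anchorgene model file")

        def mc(d):
            return MarkovChainModel(d["order"], d["periodicity"], np.asarray(d["logp"]))

        sites = {}
        for key, s in doc["sites"].items():
            sites[key] = SiteModel(
                s["site_kind"], tuple(s["window"]), s["order"],
                np.asarray(s["logp"]),
                None if s["logp0"] is None else np.asarray(s["logp0"]),
                s["phase_variant"])
        durs = {}
        for k, d in doc["durations"].items():
            pmf = np.array([-np.inf if x is None else x for x in d["logpmf"]])
            durs[k] = DurationModel(k, d["min_len"], d["l_max"], pmf,
                                    d["tail_mass"], d["tail_rate"])
        return cls(
            coding=mc(doc["coding"]), noncoding=mc(doc["noncoding"]),
            sites=sites, durations=durs,
            transitions=doc["transitions"],
            windows={k: tuple(v) for k, v in doc["windows"].items()},
            canonical_only=doc["canonical_only"], mask_gap=doc["mask_gap"],
            iteration_index=doc["iteration_index"],
            provenance=doc.get("provenance", {}))


# ---------------------------------------------------------------------------
# Heuristic initialization

# Codon-position nucleotide composition anchors at 30 / 50 / 70 % genome GC.
# Positional GC rises steeply at codon position 3 and mildly at position 1;
# position 1 carries a purine (A/G) excess.  Values interpolate linearly.
_GC_ANCHORS = np.array([0.30, 0.50, 0.70])
_POS_GC = {
    0: np.array([0.42, 0.52, 0.62]),
    1: np.array([0.35, 0.41, 0.47]),
    2: np.array([0.25, 0.55, 0.85]),
}
_POS_PURINE_SPLIT = {0: 0.60, 1: 0.50, 2: 0.50}  # A share of AT, G share of GC


def heuristic_coding_model(gc: float) -> MarkovChainModel:
    """Order-0 three-periodic coding chain from genome GC via anchor
    interpolation (exact at the 30/50/70% anchor points)."""
    logp = np.zeros((3, 1, 4))
    for pos in range(3):
        g = float(np.interp(gc, _GC_ANCHORS, _POS_GC[pos]))
        sp = _POS_PURINE_SPLIT[pos]
        at = 1.0 - g
        p = np.array([at * sp, g * (1 - sp), g * sp, at * (1 - sp)])  # A C G T
        logp[pos, 0] = np.log(p / p.sum())
    return MarkovChainModel(0, 3, logp)


def heuristic_noncoding_model(gc: float) -> MarkovChainModel:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return MarkovChainModel(0, 1, np.log(p).reshape(1, 1, 4))


def _consensus_pwm(kind: str, windows, strong: float = 0.997) -> SiteModel:
    """Near-uniform PWM with the canonical consensus pinned.

    start: ATG at codon positions; stop: T then A/G composition of the three
    stop codons; donor: GT at intron positions 1-2; acceptor: AG at intron
    end."""
    L = window_len(kind, windows)
    a, b = (windows or DEFAULT_WINDOWS)[kind]
    p = np.full((L, 4), 0.25)

    def pin(i, dist):
        v = np.asarray(dist, dtype=float)
        v = v / v.sum()
        p[i] = v * strong + (1 - strong) * 0.25

    if kind == "start":
        pin(a, [1, 0, 0, 0]); pin(a + 1, [0, 0, 0, 1]); pin(a + 2, [0, 0, 1, 0])
    elif kind == "stop":
        pin(0, [0, 0, 0, 1])          # T
        pin(1, [2 / 3, 0, 1 / 3, 0])  # A or G
        pin(2, [2 / 3, 0, 1 / 3, 0])  # A or G (TAA/TAG/TGA composition)
    elif kind == "donor":
        pin(a, [0, 0, 1, 0]); pin(a + 1, [0, 0, 0, 1])  # GT
    elif kind == "acceptor":
        pin(a - 2, [1, 0, 0, 0]); pin(a - 1, [0, 0, 1, 0])  # AG
    return SiteModel(kind, (a, b), 0, np.log(p))


DEFAULT_TRANSITIONS = {"p_single": 0.2, "p_cont": 0.7, "p_strand_fwd": 0.5}
PRIOR_DURATION_MEANS = {"initial_exon": 300.0, "internal_exon": 300.0,
                        "terminal_exon": 400.0, "single_exon": 1200.0,
                        "intron": 200.0, "intergenic": 3000.0}


def heuristic_init(genome: GenomeSequence, hc_introns: list[JunctionEvidence],
                   windows=None, l_max=None, min_len=None,
                   smoothing_bandwidth: float = 5.0) -> HSMMParameters:
    """Initial parameter set before any prediction exists.

    Coding/non-coding chains come from the GC-dependent heuristic mapping;
    donor/acceptor models and the intron length distribution are estimated
    from the high-confidence mapped introns (their genomic flanks and
    lengths); everything else is an uninformed prior.  With no
    high-confidence introns the splice models fall back to consensus-pinned
    priors (the fully unsupervised start).
    """
    if len(genome) == 0 or genome.total_length == 0:
        raise ValueError("heuristic_init: empty genome")
    windows = dict(windows or DEFAULT_WINDOWS)
    l_max = dict(l_max or DEFAULT_LMAX)
    min_len = dict(min_len or DEFAULT_MIN)
    gc = genome.gc_content
    sites: dict[str, SiteModel] = {
        "start": _consensus_pwm("start", windows),
        "stop": _consensus_pwm("stop", windows),
    }
    durations: dict[str, DurationModel] = {}
    provenance: dict[str, str] = {"coding": "heuristic", "noncoding": "heuristic",
                                  "start": "heuristic", "stop": "heuristic"}
    don, acc, lens = [], [], []
    for j in hc_introns:
        if j.contig_id not in genome.contigs:
            continue
        seq = genome[j.contig_id].seq
        d_anchor = j.start if j.strand == "+" else j.end
        a_anchor = j.end if j.strand == "+" else j.start
        don.append(site_window(seq, "donor", j.strand, d_anchor, windows))
        acc.append(site_window(seq, "acceptor", j.strand, a_anchor, windows))
        lens.append(j.length)
    if don:
        sites["donor"] = estimate_site_model(don, "donor", windows=windows)
        sites["acceptor"] = estimate_site_model(acc, "acceptor", windows=windows)
        durations["intron"] = estimate_duration(
            lens, "intron", smoothing_bandwidth, l_max["intron"], min_len["intron"])
        provenance.update(donor="high_confidence_introns",
                          acceptor="high_confidence_introns",
                          intron_duration="high_confidence_introns")
    else:
        warnings.warn("heuristic_init: no high-confidence introns; "
                      "splice-site models start from uninformed priors")
        sites["donor"] = _consensus_pwm("donor", windows)
        sites["acceptor"] = _consensus_pwm("acceptor", windows)
        durations["intron"] = geometric_duration(
            "intron", PRIOR_DURATION_MEANS["intron"], l_max["intron"], min_len["intron"])
        provenance.update(donor="heuristic", acceptor="heuristic",
                          intron_duration="heuristic")
    for kind in ELEMENT_KINDS:
        if kind == "intron":
            continue
        durations[kind] = geometric_duration(
            kind, PRIOR_DURATION_MEANS[kind], l_max[kind], min_len[kind])
    return HSMMParameters(
        coding=heuristic_coding_model(gc),
        noncoding=heuristic_noncoding_model(gc),
        sites=sites, durations=durations,
        transitions=dict(DEFAULT_TRANSITIONS),
        windows=windows, iteration_index=0, provenance=provenance)
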