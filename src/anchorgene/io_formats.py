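"""Reading and writing of external formats, plus sequence preprocessing.

All coordinates are 0-based half-open on the forward strand internally.
GFF3 (1-based inclusive) and BED are converted at this boundary and nowhere
else.  Genomes are held uppercase with a per-base boolean repeat mask that is
true wherever the input base was lowercase (soft-masked) or ``N``
(hard-masked).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "Contig",
    "GenomeSequence",
    "JunctionEvidence",
    "GeneStructure",
    "read_fasta",
    "write_fasta",
    "filter_contigs",
    "read_junctions",
    "write_junctions",
    "read_gff3",
    "write_gff3",
]

_VALID = set("ACGTN")
_STOPS = {"TAA", "TAG", "TGA"}
_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGTN string."""
    return seq.translate(_RC)[::-1]


@dataclass
class Contig:
    id: str
    seq: str  # uppercase over {A,C,G,T,N}
    mask: np.ndarray  # bool, True = repeat-masked (was lowercase or N)

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.mask):
            raise ValueError(f"contig {self.id}: seq and mask lengths differ")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeSequence:
    """A named, ordered set of contigs with per-base masking status."""

    contigs: dict[str, Contig] = field(default_factory=dict)

    def add(self, contig: Contig) -> None:
        if contig.id in self.contigs:
            raise ValueError(f"duplicate contig id: {contig.id}")
        self.contigs[contig.id] = contig

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs.values())

    def __getitem__(self, cid: str) -> Contig:
        return self.contigs[cid]

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self)

    @property
    def gc_content(self) -> float:
        """G+C fraction over unmasked, non-N bases (0.5 for an empty genome)."""
        gc = at = 0
        for c in self:
            arr = np.frombuffer(c.seq.encode(), dtype=np.uint8)
            keep = ~c.mask
            gc += int(np.sum(keep & ((arr == ord("G")) | (arr == ord("C")))))
            at += int(np.sum(keep & ((arr == ord("A")) | (arr == ord("T")))))
        tot = gc + at
        return gc / tot if tot else 0.5


@dataclass(frozen=True)
class JunctionEvidence:
    """One intron mapped from a spliced RNA-Seq read alignment.

    ``start``/``end`` delimit the intron 0-based half-open; exactly one of
    ``score`` (posterior-like, in (0,1)) or ``coverage`` (supporting read
    count) is set, uniformly per source file.
    """

    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    score: float | None = None
    coverage: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("junction start must precede end")
        if (self.score is None) == (self.coverage is None):
            raise ValueError("exactly one of score/coverage must be set")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple:
        return (self.contig_id, self.start, self.end, self.strand)


@dataclass
class GeneStructure:
    """A strand-aware CDS exon chain.

    ``exons`` are 0-based half-open intervals in genomic order (left to
    right, regardless of strand).  ``donor_anchored``/``acceptor_anchored``
    hold one flag per intron (transcript order) and are filled by the
    evidence-integration stage.
    """

    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    id: str = ""
    gene_id: str = ""
    donor_anchored: list[bool] = field(default_factory=list)
    acceptor_anchored: list[bool] = field(default_factory=list)
    mrna_exons: list[tuple[int, int]] | None = None  # incl. UTR, if known

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if a >= b:
                raise ValueError(f"gene {self.id}: empty exon {(a, b)}")
        for (_, b), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 <= b:
                raise ValueError(f"gene {self.id}: overlapping/abutting exons")
        if not self.gene_id:
            self.gene_id = self.id
        n_int = len(self.exons) - 1
        if not self.donor_anchored:
            self.donor_anchored = [False] * n_int
        if not self.acceptor_anchored:
            self.acceptor_anchored = [False] * n_int

    # -- derived geometry -------------------------------------------------

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic-order intron intervals (0-based half-open)."""
        return [(b, a2) for (_, b), (a2, _) in zip(self.exons, self.exons[1:])]

    def exons_tx(self) -> list[tuple[int, int]]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def phases(self) -> list[int]:
        """GFF3 phase per exon in transcript order."""
        out, cum = [], 0
        for a, b in self.exons_tx():
            out.append((3 - cum % 3) % 3)
            cum += b - a
        return out

    def intron_phases(self) -> list[int]:
        """Per intron (transcript order): nt of the interrupted codon 5' of it."""
        out, cum = [], 0
        exs = self.exons_tx()
        for a, b in exs[:-1]:
            cum += b - a
            out.append(cum % 3)
        return out

    @property
    def start_pos(self) -> int:
        """Genomic coordinate of the first CDS base (the A of ATG)."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    @property
    def stop_pos(self) -> int:
        """Genomic coordinate of the last CDS base (3' end of the stop codon)."""
        return self.exons[-1][1] - 1 if self.strand == "+" else self.exons[0][0]

    def cds_sequence(self, seq: str) -> str:
        s = "".join(seq[a:b] for a, b in self.exons)
        return s if self.strand == "+" else revcomp(s)

    def coordinate_key(self) -> tuple:
        return (self.contig_id, self.strand, tuple(self.exons))

    def partial_key(self) -> tuple:
        """Coordinate key with the translation-initiation boundary wildcarded."""
        exs = [list(e) for e in self.exons]
        if self.strand == "+":
            exs[0][0] = -1
        else:
            exs[-1][1] = -1
        return (self.contig_id, self.strand, tuple(tuple(e) for e in exs))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> GenomeSequence:
    """Read a (possibly soft/hard-masked) FASTA file.

    Lowercase and ``N`` bases get ``mask=True``; sequence is stored uppercase
    with ``N`` preserved.  Characters outside ACGTN are converted to ``N``.
    """
    genome = GenomeSequence()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() and not line.startswith((">", ";")):
                raise ValueError(
                    f"{path}: line {lineno}: expected FASTA header, got {line[:30]!r}")
            if line.strip():
                break
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        arr = np.frombuffer(raw.encode(), dtype=np.uint8)
        lower = (arr >= ord("a")) & (arr <= ord("z"))
        up = raw.upper()
        up = "".join(c if c in _VALID else "N" for c in up)
        arr_up = np.frombuffer(up.encode(), dtype=np.uint8)
        mask = lower | (arr_up == ord("N"))
        genome.add(Contig(rec.id, up, mask))
    return genome


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    """Write soft-masked FASTA (masked bases lowercase; N stays N)."""
    with open(path, "w") as fh:
        for c in genome:
            chars = list(c.seq)
            for i in np.flatnonzero(c.mask):
                if chars[i] != "N":
                    chars[i] = chars[i].lower()
            s = "".join(chars)
            fh.write(f">{c.id}\n")
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Contig filtering


def unmasked_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of unmasked positions as (start, end) half-open pairs."""
    if len(mask) == 0:
        return []
    um = ~mask
    d = np.diff(um.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if um[0]:
        starts = [0] + starts
    if um[-1]:
        ends = ends + [len(mask)]
    return list(zip(starts, ends))


def filter_contigs(genome: GenomeSequence, min_unmasked_run: int = 10_000):
    """Drop contigs whose longest contiguous unmasked run is below threshold.

    Returns ``(filtered_genome, report)`` where the report carries total and
    retained sequence lengths (the "sequence in training" accounting).
    """
    if min_unmasked_run < 0:
        raise ValueError("min_unmasked_run must be >= 0")
    kept = GenomeSequence()
    total = retained = 0
    for c in genome:
        total += len(c)
        longest = max((e - s for s, e in unmasked_runs(c.mask)), default=0)
        if min_unmasked_run == 0 or longest >= min_unmasked_run:
            kept.add(c)
            retained += len(c)
    report = {
        "total_contigs": len(genome),
        "retained_contigs": len(kept),
        "total_length": total,
        "retained_length": retained,
    }
    return kept, report


# ---------------------------------------------------------------------------
# Junctions


def _infer_strand(genome: GenomeSequence | None, cid: str, s: int, e: int) -> str | None:
    if genome is None or cid not in genome.contigs:
        return None
    seq = genome[cid].seq
    if seq[s:s + 2] == "GT" and seq[e - 2:e] == "AG":
        return "+"
    if seq[s:s + 2] == "CT" and seq[e - 2:e] == "AC":
        return "-"
    return None


def read_junctions(path, dialect: str, genome: GenomeSequence | None = None) -> list[JunctionEvidence]:
    """Read splice-junction evidence.

    dialect 'bed_junctions': BED12 in the TopHat junctions.bed convention —
    each line a spliced alignment whose block gaps are introns; the score
    column is the supporting read count (coverage dialect).

    dialect 'gff_introns': GFF lines with intron features taken verbatim;
    the score column is either a probabilistic score in (0,1) (score
    dialect) or a non-negative integer (coverage dialect).  A file mixing
    the two is rejected.

    Junctions without a strand are resolved from GT-AG / CT-AC intron-end
    dinucleotides when a genome is supplied; unresolvable or degenerate
    records are dropped with a warning carrying the count.
    """
    if dialect not in ("bed_junctions", "gff_introns"):
        raise ValueError(f"unknown junction dialect: {dialect}")
    out: list[JunctionEvidence] = []
    dropped = 0
    kinds = set()

    def emit(cid, s, e, strand, score=None, coverage=None):
        nonlocal dropped
        if e - s < 1:
            dropped += 1
            return
        if strand not in ("+", "-"):
            strand = _infer_strand(genome, cid, s, e)
            if strand is None:
                dropped += 1
                return
        out.append(JunctionEvidence(cid, s, e, strand, score=score, coverage=coverage))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if dialect == "bed_junctions":
                if len(f) < 12:
                    raise ValueError(f"{path}: line {lineno}: BED12 needs 12 fields")
                cid, chrom_start = f[0], int(f[1])
                cov = int(float(f[4]))
                strand = f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
                kinds.add("coverage")
                for i in range(len(sizes) - 1):
                    s = chrom_start + offs[i] + sizes[i]
                    e = chrom_start + offs[i + 1]
                    emit(cid, s, e, strand, coverage=cov)
            else:
                if len(f) < 8:
                    raise ValueError(f"{path}: line {lineno}: GFF needs >= 8 fields")
                if f[2].lower() != "intron":
                    continue
                cid = f[0]
                s, e = int(f[3]) - 1, int(f[4])  # 1-based incl -> half-open
                val = f[5]
                strand = f[6]
                if val in (".", ""):
                    raise ValueError(f"{path}: line {lineno}: intron lacks score/coverage")
                x = float(val)
                if 0.0 < x < 1.0:
                    kinds.add("score")
                    emit(cid, s, e, strand, score=x)
                elif x == int(x) and x >= 0:
                    kinds.add("coverage")
                    emit(cid, s, e, strand, coverage=int(x))
                else:
                    raise ValueError(f"{path}: line {lineno}: bad support value {val}")
    if len(kinds) > 1:
        raise ValueError(f"{path}: file mixes score and coverage dialects")
    if dropped:
        warnings.warn(f"{path}: dropped {dropped} degenerate/strandless junction records")
    return out


def write_junctions(junctions: list[JunctionEvidence], path) -> None:
    """Write junctions as GFF intron records (anchorgene's native dialect)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for j in junctions:
            val = f"{j.score:.6g}" if j.score is not None else str(j.coverage)
            fh.write(f"{j.contig_id}\tanchorgene\tintron\t{j.start + 1}\t{j.end}\t"
                     f"{val}\t{j.strand}\t.\t.\n")


# ---------------------------------------------------------------------------
# GFF3 gene structures


def read_gff3(path) -> list[GeneStructure]:
    """Read gene structures (CDS chains grouped by parent mRNA) from GFF3.

    CDS features sharing a Parent form one GeneStructure; exon features of
    the same parent populate ``mrna_exons``.  A CDS chain whose length is
    not divisible by 3 is retained with a warning (annotations are allowed
    to be imperfect).
    """
    cds: dict[str, list] = {}
    exons: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    tx2gene: dict[str, str] = {}
    orphan = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            cid, _, ftype, s, e, _, strand, _, attrs = f
            s, e = int(s) - 1, int(e)
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype in ("mRNA", "transcript"):
                tx2gene[a.get("ID", "")] = a.get("Parent", a.get("ID", ""))
            elif ftype == "CDS":
                parent = a.get("Parent") or a.get("ID")
                if parent is None:
                    orphan += 1
                    parent = f"orphan{orphan}"
                cds.setdefault(parent, []).append((s, e))
                meta[parent] = (cid, strand)
            elif ftype == "exon":
                parent = a.get("Parent", "")
                exons.setdefault(parent, []).append((s, e))
    genes = []
    bad = 0
    for parent, ivs in cds.items():
        cid, strand = meta[parent]
        g = GeneStructure(cid, strand, ivs, id=parent,
                          gene_id=tx2gene.get(parent, parent),
                          mrna_exons=sorted(exons[parent]) if parent in exons else None)
        if g.cds_length % 3 != 0:
            bad += 1
        genes.append(g)
    if bad:
        warnings.warn(f"{path}: {bad} CDS chains with length not divisible by 3 (retained)")
    genes.sort(key=lambda g: (g.contig_id, g.exons[0][0], g.id))
    return genes


def write_gff3(genes: list[GeneStructure], path) -> None:
    """Write gene/mRNA/CDS (and exon, when UTR structure is known) GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gid = g.gene_id or g.id
            tid = g.id or gid
            lo = g.exons[0][0]
            hi = g.exons[-1][1]
            if g.mrna_exons:
                lo, hi = min(lo, g.mrna_exons[0][0]), max(hi, g.mrna_exons[-1][1])
            fh.write(f"{g.contig_id}\tanchorgene\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\tID={gid}\n")
            fh.write(f"{g.contig_id}\tanchorgene\tmRNA\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                     f"ID={tid};Parent={gid}\n")
            if g.mrna_exons:
                for a, b in g.mrna_exons:
                    fh.write(f"{g.contig_id}\tanchorgene\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                             f"Parent={tid}\n")
            phases = g.phases()
            exs = g.exons_tx()
            for (a, b), ph in zip(exs, phases):
                fh.write(f"{g.contig_id}\tanchorgene\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t{ph}\t"
                         f"Parent={tid}\n")
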