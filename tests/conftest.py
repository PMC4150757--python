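"""Shared fixtures: reduced-grammar parameter sets and random contigs for
oracle cross-checks, plus small cached simulations."""

import numpy as np
import pytest
from hypothesis import settings

from anchorgene.io_formats import Contig

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from anchorgene.model import (HSMMParameters, MarkovChainModel, SiteModel,
                              geometric_duration)

REDUCED_WINDOWS = {"donor": (1, 3), "acceptor": (4, 1),
                   "start": (2, 1), "stop": (3, 2)}


def make_reduced_params(rng: np.random.Generator) -> HSMMParameters:
    """Random small-order parameter set with short duration windows, suitable
    for exhaustive enumeration of every legal parse."""
    def chain(order, period):
        p = rng.dirichlet(np.ones(4) * 1.5, size=(period, 4 ** order))
        return MarkovChainModel(order, period, np.log(p))

    def pwm(kind):
        a, b = REDUCED_WINDOWS[kind]
        L = a + 3 + b if kind == "start" else a + b
        p = rng.dirichlet(np.ones(4) * 2.0, size=L)
        return SiteModel(kind, REDUCED_WINDOWS[kind], 0, np.log(p))

    durations = {
        "initial_exon": geometric_duration("initial_exon", 10.0, 30, 4),
        "internal_exon": geometric_duration("internal_exon", 10.0, 30, 4),
        "terminal_exon": geometric_duration("terminal_exon", 10.0, 30, 4),
        "single_exon": geometric_duration("single_exon", 15.0, 45, 9),
        "intron": geometric_duration("intron", 10.0, 25, 5),
        "intergenic": geometric_duration("intergenic", 12.0, 25, 3),
    }
    return HSMMParameters(
        coding=chain(1, 3), noncoding=chain(1, 1),
        sites={k: pwm(k) for k in ("donor", "acceptor", "start", "stop")},
        durations=durations,
        transitions={"p_single": 0.35, "p_cont": 0.5,
                     "p_strand_fwd": float(rng.uniform(0.3, 0.7))},
        windows=dict(REDUCED_WINDOWS), mask_gap=6)


def make_random_contig(rng: np.random.Generator, i: int,
                       min_len: int = 40, max_len: int = 120) -> Contig:
    """Random contig; even indices get a planted forward mini-gene skeleton,
    every fifth contig gets a masked run."""
    n = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(list("ACGT"), size=n, p=[.3, .2, .2, .3]))
    if i % 2 == 0:
        s = int(rng.integers(2, 12))
        seq = seq[:s] + "ATG" + seq[s + 3:]
        d = s + 3 + int(rng.integers(4, 9))
        if d + 2 < n:
            seq = seq[:d] + "GT" + seq[d + 2:]
        a = d + int(rng.integers(5, 12))
        if a + 2 < n:
            seq = seq[:a] + "AG" + seq[a + 2:]
        t = a + 2 + int(rng.integers(4, 12))
        if t + 3 <= n:
            seq = seq[:t] + "TAA" + seq[t + 3:]
    mask = np.zeros(len(seq), dtype=bool)
    if i % 5 == 3:
        a = int(rng.integers(0, len(seq) - 10))
        mask[a:a + int(rng.integers(3, 10))] = True
    return Contig(f"c{i}", seq, mask)


@pytest.fixture(scope="session")
def small_sim():
    """A 200 kb compact-profile simulation shared across tests."""
    from dataclasses import replace
    from anchorgene.simulate import (compact_profile, simulate_genome,
                                     simulate_junctions)
    prof = replace(compact_profile(seed=42), genome_length=200_000)
    genome, truth = simulate_genome(prof)
    junctions = simulate_junctions(truth, prof, genome)
    return prof, genome, truth, junctions
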