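"""Iterative semi-supervised (ET) and unsupervised (ES) self-training.

The loop alternates Viterbi prediction over all contigs with re-estimation
of the HSMM parameters from selected predicted elements (hard, Viterbi-style
training).  In ET mode selection is restricted to elements supported by
anchor splice sites from mapped introns; in ES mode every predicted element
is eligible.  High-confidence introns seed the initial splice-site models
and intron length distribution; with fewer mapped introns than the switch
threshold the run automatically degrades to ES mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .decoder import Parse, parse_to_genes, viterbi_parse
from .evidence import (TrainingSet, anchor_splice_sites,
                       constrain_parse_with_introns, filter_high_confidence,
                       junction_dialect, select_training_elements)
from .io_formats import GenomeSequence, JunctionEvidence
from .model import (DEFAULT_LMAX, DEFAULT_MIN, DEFAULT_WINDOWS,
                    HSMMParameters, estimate_duration, estimate_markov,
                    estimate_site_model, heuristic_init)

__all__ = ["TrainingConfig", "IterationLog", "train", "check_convergence",
           "expand_phase_models", "reestimate"]


@dataclass
class TrainingConfig:
    mode: str = "auto"                    # ET | ES | auto
    max_iterations: int = 10
    es_switch_threshold: int = 1000       # mapped introns below this -> ES
    long_exon_min: int = 800
    trim: int = 60
    convergence_rule: str = "exact"       # exact | fraction
    convergence_fraction: float = 0.99
    seed: int = 0
    min_instances: int = 100              # per-phase site-model split
    constraint_decoding: bool = False
    coding_order: int = 5
    noncoding_order: int = 5
    site_order: int = 0
    smoothing_bandwidth: float = 5.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("ET", "ES", "auto"):
            raise ValueError(f"unknown mode {self.mode}")
        for name in ("max_iterations", "es_switch_threshold", "long_exon_min",
                     "trim", "min_instances"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "TrainingConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


@dataclass
class IterationLog:
    records: list[dict] = field(default_factory=list)

    def add(self, **kw) -> None:
        self.records.append(dict(kw))

    def to_tsv(self, path) -> None:
        if not self.records:
            open(path, "w").close()
            return
        keys = sorted({k for r in self.records for k in r})
        keys = ["iteration"] + [k for k in keys if k != "iteration"]
        with open(path, "w") as fh:
            fh.write("\t".join(keys) + "\n")
            for r in self.records:
                fh.write("\t".join(str(r.get(k, "")) for k in keys) + "\n")


def check_convergence(prev_genes, curr_genes, rule: str = "exact",
                      fraction: float = 0.99) -> bool:
    """True when the predicted gene sets are identical (default) or when the
    identical fraction reaches the relaxed threshold."""
    a = {g.coordinate_key() for g in prev_genes}
    b = {g.coordinate_key() for g in curr_genes}
    if rule == "exact":
        return a == b
    if rule == "fraction":
        denom = max(len(a), len(b), 1)
        return len(a & b) / denom >= fraction
    raise ValueError(f"unknown convergence rule {rule}")


def expand_phase_models(params: HSMMParameters, training_set: TrainingSet,
                        min_instances: int = 100, site_order: int = 0,
                        pseudocount: float = 1.0) -> HSMMParameters:
    """Split donor/acceptor models into phased sub-models where a phase has
    enough instances; phases below the threshold share the pooled frameless
    model.  A site whose intron phase changed between iterations is simply
    counted in its new phase bin (the bins are rebuilt every iteration)."""
    for kind in ("donor", "acceptor"):
        pooled = [w for ph in (0, 1, 2)
                  for w in training_set.site_instances.get((kind, ph), [])]
        if pooled:
            params.sites[kind] = estimate_site_model(
                pooled, kind, "frameless", site_order, pseudocount, params.windows)
            params.provenance[kind] = "anchored"
        for ph in (0, 1, 2):
            wins = training_set.site_instances.get((kind, ph), [])
            key = f"{kind}_phase{ph}"
            if len(wins) >= min_instances:
                params.sites[key] = estimate_site_model(
                    wins, kind, f"phase{ph}", site_order, pseudocount, params.windows)
                params.provenance[key] = "anchored"
            elif key in params.sites:
                del params.sites[key]
                params.provenance.pop(key, None)
    return params


def _carry(params, prev_value, name):
    warnings.warn(f"training: no data for {name}; previous model retained")
    params.provenance[name] = params.provenance.get(name, "heuristic") + "+carry"
    return prev_value


def reestimate(prev: HSMMParameters, ts: TrainingSet,
               config: TrainingConfig) -> HSMMParameters:
    """Re-estimate every sub-model from the training set; categories with no
    data keep the previous iteration's sub-model (provenance notes the
    carry-over)."""
    p = HSMMParameters(
        coding=prev.coding, noncoding=prev.noncoding,
        sites=dict(prev.sites), durations=dict(prev.durations),
        transitions=dict(prev.transitions), windows=dict(prev.windows),
        canonical_only=prev.canonical_only, mask_gap=prev.mask_gap,
        iteration_index=prev.iteration_index + 1,
        provenance=dict(prev.provenance))

    tag = "anchored" if any(f[2] == "anchored" for f in ts.coding_fragments) \
        else "all_predictions"
    if ts.coding_fragments:
        p.coding = estimate_markov([(s, o) for s, o, _ in ts.coding_fragments],
                                   config.coding_order, 3, config.pseudocount)
        p.provenance["coding"] = tag
    else:
        p.coding = _carry(p, prev.coding, "coding")

    nc_seqs = [s for s, _, _ in ts.anchored_introns] + list(ts.intergenic_fragments)
    if nc_seqs:
        p.noncoding = estimate_markov([(s, 0) for s in nc_seqs],
                                      config.noncoding_order, 1, config.pseudocount)
        p.provenance["noncoding"] = tag
    else:
        p.noncoding = _carry(p, prev.noncoding, "noncoding")

    for kind in ("start", "stop"):
        wins = ts.site_instances.get((kind, None), [])
        if wins:
            p.sites[kind] = estimate_site_model(
                wins, kind, "frameless", config.site_order,
                config.pseudocount, p.windows)
            p.provenance[kind] = tag
        else:
            p.sites[kind] = _carry(p, prev.sites[kind], kind)

    expand_phase_models(p, ts, config.min_instances, config.site_order,
                        config.pseudocount)
    if not any(ts.site_instances.get(("donor", ph)) for ph in (0, 1, 2)):
        p.sites["donor"] = _carry(p, prev.sites["donor"], "donor")
        p.sites["acceptor"] = _carry(p, prev.sites["acceptor"], "acceptor")

    # durations
    if ts.anchored_introns:
        p.durations["intron"] = estimate_duration(
            [ln for _, ln, _ in ts.anchored_introns], "intron",
            config.smoothing_bandwidth,
            prev.durations["intron"].l_max, DEFAULT_MIN["intron"])
        p.provenance["intron_duration"] = tag
    else:
        p.durations["intron"] = _carry(p, prev.durations["intron"], "intron_duration")
    for role in ("initial_exon", "internal_exon", "terminal_exon"):
        lens = ts.exon_lengths.get(role, [])
        if lens:
            p.durations[role] = estimate_duration(
                lens, role, config.smoothing_bandwidth,
                prev.durations[role].l_max, DEFAULT_MIN[role])
            p.provenance[f"{role}_duration"] = tag
        else:
            p.durations[role] = _carry(p, prev.durations[role], f"{role}_duration")
    single_lens = [g.cds_length for g in ts.complete_structures
                   if len(g.exons) == 1]
    if single_lens:
        p.durations["single_exon"] = estimate_duration(
            single_lens, "single_exon", config.smoothing_bandwidth,
            prev.durations["single_exon"].l_max, DEFAULT_MIN["single_exon"])
        p.provenance["single_exon_duration"] = "all_predictions"
    if ts.intergenic_fragments:
        p.durations["intergenic"] = estimate_duration(
            [len(s) for s in ts.intergenic_fragments], "intergenic",
            max(config.smoothing_bandwidth, 25.0),
            prev.durations["intergenic"].l_max, DEFAULT_MIN["intergenic"])
        p.provenance["intergenic_duration"] = tag
    else:
        p.durations["intergenic"] = _carry(
            p, prev.durations["intergenic"], "intergenic_duration")

    # transitions from complete predicted structures (anchored or not)
    genes = ts.complete_structures
    if genes:
        n_single = sum(1 for g in genes if len(g.exons) == 1)
        n_multi = len(genes) - n_single
        n_introns = sum(len(g.exons) - 1 for g in genes)
        n_fwd = sum(1 for g in genes if g.strand == "+")
        p.transitions = {
            "p_single": (n_single + 1.0) / (len(genes) + 2.0),
            "p_cont": (n_introns - n_multi + 1.0) / (n_introns + 2.0) if n_introns
            else prev.transitions["p_cont"],
            "p_strand_fwd": (n_fwd + 1.0) / (len(genes) + 2.0),
        }
        p.provenance["transitions"] = "all_predictions"
    return p


def train(genome: GenomeSequence, junctions: list[JunctionEvidence],
          config: TrainingConfig | None = None):
    """Run the full training loop.

    Returns ``(params, parses, log)``: the final parameter set, the final
    per-contig Parse list and the per-iteration log.
    """
    config = config or TrainingConfig()
    if len(genome) == 0 or genome.total_length == 0:
        raise ValueError("train: no contigs survive preprocessing")

    mode = config.mode
    if mode == "auto":
        mode = "ET" if len(junctions) >= config.es_switch_threshold else "ES"

    if mode == "ET":
        dialect = junction_dialect(junctions)
        hc = filter_high_confidence(junctions, dialect)
        params = heuristic_init(genome, hc,
                                smoothing_bandwidth=config.smoothing_bandwidth)
    else:
        params = heuristic_init(genome, [],
                                smoothing_bandwidth=config.smoothing_bandwidth)

    log = IterationLog()
    prev_genes: list = []
    parses: list[Parse] = []
    for it in range(1, config.max_iterations + 1):
        parses = []
        for contig in genome:
            if config.constraint_decoding and mode == "ET":
                parses.append(constrain_parse_with_introns(params, contig, junctions))
            else:
                parses.append(viterbi_parse(params, contig))
        genes = [g for p in parses for g in parse_to_genes(p)]
        if mode == "ET":
            genes = anchor_splice_sites(genes, junctions)
        ts = select_training_elements(
            genes, genome, config.long_exon_min, config.trim,
            params.windows, es_mode=(mode == "ES"))
        params = reestimate(params, ts, config)

        same = len({g.coordinate_key() for g in genes}
                   & {g.coordinate_key() for g in prev_genes})
        frac = same / max(len(genes), len(prev_genes), 1)
        log.add(iteration=it, mode=mode, n_genes=len(genes),
                identical_fraction=round(frac, 4), **ts.counts())
        converged = it > 1 and check_convergence(
            prev_genes, genes, config.convergence_rule, config.convergence_fraction)
        prev_genes = genes
        if converged:
            break

    if config.constraint_decoding and mode == "ET":
        # final prediction pass without the junction constraints
        parses = [viterbi_parse(params, c) for c in genome]
    return params, parses, log
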