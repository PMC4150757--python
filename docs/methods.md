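# Methods

## The generative model

A contig is modelled as a left-to-right alternation of intergenic segments
and genes under a hidden semi-Markov model.  A gene on either strand is a
single coding exon, or an initial exon, one or more (intron, exon) pairs
and a terminal exon; the exon following an intron is internal with
probability `p_cont`, terminal with `1 − p_cont`; a fresh gene is
single-exon with probability `p_single`; strands carry a Bernoulli prior.
These three distributions are the grammar's transition parameters and are
re-estimated from the complete predicted gene structures each iteration.

Emissions: intergenic regions and introns come from a homogeneous Markov
chain (order 5 by default); coding exons from a three-periodic chain
(order 5 by default) whose frame is tracked across introns via
phase-indexed intron states (intron phase = number of nucleotides of the
interrupted codon 5′ of the intron).  In-frame stop codons are structurally
forbidden inside the CDS, including codons split by an intron; the CDS
begins with `ATG` and ends with a stop, and introns carry `GT`/`AG`
dinucleotides (decoding is restricted to canonical, unmasked signal
motifs).

Signals — donor, acceptor, translation initiation and termination — carry
positional weight models over fixed windows (donor: 3 exonic + 6 intronic
nt; acceptor: 18 intronic + 3 exonic; initiation: 6 upstream + ATG + 3;
termination: stop codon + 6 downstream; all configurable).  A signal's
contribution to a parse score is the **log-odds** of its window: the PWM
log-probability minus the chain emission the window would otherwise
receive (coding part in the adjacent exon's frame, non-coding part on the
intron or intergenic side).  This makes the total score the exact
generative log-likelihood of a sequence in which windows are emitted by
the signal models and all other bases by their segment chains, and removes
the systematic anti-junction bias a pure additive PWM bonus would create.
Donor and acceptor models begin frameless and split into three intron-phase
sub-models once a phase accumulates at least `min_instances` (default 100)
training sites; bins are rebuilt each iteration, so a site whose predicted
intron phase changes simply counts in its new bin.

Durations: each element kind (initial/internal/terminal/single exon,
intron, intergenic) has a length distribution estimated as a
Gaussian-kernel-smoothed histogram on `[min_len, L_max]` plus a geometric
tail whose mass is the empirical fraction of observations beyond `L_max`
and whose rate matches the mean excess.  Defaults: `L_max` 10 000 for
introns, 5 000 for exons, 20 000 for intergenic; pseudocounts keep every
estimated distribution strictly positive and normalized to 1 ± 1e−9.

## Decoding

`viterbi_parse` runs an exact semi-Markov dynamic program over candidate
signal positions (ATG, GT, AG and stop motifs on the forward strand, their
reverse-complement images on the reverse strand), with both strands in one
state space so a single parse tiles the contig.  Segment emissions are
O(1) via phased prefix sums; in-frame-stop and repeat-barrier constraints
reduce every lookback to a contiguous candidate window, scanned directly
(numba-compiled kernels).  Numerical and structural choices:

* Genic durations are hard-capped at `L_max` during decoding (no tail);
  the intergenic state keeps its geometric tail, handled by a running
  maximum so arbitrarily long gaps cost O(1).
* Contig edges: leading and trailing intergenic segments are scored with
  the survival function P(D ≥ d) rather than the pmf, since their true
  extent is censored by the contig boundary.  Genes truncated by contig
  ends are not modelled.
* Masking: bases that were lowercase or `N` in the input (and bases whose
  Markov context touches them) are emitted uniformly by every model, so
  short masked runs are score-neutral; no exon or intron may overlap a
  masked run longer than `mask_gap` (default 50 nt), while intergenic
  segments may span repeats of any length.
* Ties resolve to the higher score, then fewer segments, then the
  earliest-scanned predecessor, making decoding fully deterministic.
* A single `score_parse` function defines the scoring semantics; the
  decoder's reported score is always re-derived through it, and the
  brute-force enumeration oracle (`brute_force_parse`, for contigs up to
  ~150 nt) maximises the same function, so the two paths can be compared
  to 1e−9.

Evidence-constrained decoding (`constrain_parse_with_introns`) adds a
large constant reward to constrained junctions used as introns, which
maximises the number of satisfied constraints (a maximal consistent subset
when the set is jointly infeasible) and reports which junctions made it;
the returned score is recomputed without rewards.

## Training

Re-estimation is hard (Viterbi) training: each iteration decodes every
contig, selects elements, and re-fits all parameters from the selection.
In the semi-supervised (ET) mode, selection requires anchor splice sites —
exact coordinate-and-strand agreement between a predicted donor/acceptor
and a mapped-intron boundary.  Exons need ≥ 1 anchored site; predicted
exons > 800 nt enter regardless, trimmed by 60 nt per end (their boundary
placement is less reliable); non-coding training sequence comes from
introns with both ends anchored and from intergenic runs between two
anchored border exons; initiation/termination windows come from anchored
initial/terminal exons; transition statistics use all complete predicted
genes.  Exon length distributions are fitted from anchored exons by role;
single-exon gene lengths, which cannot be anchored, are taken from the
complete predicted structures.  A category that comes up empty keeps the
previous iteration's sub-model, with provenance noting the carry-over.

The unsupervised (ES) mode is the minimal degradation of the same loop:
identical grammar, estimation and long-exon trimming, but every predicted
element is eligible — so the measured ET−ES difference isolates the
anchoring itself.  ES initialization has no high-confidence introns, so
splice models start from consensus-pinned priors.  `auto` mode selects ES
below 1000 mapped introns.

Initialization (ET): introns with score > 0.5 (probabilistic aligners) or
coverage > 3 (read-count aligners) form the high-confidence set that seeds
the donor/acceptor models and the intron length distribution.  The initial
coding/non-coding chains come from a GC-content mapping: codon-position
nucleotide compositions anchored at 30/50/70% genome GC (position 3
tracking GC strongly, position 1 moderately with a purine excess) and
interpolated linearly; the non-coding chain is the genome composition
implied by the GC value.  The anchor tables are this package's own
calibration of that classic heuristic.

Convergence: the loop stops when the predicted gene coordinate sets of two
successive iterations are identical (a relaxed ≥ 0.99-identical rule is
available), or after `max_iterations` (default 10).

## Evaluation

`build_test_set` filters an annotation to unambiguous genes: exons
overlapping masked repeats or other genes (including UTR exons when
annotated), exons < 6 nt, introns < 20 nt or > 10 000 nt, internal
in-frame stops or non-GT-AG splice dinucleotides, and genes with
alternative isoforms are excluded; protein-level screens can be supplied
as an external exclusion list, and `require_utr` demands annotated UTRs on
both sides.  `compare` reports Sn and Sp at nine levels (internal exon,
intron, donor, acceptor, initiation, termination, nucleotide, gene,
partial gene — the last ignoring the initiation boundary, since start
annotation is the least reliable element).  Matching is exact-coordinate.
Sensitivity is genome-wide; Specificity counts only predictions lying
within evaluation intervals (each test gene ± 300 nt), and the nucleotide
level is restricted to those intervals on both sides for symmetry.
Predictions that stick out of every interval are excluded from Sp
denominators rather than penalised, since their ownership is ambiguous.

## The synthetic-data generator

`simulate_genome` samples a state path from the grammar under a known
parameter set and emits sequence accordingly: gamma-shaped duration models,
an order-2 three-periodic coding chain derived from a realistic codon-usage
construction, an AT-rich CpG-depleted order-2 background, and
hand-specified signal PWMs (consensus `MAG|GTAAGT` donor,
pyrimidine-tract acceptor, Kozak-like start context, TAA-biased stop).
Signal windows are planted over the chain-emitted bases with canonical
motifs forced, exactly matching the decoder's emission semantics, and
genes are rejection-sampled until structurally valid.  Repeats are modelled
as soft-masked runs (exponential lengths) inserted into intergenic
sequence.  Junction evidence reproduces a spliced aligner's output: each
true intron is reported with probability `detection_rate` with
high-support scores/coverage, and false junctions (at `fp_rate` × the
detected count) are placed on decoy GT..AG / CT..AC loci with low-support
distributions — deliberately not filterable by motif, so anchoring has
real noise to reject.

Two profiles fix the study conditions: `compact` (2 Mb, ~300 genes, 150 nt
mean introns, 4.2 kb mean intergenic, 5% repeat fraction, score-dialect
evidence at detection 0.8 / false-junction rate 0.1) emulates a gene-dense
fruit-fly-like genome; `large` (500 kb, ~33 genes, 400 nt introns, 12 kb
mean intergenic, 40% of intergenic sequence masked, coverage-dialect
evidence) emulates the repeat-heavy long-intergenic regime where
unsupervised training struggles.  The `large` genome length keeps the
five-seed two-mode comparison tractable on one CPU while preserving the
regime's character (intergenic-to-genic ratio and masking, not absolute
genome size, drive the difficulty).

What the simulations do **not** contain — alternative splicing, UTRs and
UTR introns, non-canonical splice sites, GC isochores, transposon ORFs
inside repeats, sequencing-level read errors — bounds what passing tests
show: they validate the algorithmic machinery (exact decoding, selection
rules, estimation, the anchoring advantage) under the model's own
assumptions, not performance on real annotation projects.

## Known limitations

* Decoding considers canonical (`GT`/`AG`) splice sites only; non-canonical
  introns are evaluated (filter v) but never predicted.
* One optimal parse per contig: no alternative isoforms, no posterior
  probabilities, no partial genes at contig edges.
* The heuristic GC initialization uses package-calibrated anchor tables;
  on real genomes an externally trained initial model may be better.
* Intergenic emission uses the forward-strand background chain for both
  strands (the background is near strand-symmetric; introns do use
  strand-specific emission).
* Branch-point modelling (important for fungal introns) is not
  implemented.
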