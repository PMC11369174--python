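# Methods notes

This note documents the models, conventions and numerical choices behind
`mutprop`, and what the synthetic-data generator does and does not emulate.

## Library design

IDRs are tiled with 16-residue windows advanced by 4 residues, so an
interior mutation is covered by ceil(16/4) = 4 overlapping peptide pairs and
at least 3 even near step boundaries. Both parameters are exposed
(`peptide_len`, `step`); the defaults reflect displayed peptides of at most
16 residues and the design goal of ≥3 covering windows per mutation.

Window placement: full-step windows are laid down while a complete 16-mer
fits; one extra window anchored at the region end is added **only when some
variant would otherwise be uncovered**. Anchoring unconditionally would
duplicate near-terminal coverage and change the covering-window count for
interior variants; anchoring on demand loses no terminal variant while
keeping the tiling geometry regular. Regions shorter than one window yield
no pairs (with a warning).

Only a single mutation is introduced per designed peptide: when several
variants fall in one window, each gets its own mutant peptide sharing the
wild-type partner. Multi-residue substitutions (delins) are supported as
equal-start substitution strings rather than hard-coded special cases. All
peptides are sanitised by replacing cysteine with alanine (avoiding
disulphide artefacts on the phage coat); if sanitisation erases the
wild-type/mutant difference (a variant *to* cysteine), the pair is skipped
with a warning.

Reverse translation uses a built-in ranked E. coli K-12 codon-usage table
(replaceable per call). Codon choice is deterministic greedy — the
top-ranked codon unless it would complete a forbidden site (default the
SmaI site `CCCGGG`, checked across codon junctions) — with local
backtracking to lower-ranked codons, and to previous positions if needed.

Coordinates are 1-based inclusive throughout, matching the conventional
`PROTEIN_start-end` peptide subscripts.

## NGS processing

Demultiplexing requires an exact match of both the 5′ and the 3′ barcode; a
read matching two different samples' barcodes is unassigned. No mismatch
tolerance is applied by default since barcode sets are designed for exact
discrimination. Reads with arithmetic-mean base quality < 20 are discarded
(strict less-than: mean 20.0 is kept). Inserts between the constant
adapters are translated in the single fixed phagemid frame; reads failing
adapter location, frame/stop, or design membership are tallied as rejection
reasons, not errors.

Counts of exactly 1 within a (replicate, selection-day) sample are removed
as sequencing noise. Remaining counts are normalised per (replicate, day)
to counts-per-million (the constant cancels in all downstream ratios within
a day), and a per-peptide normalised average count is formed per replicate
across its sequenced days. A peptide absent on one of a replicate's days
contributes zero to the average (zero-fill, configurable): treating absence
as zero reflects that the day was sequenced and the peptide not seen.
Days with zero total count are excluded with a warning.

## Confidence scoring

Each retained peptide scores one point per satisfied criterion:
(i) observed in ≥ 2 replicates, (ii) overlapped by ≥ 4 residues (one tiling
step) by another enriched peptide of the same protein, (iii) matching the
bait's consensus motif, (iv) mean merged count at or above the median of
retained peptides. The thresholds for (i), (ii) and (iv) are pipeline
conventions, exposed as parameters; the class mapping (4 = high, 2–3 =
medium, otherwise low) is fixed. A missing motif model evaluates criterion
(iii) as false with a warning so baits without a known consensus can still
be scored.

## Mutation-centred analysis

The observation unit is (peptide window × replicate) on merged
per-replicate counts; using per-day counts instead is a configuration
switch. Observations with zero counts on both sides carry no evidence and
are excluded — the enrichment-score term is undefined at 0/0. The score is
the sum of mutant count fractions minus wild-type count fractions; each
term is a within-pair ratio, so rescaling all counts of one replicate
leaves it unchanged.

The Mann–Whitney test compares the vector of wild-type against mutant
counts: the exact null distribution is used for combined samples of ≤ 20
tie-free values, otherwise the midrank normal approximation with tie
correction. Identical vectors return p = 1. Pairs are classified at
p ≤ 0.001 (cut-off exposed); sub-threshold pairs are labelled *neutral*
rather than dropped. A Benjamini–Hochberg FDR column is reported for
convenience but never used for classification, since the classification
convention is a raw-p cut-off.

Per-window ("individual peptide pair") significance uses its own cut-off,
default 0.05: with r replicates per window the exact-test floor is
2/C(2r, r) (≈ 0.008 at r = 5, ≈ 0.029 at r = 4), so the collapsed-pair
cut-off of 0.001 is unattainable at the window level and would make the
statistic vacuous.

## Motif mapping

Mutations are classified within a ±20-residue window around the site
(truncated at protein termini). Consensus patterns are an ELM-style regex
subset: literal residues, bracketed residue classes (fixed/key positions)
and `x`/`.` wild-cards. Priority: a wild-type match covering the site →
*key* or *wildcard* by the consensus position; otherwise a mutant-only
covering match whose mutated residue sits at a fixed position →
*motif_created*; otherwise any match elsewhere in the window → *flanking*
with the nearest-match distance; otherwise *no_motif*. Ties between
overlapping matches are broken toward the match covering the mutation, then
leftmost. Curated (known) motif instances, when supplied, take precedence
over de novo scanning. An optional PSSM path scores log-odds sums against a
user threshold; the consensus scan is the primary route.

Grantham distances are computed from the 1974 composition/polarity/volume
formula, with the normalisation constant fixed by setting the mean of the
190 residue-pair distances to 100 and rounding to integers (reference
anchors R–C = 180, L–I = 5, C–W = 215 reproduce the published matrix).
Severity classes: conservative < 51, moderately conservative 51–100,
moderately radical 101–150, radical > 150 (boundary values belong to the
named closed ranges).

## Affinity analytics

Saturation curves are fitted with mP = mP_free + (mP_max − mP_free)·f_bound,
where f_bound is the physical root of the quadratic ligand-depletion
equilibrium in total protein, total probe and K_D — valid when the probe
concentration is not negligible against K_D, and reducing to the hyperbola
in the excess-protein limit. Flat series (span below ~3× the point-to-point
noise or 2% of signal) are flagged instead of fitted.

Displacement curves are fitted with a 4-parameter logistic on log₁₀
competitor concentration. A curve is called **non-binding** when the fitted
amplitude is indistinguishable from noise (≤ max(3×residual SD, 2% of the
top plateau)) or the midpoint falls outside the titrated range; increasing
mP with competitor is flagged anomalous. IC50 → K_D uses the
competitive-binding correction (free competitor at 50% inhibition divided
by probe-occupancy and free-protein terms); the implementation was checked
against an exact three-species equilibrium solver and agrees to numerical
precision, tends to IC50 in the dilute limit, and never exceeds IC50.

Fold-changes are oriented so fold > 1 means the mutant binds tighter —
making sign(log₂ fold) directly comparable to the sign of the enrichment
score. A non-binder on either side is an unbounded change and is capped at
20 (|log₂| = 4.3, reported to 1 decimal); capped records count as exceeding
the twofold agreement threshold. A record *agrees* with the phage screen
when the fold-change is at least twofold in either direction **and** its
direction matches the sign of the enrichment score; agreement percentages
are reported as integers. For the packaged validation table the
importin-α (KPNA4) records scored for agreement are the major-pocket
affinities (the higher-affinity, motif-cognate site); minor-pocket rows are
retained as supplementary records, and the score-less KPNA7 row is
excluded. Upper-limit K_D entries ("<x") are parsed at their limit value,
which does not affect any agreement call.

## Synthetic data

The generator plants one variant per toy protein against a PPxY-style
consensus (two fixed prolines, a wild-card, a fixed tyrosine), with four
classes: key-breaking (Y→E in a planted instance), motif-creating (F→Y
completes an almost-motif), wild-card substitution, and flanking
substitution. Background sequences exclude proline (no accidental motif
instances) and cysteine (sanitisation-neutral). Counts per (replicate, day)
are negative-binomial with mean proportional to peptide binding propensity:
baseline b for motif-bearing peptides, b·(1−δ) for the disfavoured allele
of an effect pair, symmetric for neutral pairs; δ = 0 is an exact null.
Defaults (δ = 0.9, depth 10⁵ reads per replicate-day, 5 replicates, 2 days,
NB size 10) represent a strong, well-powered selection; the type-I-control
simulation uses 300 symmetric pairs. The FP forward models are the
quadratic binding equation and the exact competitive equilibrium (solved
numerically, independent of the logistic fit used for inversion) plus
Gaussian mP noise.

What the generator does **not** emulate: amplification bias across
selection rounds, cross-replicate depth variation, barcode/sequencing
errors (FASTQ emission is uniform Q30), chimeric reads, peptides shared
between paralogous proteins, and motif grammar beyond a single consensus
per bait. Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated count model, not robustness to every
artefact of real selections.

## Problem sizes

The test-suite simulations use 16–300 domain-mutation pairs, 4 windows per
mutation and 5 replicates — enough for exact/asymptotic Mann–Whitney
regimes, direction recovery and type-I control at the asserted margins
while keeping the whole suite fast and deterministic (all randomness seeded).
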