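# Methods

## Scope and model

`degdet` treats a protein's degradation propensity as a bundle of
sequence-readable determinants and provides, for each, a scanner, a null
model and a comparison statistic.  The package works entirely from primary
sequence plus (optionally) per-residue predictor outputs supplied as text;
it never runs disorder, topology or aggregation predictors itself, and the
parsers accept the field's de-facto formats (IUPred-style three-column
scores, TOPCONS-style one-letter topology strings, PASTA-style
energy/probability tables).

## Determinants and their parameters

**CTTH.**  Mean Kyte–Doolittle hydropathy over the last `tail_window`
residues (default 30, dimensionless KD units, positive = hydrophobic);
`rest_gravy` is the mean over the remaining prefix, which is why analyses
require length > 60 so both parts are scored on ≥ 30 residues.  The
stability-pattern classifier uses four thresholds: `ctth_low_quartile`
(−0.963) and `ctth_high_quartile` (−0.110), the lower/upper quartiles of
CTTH in a canonical AUG reference set, and rest-of-chain cuts at 0
(hydrophobic) and −1 (strongly hydrophilic).  All inequalities are strict,
so boundary values fall into `other`; `ctth_quartiles()` recomputes the
quartile thresholds (linear-interpolation quantiles) from any user-supplied
reference distribution.  Proteins with a TMD ending within
`cterm_tmd_margin` (30) residues of the C-terminus are never called
`destabilized_tail`, because a membrane anchor inflates tail hydropathy
without implying degradation.

**Degrons.**  Motif tables carry ΔPSI, the experimentally measured
stability difference between terminal and internal placement of a motif
(more negative = stronger degron); loading retains ΔPSI ≤ −0.4 and
collapses duplicate motifs to their most negative value.  Matching is
anchored and exact-letter: C-end motifs must equal the sequence suffix;
N-end motifs must equal the prefix starting at residue 2 when the chain
begins with Met, else at residue 1.  The non-Met rule is this package's
choice for non-AUG isoforms, which have no initiator Met to skip; it keeps
the scanner total on every input.  Downstream analyses use
presence/absence, matching how terminal-degron prevalences are compared
between protein groups.

**KFERQ-like motifs.**  Every 5-residue window is classified independently
against three rules.  Canonical: Q anchor at either end; the remaining four
residues contain 1–2 basic (K/R), 1–2 hydrophobic (F/I/L/V) and exactly one
acidic (E/D), with basic + hydrophobic = 3.  Phospho-activated: the acidic
slot holds S/T (Y admitted via `include_tyrosine`, default off) and no E/D.
Acetyl-activated: K fills the anchor slot and does not also count toward
the basic tally.  Overlapping windows each count and a window can satisfy
several classes (one hit per class); per-window classification is the only
decomposition under which a brute-force per-window oracle is well defined,
and the test suite holds the scanner to exact agreement with such an
oracle.  A window can anchor at both ends; it is still reported once per
class.  Densities are counts per residue; dataset-level rates divide the
total count by the summed dataset length.

**Terminal IDRs.**  The N-run is the maximal prefix of residues with
disorder score strictly above `idr_threshold` (0.5); the C-run is
symmetric.  A terminal IDR is called when the run is ≥ `idr_min_len` (30)
— the inclusive reading of the length rule, chosen because the experimental
source for the 30-residue figure states it inclusively; both parameters are
configurable.  Only terminal IDRs are implemented: internal-IDR content
scales strongly with protein length, which would confound comparisons
between length-skewed groups.

**TA classification.**  TA-like requires, in order: no signal peptide,
exactly one TMD, TMD length ≤ `ta_tmd_max` (29), and a post-TMD tail of ≤
`ta_tail_max` (29) residues; the first failed criterion is reported as the
reason.  The ordering makes the reason deterministic and mirrors how a
curator would triage the topology string.

**Aggregation.**  The aggregation fraction is the share of residues with
pairing free energy < `agg_energy_max` (−5, PASTA units) and pairing
probability > `agg_prob_min` (0.01).  It is a count, hence invariant to
residue order — which is why original-vs-shuffled aggregation differences
require re-running the predictor on shuffled sequences and cannot be
obtained from this module's shuffle null.

## Redundancy filters

Terminal determinants are computed on terminal-deduplicated records so that
families of isoforms sharing a terminus do not count multiple times:
CTTH uses C-terminal 30-mer uniqueness, degron scanning uses terminal
10-mer uniqueness at the respective end, IDR calling uses terminal 30-mer
uniqueness, and KFERQ scanning applies no filter (motifs occur anywhere in
the chain).  Within a redundancy group the longest record is kept, ties
broken by input order; records shorter than the k-mer are dropped with a
logged count, since they cannot participate in the uniqueness contract.
`profile()` reports per-determinant analyzable counts alongside the table.

## Shuffle null

The null for positional signal is a uniform within-sequence permutation of
residues (Fisher–Yates), which preserves length and composition exactly.
Under it, the expected CTTH of a shuffled sequence equals the sequence's
full-chain mean KD — a closed form the calibration tests check by Monte
Carlo.  Paired original-vs-shuffled designs use one shuffled counterpart
per sequence by default (`n_reps` raises this for variance estimation).
Per-record seeds derive from the master seed and the record ordinal through
a splitmix-style 64-bit hash reduced below 2³¹, so results are reproducible
and independent of iteration order.  Shuffled sets are not re-deduplicated
unless mirrored filtering is requested explicitly.

## Statistics

Continuous determinants: two-sided Wilcoxon rank-sum (exact enumeration up
to total n = 50 without ties, tie-corrected normal approximation with
continuity correction otherwise), with rank-biserial
`r = 1 − 2U/(n₁n₂)` as the primary effect (+1 when the first sample ranks
entirely below the second).  A `z/√N` variant is emitted alongside because
some effect-size packages define r that way and the two differ under ties.
Paired designs use the signed-rank test; for ≤ 25 nonzero deltas the
two-sided p is computed exactly as `P(|W⁺ − μ| ≥ |w − μ|)` over all 2ⁿ sign
patterns via dynamic programming on doubled (hence integer) average ranks —
a definition that remains exact under tied magnitudes, where off-the-shelf
exact modes disagree with sign-flip enumeration.  Binary determinants:
Fisher's exact test with the conditional-MLE odds ratio and 95% CI (the
sample ad/bc ratio, Haldane–Anscombe-corrected at zero cells, is also
reported); paired binary designs use McNemar's test, exact binomial up to
25 discordant pairs.  Proportion CIs follow the Wilson score interval with
continuity correction exactly as R's `prop.test` computes it (including the
correction's cap at |x − n/2|), verified against R output.  Spearman
correlation uses exact permutation p for n ≤ 7.  Motif-count comparisons
use the exact conditional Poisson rate test: conditional on the total
count, the first count is binomial with the exposure share as success
probability; the rate-ratio CI is transformed from the exact binomial
proportion CI.  This rate test is the package's implementation of
count-per-length comparisons; a full Poisson GLM is deliberately out of
scope.  P values are BH-adjusted within each report (one `compare` or
`null_compare` call defines the family).

Degenerate inputs (all values tied, no discordant pairs, zero pooled SD)
raise `DegenerateDataError`; pipeline reports catch it and record a note
instead of a p value, so homopolymer-like edge cases cannot produce
spurious significance.

## Synthetic data

The generator emulates the statistical structure of canonical vs.
noncanonical protein sets, not their biochemistry: i.i.d. residues from a
human-like composition table, log-normal lengths (median 120 aa, sigma
0.45, floor 60 — a realistic mix of microprotein- and domain-scale chains
whose floor is the analyzable minimum), and planted determinants.  The
i.i.d. model is a deliberate choice: it is the model under which the
shuffle null is exact, so null-calibration tests are clean.  It carries no
dipeptide structure, no secondary-structure periodicity and no homology
between sequences — so passing tests demonstrate correctness of scanners
and statistics, not realism of any biological claim.

The tail-hydropathy shift is produced by exponential tilting of the
composition on the KD scale: tail residues are drawn from
`p_i exp(θ·KD_i)` with θ solved so the tilted mean exceeds the base mean by
`tail_kd_shift`; the realized mean CTTH is verified within 0.05 at n ≥
1,000 sequences.  Planting probabilities are realized prevalences: when
planting is enabled for a terminus, non-planted sequences have accidental
anchored matches against the planting motif set resampled away, so truth
tables are exact and the implied odds ratio is fully controlled.  With
planting disabled, the anchored-match rate is whatever the composition
implies (and the tests check it against the closed-form rate).  Planting
order is tail tilt → TA block → degrons → KFERQ, with later plants redrawn
(≤ 100 attempts) rather than allowed to overwrite earlier anchored windows,
and KFERQ windows kept clear of the anchored terminal regions so planting
can neither create nor destroy a degron match.

The default two-group study plants C-end degron prevalences of 8.4% vs.
16.8% (odds ratio ≈ 2.20) and a +0.15 tail-KD shift — the prevalence
contrast and mean-shift magnitude characteristic of canonical-vs-
noncanonical comparisons — at n = 5,000 per group, where a +0.15 shift
yields a rank-biserial magnitude near 0.15.

Companion files are emitted in the parsers' own formats.  Disorder scores
are synthetic: background residues uniform on [0, 0.98] (iid, so terminal
runs of 30 above 0.5 essentially never arise by chance) with planted
terminal runs of 30–60 residues above 0.5.  The separate
`surrogate_disorder()` generator used in null comparisons is likewise a
labelled stand-in — a fixed per-residue propensity scale smoothed over a
21-residue window — not a reproduction of any predictor.  Aggregation
companions draw energies from N(−2, 2) and probabilities from U(0, 0.02),
giving a few percent of qualifying residues.

## Numerical and design choices

* Hydropathy means are unweighted double-precision arithmetic means (the
  GRAVY convention); the tail/rest decomposition identity
  `(w·CTTH + (L−w)·rest)/L = full-chain mean` is tested to 1e−12.
* Tie-breaks are everywhere "first in input order", making every filter
  order-stable and idempotent.
* Exact/approximate switchovers (rank-sum 50, signed-rank 25, McNemar 25,
  Spearman 7) are module constants; they bound runtime while keeping the
  small-sample regimes exact.
* Identity collapse uses exact full-sequence equality; substring
  containment is not implemented.
* Degron matching has no wildcard support by default; the bundled toy
  tables are synthetic fixtures, and users supply real curated tables as
  TSV.
* `read_fasta` strips a single trailing `*`, uppercases, and keeps the
  description after the first whitespace as metadata; filters reject
  nonstandard residues (U and ambiguity codes) rather than editing them.
* All TSV output uses a fixed `%.10g` float format so that reruns under a
  fixed seed are byte-identical; `simulate` writes into a temporary
  directory and moves files into place only on success.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use: 500 random cases per
scanner-oracle check; 10 sequences × 10,000 shuffles for null calibration;
full enumeration of all exact-test instances with total n ≤ 10; 1,000
null replicates for type-I error; and 20 replicates of the n = 5,000 ×2
two-group study for parameter recovery.  These sizes make the whole
validation run complete in a few minutes on one CPU while keeping every
binomial tolerance comfortably powered.

## Limitations

* Scanners operate on primary sequence; they cannot see surface exposure,
  so motif hits (especially KFERQ-like) are candidates, not accessible
  sites.
* The synthetic generator's i.i.d. model understates the clumpiness of real
  hydrophobic segments and contains no isoform structure beyond what the
  redundancy filters are tested against.
* BLAST-based cross-dataset deduplication, predictor execution (disorder,
  topology, aggregation), ORF calling and gene-age assignment are out of
  scope; their outputs are consumed as files.
* The `r = z/√N` and `r = 1 − 2U/(n₁n₂)` rank-biserial conventions diverge
  under heavy ties; both are reported, the latter is primary.
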