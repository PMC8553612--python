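# Methods

This note documents the statistical procedures `vepbench` implements, the
choices made where the procedure was genuinely open, and what the
synthetic data generator does and does not emulate.

## Truth-set curation

A variant enters the functional truth set iff it is missense, does not
sit on either of the two exonic bases flanking an intron–exon boundary
(potentially spliceogenic; the flag is an input, never derived from
coordinates), all of its per-assay outcomes agree, and the agreed outcome
is not intermediate. Unanimous nonfunctional maps to DEL, unanimous
functional to TOL. Every excluded variant is logged with exactly one
reason using the fixed precedence **non-missense > splice-flank >
discordant > intermediate**; the source protocol applies these rules as a
pipeline without stating a tie order, so the precedence here is a
documented package choice. Multi-assay genes are integrated strictly:
any disagreement between constituent assays (including
functional-vs-intermediate) is discordant — no weighting precedes the
concordance check. Conservation holds exactly: |input| = |truth set| +
|exclusion log|, and curation is idempotent.

Per-assay raw scores can be mapped to outcomes via `AssayRule` numeric
cutoff pairs (a nonfunctional region, a functional region, an
intermediate gap, on either scale orientation) or supplied precomputed;
both paths are equivalent downstream.

The ClinVar truth set is restricted to variants already in the functional
truth set. P/LP records are taken at any star rating; the ≥1-star
requirement applies only to the benign arm (B/LB), a literal reading of
the source criteria. Everything else (VUS, 0-star benign, unannotated)
drops.

## Harmonization

A tool–threshold spec carries a TOL rule and a DEL rule, each a
comparator (`<`, `<=`, `>`, `>=`) plus cutoff, authored on the tool's
native scale. Comparators are per-spec data, not a global convention,
because published combinations mix boundary conventions (e.g. `<0.4`,
`≤0.7`, `>0.5`). Overlapping regions are rejected when the spec is
loaded. Binary specs partition the score line; nonbinary specs leave an
indeterminate zone. Scores satisfying neither rule are INDETERMINATE;
absent or unparseable values are MISSING. The two states stay distinct
through the whole pipeline: both are excluded from confusion counts and
both reduce variant inclusion, but only MISSING counts against coverage —
an indeterminate call is still a produced value. This reconciles the two
published exclusion rules (a tool covering <3% of variants is excluded at
the 25% coverage bar, while a nonbinary spec leaving 42.4% of variants
indeterminate survives with 57.6% inclusion). Coverage exclusion is
strict (`< 0.25`); exactly 25% survives.

## Metric panel

From the 2×2 tally over definite calls: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), PPV, NPV, prevalence, detection prevalence,
BA = (sens+spec)/2, F1, and MCC. Any zero-denominator metric is flagged
undefined and propagated as such — silent zeros would corrupt the
unweighted mean across gene truth sets, which averages each metric over
the genes where it is defined and records the contributing count.

AUC is the Mann–Whitney statistic on average ranks (ties count ½),
direction-aware, computed on raw scores for all scored variants —
including those indeterminate under the threshold spec — since AUC is
threshold-free. A dichotomized-score variant (calls mapped to 1/0) is
available via `auc_mode: dichotomized` and is always used for categorical
tools. Internal arithmetic is full precision; integer-percent rounding
happens only in the `report` rendering layer.

## Likelihood ratios

PLR = sens/(1−spec). The NLR follows the benignity-oriented convention
used in clinical evidence calibration — spec/(1−sens), the true-negative
rate over the false-negative rate, so values above 1 favour benignity;
the textbook (1−sens)/spec is emitted in a separate column
(`nlr_conventional`) to avoid ambiguity. When any cell of the 2×2 table
is zero, the Haldane correction adds 0.5 to all four cells before
estimation (idempotent: corrected tables have no zero cell). 95% CIs use
the standard log-SE method, exp(ln L̂ ± 1.96·SE) with
SE² = 1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN) for the PLR and the
TP↔TN/FP↔FN swap for the NLR; the source never names its CI method, so
the method is recorded in the output provenance.

### Banded analysis

A band is a closed score interval compared against a disjoint reference
half-line; variants in neither region are excluded. Pathogenicity (PLR)
bands sit above the working threshold and report
P(band | DEL)/P(band | TOL) conditioned on band ∪ reference; benignity
(NLR) bands sit below and report P(band | TOL)/P(band | DEL). A band
that degenerates to the full positive region of a binary spec reproduces
the binary PLR exactly. The shipped default layout covers
0.9–1.0 / 0.8–1.0 / 0.8–0.9 / 0.7–0.8 against scores below 0.7 and
0.5–0.7 / 0.4–0.5 / 0–0.5 / 0–0.4 against scores above 0.7.

### Cross-gene means

The mean LR across genes is, by default, the arithmetic mean of the
per-gene estimates and of the per-gene CI bounds; the pooling method for
the published mean intervals is not derivable from the text, so a
log-scale (geometric-mean) alternative is available via
`lr_pooling: log`, and neither mode is claimed to reproduce the published
mean intervals numerically. The mode used is recorded in the result.

## Threshold optimization

Candidate cutoffs start at the lowest observed score and advance in steps
of 2% of the observed score range (`step_fraction = 0.02`), terminating
once past the maximum observed score. Relative steps accommodate tools on
unbounded scales (GERP++-like, CADD-like); an absolute step is available
for [0, 1] tools. Dichotomization uses strict `> cutoff` ⇒ DEL (mirrored
`<` for lower-is-deleterious tools). Ties break toward the lowest cutoff
achieving the maximal BA — deterministic and conservative toward
sensitivity. The iteration starts at the lowest observed score rather
than a theoretical minimum (the source is silent; observed minimum makes
the grid data-adaptive). The consensus threshold is the unweighted mean
of the per-gene optima, re-evaluated per gene and on the combined set;
by construction each gene's own optimum dominates the consensus on that
gene.

## Concordance combinations

A combination keeps a variant iff every member makes a definite call and
all calls agree. Variants where some member is MISSING/INDETERMINATE are
"incomplete", reported separately from discordant dropout. The dropout
denominator is the set of variants where all members made definite calls;
because the published dropout range does not pin down its denominator,
the fraction over all variants is emitted alongside. Pair ranking takes
the top 12 specs by mean-across-genes BA (ties: MCC, then label), and a
pair's BA is the gene-wise mean computed on its retained variants. On the
retained subset, combined sensitivity and specificity are each at least
the minimum over members (concordance restriction property).

## Synthetic data

The generator emulates the structure the evaluation assumes: five gene
strata at the published sizes (1,641 / 188 / 4,783 / 957 / 1,867) and
rounded deleterious fractions (23 / 34 / 8 / 20 / 22%), class-conditional
continuous scores (Beta by default, since most real tool scores live on
[0, 1]; uniform, truncated normal, and point-mass kinds are available),
configurable direction, missingness, categorical callers with per-class
call probabilities, and intermediate/discordant assay outcomes that
curation must drop. Class counts are allocated deterministically by
rounding so composition invariants are exact (a multinomial sampling mode
exists behind `allocate: "sampled"`); with the default fractions the
combined prevalence is 1,426/9,436 = 15.1%, matching the published 15% at
integer rounding (the published total of 1,413 deleterious is not exactly
recoverable from the rounded per-gene percentages). Intermediate and
discordant variants draw scores from an even mixture of the two class
densities, reproducing the observation that intermediate variants score
between the class medians.

Each (tool, gene) pair gets its own random stream seeded from a CRC32 of
the labels, so adding a tool or gene never perturbs other draws, and a
fixed config is bit-reproducible. Tools are conditionally independent
given the class; real predictors are strongly inter-correlated (many are
metapredictors sharing components), so synthetic concordance-dropout
levels are upper bounds on what correlated tools would show, and passing
tests demonstrate correctness of the machinery, not realism of intertool
correlation. Other known gaps: no sequencing noise, no assay chemistry,
no transcript coordinates (variant keys are opaque), and no
score–mechanism structure (e.g. dominant-negative hotspots).

`analytic_operating_point` gives the closed-form (sensitivity,
specificity) of a continuous profile at a cutoff from the class CDFs and
anchors the parameter-recovery tests: at 10,000 variants per stratum the
pipeline estimates match analytic values within three binomial standard
errors, and the log-SE 95% CI covers a known PLR in 93–97% of 2,000
simulated tables.

## Numerical and degenerate-input policy

- Undefined metrics are `None`/flagged, never NaN-propagated or zeroed.
- Empty truth sets, single-class truth sets, constant score vectors, and
  empty call columns raise typed errors (`ConfigError` exit 1,
  `DataError` exit 2 at the CLI) or return explicit undefined flags, as
  the operation's contract specifies.
- Confusion cells may be half-integers only after Haldane correction.
- The Haldane path guarantees interior sensitivity/specificity, so LRs
  and their CIs are always finite and positive.
- Report TSVs are written in full precision; integer-percent rounding is
  applied only by `vepbench report`.

## Problem sizes

The shipped demo and the test suite run at the published five-stratum
scale (9,436 variants, up to 72 synthetic tool–threshold combinations),
with 10,000 variants per stratum for parameter-recovery checks and 2,000
replicate tables for CI calibration — sizes at which every documented
property is measurable with comfortable margins on a single CPU.
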