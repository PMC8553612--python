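# vepbench

Benchmarking of in silico missense-variant predictors against functional
assay truth sets.

## The problem

Clinical variant classification under the ACMG/AMP framework leans on in
silico predictors (REVEL, SIFT, PolyPhen-2, Meta-SNP, CADD, ...) whose
evidence weight — nominally "supporting", a likelihood ratio of about 2 —
was set without calibration against trustworthy ground truth. Multiplexed
assays of variant effect (MAVEs) such as saturation genome editing now
provide thousands of clinically validated deleterious/tolerated (DEL/TOL)
classifications per gene, enabling unbiased evaluation. `vepbench`
implements that evaluation end to end for anyone with a per-variant score
table:

- **truth-set curation** — retain missense variants away from the two
  exonic bases flanking intron–exon boundaries, with unanimous,
  non-intermediate assay outcomes (nonfunctional → DEL, functional → TOL);
  optionally a parallel ClinVar truth set (P/LP → DEL; B/LB at ≥1 star → TOL);
- **tool–threshold harmonization** — declarative specs (comparator +
  cutoff per side, or a categorical map) turn each tool's raw output into
  DEL / TOL / INDETERMINATE / MISSING calls on its native scale, and
  combinations with no discrimination or <25% coverage are excluded;
- **the diagnostic panel** — prevalence, detection prevalence,
  sensitivity, specificity, PPV, NPV, balanced accuracy
  BA = (sens + spec)/2, F1, MCC, and rank-based (Mann–Whitney) AUC, per
  gene, combined, and as the unweighted mean over genes;
- **likelihood ratios** — PLR = sens/(1 − spec) toward pathogenicity and
  the benignity-oriented NLR = spec/(1 − sens), with Haldane correction
  (+0.5 to every cell when any cell is zero) and 95% CIs via
  exp(ln L̂ ± 1.96·SE); plus score-band analyses (e.g. scores 0.8–1.0
  versus <0.7) that calibrate evidence strength by absolute score;
- **threshold optimization** — BA-optimal cutoffs by grid search in 2%
  steps of the observed score range, per gene, with a cross-gene mean
  consensus threshold;
- **concordance combinations** — pairwise/k-way tool combinations keeping
  only unanimously called variants, with discordance-dropout accounting.

A first-class synthetic-data generator reproduces the statistical shape
of the published five-gene truth sets (strata of 1,641 / 188 / 4,783 /
957 / 1,867 variants with deleterious fractions ≈ 23 / 34 / 8 / 20 / 22%)
with configurable class-conditional score distributions, direction,
missingness and intermediate/discordant assay outcomes, so the whole
pipeline is testable without any downloads.

## Worked example

The shipped demo config simulates the five gene strata at published sizes
with three synthetic tools (a well-separated metapredictor `metaA`, a
lower-is-deleterious tool `lowB`, a categorical caller `catC`) and six
threshold specs:

```sh
vepbench evaluate \
  --config src/vepbench/data/demo_config.yaml \
  --outdir demo_out
```

`demo_out/truthset_summary.tsv` shows the curated composition — 9,436
variants, 1,426 DEL, overall prevalence 15% at integer rounding:

```
stratum  n     n_del  n_tol  prevalence
BRCA1    1641  377    1264   0.2297
BRCA2    188   64     124    0.3404
MSH2     4783  383    4400   0.0801
PTEN     957   191    766    0.1996
TP53     1867  411    1456   0.2201
ALL      9436  1426   8010   0.1511
```

`metrics_long.tsv` / `metrics_wide.tsv` carry the panel per truth set.
For the MEAN truth set (unweighted mean over the five genes) the demo
prints, among others:

```
spec_name  sensitivity  specificity  balanced_accuracy  mcc    auc
metaA_b    0.808        1.000        0.904              0.873  0.999
lowB_a     0.682        0.981        0.832              0.728  0.963
catC_a     0.881        0.725        0.803              0.490  0.803
```

`metaA_b` (binary at 0.7) trades sensitivity for perfect specificity;
`metaA_a` (indeterminate zone 0.4–0.7) recovers sensitivity at the cost
of variant inclusion (0.889 versus 0.985). The banded analysis in
`bands.tsv` shows evidence strength growing toward the score extremes —
for `metaA` the 0–0.4 band against scores >0.7 has a mean benignity LR of
266 while the working-threshold NLR of `metaA_b` is 5.2 — and
`thresholds.tsv` reports per-gene BA-optimal cutoffs (0.475–0.559) whose
consensus 0.513 loses at most 0.002 BA against any single gene's optimum.
`combinations.tsv` ranks concordance pairs with their dropout fractions.

All outputs are byte-identical across reruns of the same config and seed;
`manifest.json` records versions, the config hash, and row-count
reconciliation.

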