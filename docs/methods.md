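# Methods

This note documents the statistical procedures implemented in `mirmark`, the
assumptions behind them, the synthetic data model used to exercise them, and
the design decisions taken where a published convention was ambiguous or
genuinely open.

## Study design assumed by the workflow

The discovery workflow assumes several independent tumour/normal miRNA
expression cohorts on a common log2 scale, with partially overlapping miRNA
inventories and possibly very unequal group sizes, plus one designated
*reference* cohort that additionally carries clinical follow-up (stage,
overall survival, recurrence-free survival) and matched gene expression.
Cohorts measured on a linear scale can be converted on read with
`log2(x + offset)`; the offset defaults to 1.0, the usual pseudo-count, since
nothing in the inputs determines it. Zeros are treated as valid measurements,
never as missing; only empty cells and `NA` are missing.

## Preprocessing

**Missingness filter.** A miRNA is removed when its missing fraction is
*strictly* greater than the threshold (default 0.5) in the tumour group or in
the normal group, each with its own denominator. The strict inequality means
a miRNA missing exactly half of each group is kept; the per-group rule keeps
markers that are well measured in the large group but sparsely measured in a
small one from slipping through on the pooled rate. The filter is idempotent.

**Outlier masking.** Per miRNA and class group, values outside the closed
interval `[Q1 − k·IQR, Q3 + k·IQR]` (k = 1.5) are set to missing. Quartiles
use linear interpolation between order statistics — the default convention in
numpy/R — and the fences are inclusive, so a group of identical values (IQR
= 0) loses nothing. Masking is entry-level, not sample-level: a sample can be
an outlier for one miRNA and ordinary for another. One pass only; iterated
re-fencing would keep shaving the tails of clean distributions. Groups with
fewer than 4 observed values are skipped (their quartiles are unstable) with
a warning. Outlier masking runs after the missingness filter and operates on
the log2 matrix.

## Differential testing and consensus

Per miRNA and cohort, both groups need ≥ 3 observed values (the Shapiro–Wilk
minimum); miRNAs failing this are excluded from the cohort's test batch and
reported. The default `conventional` policy routes the comparison by
normality and variance: Shapiro–Wilk on each group, both p > 0.05 → Levene's
test (centered on the mean), then Student *t* if Levene p > 0.05 else Welch
*t*; otherwise a two-sided Mann–Whitney *U*, exact when the pooled sample is
tie-free and ≤ 20 observations, else the tie-corrected normal approximation.
The alternative `paper_literal` policy inverts the first branch (normal →
Mann–Whitney, non-normal → Levene + *t*): some published pipelines state the
rule this way, and both readings are reproducible here because the choice can
move individual miRNAs across the significance threshold. Normality is
declared only when *both* groups pass, the stricter of the two plausible
readings. A constant group is routed as non-normal; two constant equal groups
return p = 1 by convention.

P-values are Benjamini–Hochberg adjusted within each cohort: cohorts have
different miRNA inventories, so a pooled batch would mix exchangeable and
non-exchangeable hypotheses. The effect size is the log2 fold change; the
default `diff_of_log_means` subtracts group means of the log2 values (the
natural statistic when data arrive log-transformed), while
`log_of_linear_mean_ratio` un-logs first. The two differ on real data
(Jensen's inequality), so the mode is an explicit parameter rather than a
guess.

**Consensus rule.** A miRNA is *selected* when significant (q ≤ 0.05) in the
reference cohort and in at least `min_support` (default 2) supporting
cohorts — a reference-anchored replication requirement. The *direction
filter* then keeps only selected miRNAs whose fold-change sign agrees in
every cohort where they were significant; a selected miRNA always has ≥
1 + min_support recorded directions, so the consistency check is never
vacuous. Both steps are invariant to cohort input order, and the selected set
shrinks monotonically in `min_support`.

## Target network

Interaction edges are filtered to one species and, by default, to
functional-evidence support (support tags containing "weak",
case-insensitively, are dropped — the functional vs weak-evidence dichotomy
of curated MTI databases), then deduplicated on (miRNA, gene). Crossing with
a disease-gene list uses case-insensitive symbol matching without alias
resolution; miRNAs left with zero disease-gene targets stay in the degree
ranking so they can be flagged. An empty disease list is treated as a parsing
failure and raises.

Expression correlation per edge uses matched samples (tumour-only by
default — the between-patient contrast is the regulatory signal of interest;
mixing classes inflates correlations through the shared tumour/normal shift,
but a tumour+normal mode is available). Pearson is used when both vectors
pass Shapiro–Wilk at 0.05, Spearman otherwise; strength is binned on the
Mukaka scale (|r| < 0.3 negligible, < 0.5 low, < 0.7 moderate, < 0.9 high,
else very high) with the sign carried separately. Constant vectors yield a
flagged result with p = 1. BH q-values are added across all tested pairs.

Gene-set over-representation is the one-sided hypergeometric upper tail
`p = Σ_{j≥k} C(K,j)·C(N−K,n−j)/C(N,n)`, the canonical open replacement for
web-service enrichment tools; an EASE-style correction (scoring k−1
successes) is available behind a flag for users wanting the more conservative
variant. The universe defaults to every gene in the supplied collection, the
only background the inputs define. BH correction runs across sets. The
miRNA × pathway crossing matrix marks (m, P) = 1 when some disease-crossed
target of m lies in P.

## Diagnostics

Per-miRNA AUC is computed from the rank-sum (Mann–Whitney U) form with ties
contributing ½, so it inherits the U test's invariance under strictly
monotone transforms. Because a downregulated marker separates classes exactly
as well as an upregulated one, the reported AUC is orientation-resolved,
`max(A, 1 − A)`, with the raw oriented value and the orientation
(`high_in_tumour`/`low_in_tumour`) kept for audit. Accuracy classes follow
Greiner's bins: perfect (= 1), highly accurate (0.9, 1), moderately accurate
(0.7, 0.9], less accurate (0.5, 0.7], otherwise uninformative. No AUC
confidence interval is attached by default. Samples with a missing score are
dropped pairwise.

## Prognosis

Single markers use a median split of tumour expression among the analyzed
patients: strictly above the median is "higher", ties go to "lower" (equality
is not "above"). Multi-miRNA panels use the *concordant-median* rule: higher
requires being above the median for every panel member, lower requires
at-or-below for every member, and discordant patients are excluded. Under
independence each side keeps ≈ n/2^k patients, which is why panel size is
capped (default 5) and panels whose smaller group falls below `min_group`
(default 30) are rejected untested — the group-size floor is what makes the
log-rank test and Cox fit trustworthy. A `meanscore` grouping (median split
of the mean per-miRNA z-score, no exclusions) is provided for sensitivity
analysis. Medians are computed within the stage-specific analyzed patient
set; patients missing any panel value are excluded from that panel's
analysis.

Tested panels are compared with the standard two-group log-rank test; a panel
"passes" at nominal log-rank p < α (default 0.05) with no multiplicity
correction across panels by default — the screen is exploratory and the
p-values are exported so callers can BH-adjust. The hazard ratio of higher vs
lower comes from a single-covariate Cox proportional-hazards partial
likelihood (Efron tie handling, the standard default) with a 95% Wald CI;
complete separation is returned as a flagged non-converged result. The Cox
fit is optional (`compute_hr=False`) so large Monte-Carlo screens pay only
for the log-rank test. Stages (or whole endpoints) with fewer than
2·min_group eligible patients are skipped with a recorded reason.

## Synthetic data model

The generator produces the study structure above with planted ground truth:

* **Expression.** Each miRNA has a baseline mean drawn once from U(4, 12)
  log2 units, shared across cohorts; values are Normal(baseline, `noise_sd`)
  with `noise_sd` = 1.0 by default. Planted differential miRNAs shift the
  tumour mean by `de_shift` (default −2 log2 units, i.e. downregulated) in
  every cohort containing them. A core inventory of
  `round(overlap_fraction · n_mirnas)` miRNAs — hosting all planted DE
  miRNAs — appears in every cohort; each remaining miRNA enters each cohort
  independently with probability ½, so inventories genuinely differ.
* **Cohort sizes.** Default four cohorts with tumour/normal sizes
  (40, 9, 25, 20)/(10, 9, 12, 30): one tumour-heavy reference, a small paired
  cohort, a mid-size tumour-heavy cohort and a normal-heavy cohort, the mix
  of imbalances typical of public repositories, at a scale where the suite
  runs in seconds.
* **Contamination.** Entries go missing independently at `missing_rate`
  (default 5%); spike outliers add ±`outlier_magnitude` (default 6 log2
  units) at `outlier_rate` (default 1%) — the additive spike model is exactly
  what Tukey fences are designed to remove.
* **Target layer.** Planted miRNA–gene pairs set the gene's expression to
  `sign·ρ·z + √(1−ρ²)·ε` around its baseline, giving correlation `sign·ρ` in
  expectation (default |ρ| = 0.6, random sign); other genes are independent
  noise. The MTI table holds the planted pairs, human functional decoys, and
  a few non-human and weak-evidence rows so the filters are exercised. The
  disease list covers 60% of targeted genes plus untargeted padding; gene
  sets partition a 60% subset of the genes into six disjoint blocks.
* **Survival.** Event times are exponential with
  log-hazard = log(`baseline_hazard`) + `panel_log_hr` · score, where the
  score is the mean of the planted panel miRNAs' standardized tumour
  expressions (defaults: baseline 0.08/year, panel = three planted DE
  miRNAs, log HR = log 4). Censoring is independent exponential with rate
  `baseline · c/(1−c)`, so the expected censored fraction at the baseline
  hazard equals `censor_rate` (default 0.5); `censor_rate = 0` disables
  censoring. Recurrence uses the same score with a 1.5× baseline. Stages are
  i.i.d. from (0.15, 0.35, 0.35, 0.15), weighting the mid stages the way CRC
  series usually do. Exponential hazards keep the planted effect in
  closed form, which is what makes the coverage and power checks in the test
  suite exact statements rather than approximations.

Everything is reproducible from a single seed (the three generators use
disjoint seeded streams), and the simulation writes the same flat-file
formats the readers consume.

**What the generator does not emulate** — and hence what passing tests do not
establish about real data: platform- or batch-specific noise, compositional
effects of sequencing, correlated miRNA co-regulation, non-proportional
hazards, informative censoring, stage-dependent expression, and real miRNA
nomenclature drift. Recovery results on synthetic cohorts demonstrate that
the machinery is correct and calibrated, not that any particular real dataset
will yield similar sensitivity.

## Numerical and degenerate-input conventions

* Exact Mann–Whitney only for tie-free pooled samples of ≤ 20 values;
  otherwise the tie-corrected asymptotic form.
* Constant group → treated as non-normal; both groups constant and equal →
  p = 1.
* Log-rank with zero events in both groups → (χ² = 0, p = 1) with a warning.
* Cox non-convergence or separation → flagged result, never an exception.
* Median-split ties go to the lower group; a constant marker cannot be split
  and raises.
* BH q-values capped at 1; empty input → empty output.
* Quartiles by linear interpolation; fences inclusive.
* Correlation requires ≥ 4 complete pairs; constant vectors are flagged with
  p = 1.

## Problem sizes used by the test suite and acceptance script

Monte-Carlo checks use deliberately small designs chosen for statistical
sufficiency: null calibration over 200 replicate studies of 4 cohorts × 40
miRNAs × 15/15 samples; consensus recovery over 25 replicates of 4 cohorts ×
120 miRNAs × 30/30 samples with a −2 log2-unit shift at sd 0.5; panel
recovery over 50 replicates of a 300-patient cohort with a planted 3-miRNA
panel at log HR = log 4; correlation recovery at |ρ| = 0.9 on 100 matched
samples. The acceptance script reuses the same designs with fewer replicates
where a point estimate suffices.

## Known limitations

* The concordant-median panel rule is one defensible reading of
  "median-based" multi-marker grouping; results for specific panels can
  differ under the mean-score rule, which is why both are exposed.
* No covariate-adjusted or multivariable Cox models, no proportional-hazards
  diagnostics, no effect-size shrinkage or cross-cohort batch correction.
* Gene symbols are matched case-insensitively without alias resolution;
  miRNA aliases are resolved only through the user-supplied table.
* The hypergeometric universe is only as good as the supplied collection;
  enrichment p-values are not comparable across collections with different
  backgrounds.
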