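# Methods

This note documents the statistical models implemented in `lupusgrs`, the
choices made where the analysis design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Genotype coding and data model

Genotypes at each biallelic locus are stored as risk-allele doses 0/1/2
(NaN for missing), oriented once at ingestion: the TSV reader takes doses
directly, and the VCF reader converts GT fields using a declared risk
allele per site, so REF/ALT polarity never reaches the statistics. All
downstream computation consumes doses; nucleotide pairs are never stored.

## Hardy-Weinberg testing

The risk-allele frequency q is estimated from the observed counts;
expected counts are N·((1−q)², 2q(1−q), q²) and the Pearson statistic is
referred to χ² with 1 df (three cells minus one constraint minus one
estimated frequency). This is the asymptotic test; an exact test is not
provided because the asymptotic χ² is the stated analysis and the cell
expectations at the studied frequencies (all ≫ 5) are comfortably inside
its validity range. Monomorphic samples return χ² = 0 with a flag rather
than raising: a fixed sample trivially fits HWE. The statistic is
invariant to which allele is labelled "risk" (verified by property test).

## Dominant-model association

Carriers (dose ≥ 1) versus non-carriers per arm form a 2×2 table.

* **Odds ratio and CI.** OR = ad/bc with Woolf's log-scale interval at
  z = 1.96. On the reference cohort's printed counts this reproduces the
  published 1.54 (1.07–2.23) exactly at 2 decimals.
* **No Yates correction.** The uncorrected Pearson χ² gives p = 0.0207
  ("0.02" at printed precision) on those counts; the continuity-corrected
  statistic would give 0.0264 ("0.03"). The uncorrected test is therefore
  the one the pipeline computes, and it is also the asymptotically
  standard choice at these cell sizes.
* **Zero cells.** The Haldane–Anscombe 0.5 is added to all four cells for
  the OR and CI only, with a `continuity_corrected` flag; the χ² and p are
  left NaN in that case rather than reported from a corrected table.
* **Implementation vs oracle.** The χ² is computed from expected counts;
  tests verify it against the closed-form N(ad−bc)²/(row·column margins)
  identity on random tables, and the CI against independent log-scale
  arithmetic.

## Reference-population goodness-of-fit

Observed genotype counts are compared with fixed reference proportions
(the reference cohort is treated as error-free, the only construction
possible when its size is unknown). Two constructions exist: all three
genotype cells (2 df) or carrier-collapsed (1 df). On the study's printed
case counts against the gnomAD NFE proportions these give p = 0.0092 and
p = 0.0047 respectively; only the carrier-collapsed construction matches
the reported significance level (0.005), and since it is also the
construction congruent with a dominant-model analysis it is the default
(`mode="dominant_collapse"`). Both modes remain available and the chosen
mode is echoed into every report. Expected cells below 1 set a warning
flag.

## Weighted genetic risk score

S = Σⱼ gⱼ·wⱼ with wⱼ the per-locus odds ratio. Two deliberate departures
from generic polygenic-score practice, both following the source analysis:

* **Raw OR weights**, not ln(OR). A `weight_transform="log"` switch
  provides the conventional weighting for sensitivity analysis; the
  default matches the source definition ("sum of the products of the
  number of risk alleles and their respective ORs").
* **Half-up rounding** of the raw score to a whole number (5.5 → 6),
  the reading of "nearest whole number" least surprising to a biomedical
  reader; banker's rounding is not used.

Classes are low (rounded ≤ 2), mid (3–4, defined by complement of the two
published cut points) and high (≥ 5). Between-arm comparisons are 2×2
Pearson χ² tests on the low-threshold and high-threshold dichotomies,
reusing the same χ² core as the association module; inner strata are
never tested in isolation, so empty classes are harmless.

Missing genotypes: a subject's score is computed over observed loci; a
subject missing more than 1/6 of loci is flagged and excluded from class
comparisons and histograms (with six loci: one missing genotype is
tolerated, two are not). The raw-OR weighting makes scores of subjects
with different missingness patterns not strictly comparable; the
exclusion rule bounds that distortion.

Only the rs2836882 weight (1.54) is a cohort-derived estimate reproduced
here. The five companion-locus weights shipped in
`default_weight_specs()` are placeholders at literature-plausible values,
clearly marked as such, and must be overridden with cohort estimates for
any real analysis; consequently the score distribution and threshold
p-values are reproducible in shape but not numerically.

## qPCR relative quantification

Technical replicates are collapsed to their per-sample mean before any
inference — the biological sample is the only defensible inferential
unit, so reported standard errors are between-sample SEs of the
per-sample fold changes. ΔCt = mean target − mean reference Ct;
ΔΔCt subtracts the calibrator group's mean ΔCt; relative expression is
2^−ΔΔCt with the amplification base fixed at 2 (efficiency-corrected
quantification is out of scope). The calibrator defaults to the
non-carrier (wild-type) genotype group, so the calibrator's mean ΔΔCt is
0 by construction and its geometric-mean fold change exactly 1.

Group comparisons are one-way fixed-effects ANOVA computed by direct
sum-of-squares decomposition (cross-checked against `scipy.stats.f_oneway`
and, for two groups, against the squared pooled-variance t statistic).
The ANOVA runs on the fold-change scale by default, matching comparisons
of reported relative-expression values; because fold changes are
right-skewed, a `scale="log2"` option (equivalently −ΔΔCt) is provided.
Degenerate inputs are flagged rather than NaN-propagated: identical
groups give F = 0, p = 1; separated constant groups give infinite F with
p reported as 0. Clinical-feature comparisons are the same two-group
ANOVA restricted to cases. The disease-activity correlation defaults to
Spearman (activity indices are ordinal); Pearson is available.

## Synthetic cohort generator

Population genotypes are drawn per locus under HWE at the locus's
source-population risk-allele frequency (loci independent — linkage
disequilibrium, haplotypes and population stratification are not
modelled). Disease status is Bernoulli with
logit p = logit(π₀) + Σⱼ βⱼ xⱼ, where βⱼ = ln(ORⱼ) and xⱼ is the dose
(additive model) or carrier indicator (dominant model). Arms are filled
by rejection sampling from this population model — exact for multi-locus
models and easy to audit — with a cap of 10⁶ population draws per
unfilled arm before a `QuotaError` naming the arm.

Defaults mirror the reference study: 246 cases, 216 controls, the
six-locus panel, and baseline prevalence π₀ = 0.001 (the order of
magnitude of SLE prevalence). Two facts about this construction are worth
stating because the calibration routines rely on them: under the null
(all OR = 1) genotypes are independent of case status for any intercept,
and under a dominant alternative the carrier odds ratio estimand equals
exp(β) exactly at any prevalence (odds-ratio symmetry; controls are
sampled from non-cases). The Monte-Carlo calibration helpers therefore
pass a larger intercept (0.1–0.2) to keep rejection sampling cheap over
1000 replicates without changing any quantity being measured.

Note the two distinct uses of odds ratios: the disease model uses ln(OR)
on the logit scale (the standard epidemiological construction), while the
risk score deliberately weights by raw OR as described above.

The expression generator draws, per sample, replicate reference Cts from
Normal(20, σ) and target Cts from Normal(20 + ΔCt_group, σ), with
ΔCt_group = 5 cycles for non-carriers (target less abundant than a
housekeeping reference) plus a −1 cycle carrier shift (a twofold
increase, the direction reported for risk-allele carriers) and σ = 0.2
cycles of technical noise; 15 samples per genotype-by-phenotype cell
(30 cases + 30 controls) in triplicate. The reference mean of 20 cycles
is arbitrary and cancels in ΔCt.

What the generators do **not** emulate: linkage disequilibrium between
loci, genotyping error and missingness mechanisms, amplification
efficiency differences between genes, inter-run plate effects, outlier
replicates, covariates (age, sex, treatment) and cell-composition
heterogeneity. Passing calibration on synthetic data therefore shows the
statistics are implemented correctly and hold their nominal error rates
under the stated model, not that real data meet that model's assumptions.

## Problem sizes and numerical conventions

Monte-Carlo routines: type-I calibration uses 1000 replicate cohorts at
246/216; OR recovery uses 200 seeds; expression direction checks use
100–200 seeds — sizes at which the Monte-Carlo standard errors (≈ 0.7
percentage points on a 5% rate; ≈ 0.013 on the mean log OR) are small
against the effects being checked, while a full run stays in the tens of
seconds. All replicate seeds are spawned from one master seed via
`numpy.random.SeedSequence` (kept below 2³¹); each simulate call owns its
generator and no global RNG state is touched.

Display formatting follows conventional association-table precision
(OR/CI to 2 decimals, percentages to 1 decimal half-up, p-values to 2
decimals with a "<0.00001" floor); JSON reports keep full precision.
"Zero" sums of squares in the ANOVA are detected at a relative tolerance
of 1e-12 against the total sum of squares.

## Known limitations

Single-variant dominant analysis only (no allelic/trend/recessive tests,
no covariate-adjusted logistic regression, no multiple-testing
correction — none were part of the source design); fixed-proportion
goodness-of-fit only; no LD-aware score construction or score-performance
validation (AUC); no efficiency-corrected or multi-reference qPCR
normalisation. The companion-locus score weights are placeholders, as
noted above.
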