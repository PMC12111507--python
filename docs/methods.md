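# Methods

This note documents the statistical models implemented in `eopmeth`, the
design choices that were genuinely open, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## Association model (EWAS)

The default per-CpG model regresses methylation on the group indicator plus
covariates by ordinary least squares and reports the group coefficient:

    meth_i ~ intercept + b·group + c1·age + c2·sex + d1..dk·SV

With β-values as input, `b` is a β-scale between-group methylation
difference, the scale on which array-EWAS effect sizes of this kind are
conventionally reported (effects of magnitude 0.2–0.6 with SEs of 0.03–0.09
at n ≈ 23), and the Wald statistic is `t = b/SE`. Two-sided p-values use
Student's t with `df = n − #coefficients` rather than a normal reference:
at n ≈ 23 with eight fitted coefficients the normal approximation is
materially anticonservative. A logistic orientation (group as response, CpG
as predictor, z reference) is available behind `mode="logistic"`; on planted
cohorts the two orientations agree in sign and significance ordering, and
the OLS orientation is the default because its effect column has the
interpretable β-difference scale. Constant CpG rows are skipped and flagged,
never fitted. Covariates are screened with variance inflation factors before
fitting; exact collinearity is an error, not a warning.

Genomic inflation is `λ = median(χ²₁(1 − p)) / 0.454936`; QQ data pair the
sorted observed p against expected quantiles `(i − 0.5)/n`.

## Surrogate variables

The batch-correction covariates are estimated by residual PCA with
rescoring: latent CpG-space directions are the left singular vectors of the
matrix of residuals after removing the group mean from every CpG row, and
the surrogate variables are the scores of the *original* (row-centered) data
along those directions, orthonormalized and scaled to unit variance.

The rescoring step is essential and easy to get wrong. Scores confined to
the residual space are exactly orthogonal to the group indicator by
construction, so including them in the association model cannot remove
chance confounding between latent batch structure and group — it only
shrinks residual variance and hence standard errors, which *inflates* the
test statistics (on null synthetic cohorts: type-I error ≈ 0.48, λ ≈ 7).
Scoring the original data on residual-derived directions preserves the
batch/group correlation that needs adjusting; with it, null cohorts are
calibrated (type-I ≈ 0.05, λ ≈ 1.0, uniform p-values). Whether SVs are
computed on the β or M scale is configurable; M is the default (variance
stabilized). The default k = 5 follows common practice for small array
cohorts.

## Methylation risk score

CpGs are stratified by EWAS p-value cutoffs (default 1e-6 … 1e-1, strict
inequality, so the sets are nested). Per sample,

    MRS_s = Σ_{i: p_i < t} M_is · Z_i,     Z_i = effect_i / SE_i

then standardized across samples with the n−1 SD. The score deliberately
sums M-values even though the association model fits β-values — this is the
published construction of the score this package implements; a β-scale
variant is one argument away for users who prefer scale consistency.
Weights are reused in-sample by default (EWAS and MRS on the same cohort),
which overfits — the association p-values for MRS/phenotype models on the
training cohort are descriptive, not confirmatory. External weight tables
are accepted for replication designs.

Phenotype associations put the phenotype on the left-hand side (the MRS is
the predictor). Binary phenotypes use maximum-likelihood logistic
regression; under complete or quasi-complete separation — near-certain at
n ≈ 23 for rare symptoms — the fit falls back to Firth's bias-reduced
likelihood (Jeffreys-prior score correction), which has finite estimates
under separation, and the row is flagged `separation_firth`. Nothing falls
back silently.

## Epigenetic clocks

A clock is `raw_s = intercept + Σ w_i β_is`, optionally inverted through the
Horvath age transform (log-linear below `adult_age`, linear above):

    inverse(x) = (A+1)·exp(x) − 1   if x < 0
                 x·(A+1) + A        if x ≥ 0

Telomere-length clocks are identity-transform models with kilobase units;
pace-of-aging clocks are unitless rates. Published clock coefficients are
consumed from coefficient files (`#name=`, `#intercept=`,
`#transform=identity|horvath:20`, `#units=`, then `cpg,weight` rows); none
are bundled. Missing clock CpGs are an error by default; the `mean_impute`
policy substitutes the per-sample mean β of the clock CpGs that are present
— a pragmatic stand-in when a training-set mean is unavailable, adequate
when few weights are missing.

Age acceleration is the residual of epigenetic age regressed on
chronological age (mean zero, shift-invariant). Clock/trait correlations use
Pearson when both variables pass Shapiro-Wilk at α = 0.05 and Spearman
otherwise, recording the method per cell; binary and skewed count traits
therefore land in the Spearman branch automatically.

Stepwise clock-phenotype regressions start from the intercept-only model and
take the best single addition or removal by information criterion until no
move improves it. AIC is the default; BIC is selectable. A caution for users
reading the selected models: with AIC each pure-noise candidate survives
with probability ≈ 0.16, so at four or five candidates roughly half of all
fits retain at least one noise term; BIC at n = 100 reduces that to ≈ 3%
per candidate (so even BIC selects *exactly* the true model only ~87% of the
time with four noise candidates). Genuinely strong predictors (R² ≈ 0.9)
are retained essentially always under either criterion. Retained terms are
reported with Wald 95% CIs at the model's residual df.

## Cohort statistics

- `t_test_from_summary` implements Welch (Satterthwaite df, the default) and
  pooled variants from (n, mean, SD) triples, so comparisons are exactly
  reproducible from printed summary tables. Note that summaries rounded for
  publication bound the recoverable precision of p: expect agreement to
  about one unit in the last printed digit.
- `mann_whitney` uses exact enumeration when `n1·n2 ≤ 400` and there are no
  ties, else the tie-corrected normal approximation without continuity
  correction (so identical samples give p = 1 exactly).
- `fisher_exact_2x2` computes hypergeometric table probabilities in exact
  rational arithmetic and applies the minimum-likelihood two-sided rule
  (sum of probabilities of all margin-fixed tables no more probable than the
  observed one). This rule — not the tail-doubling rule — reproduces the
  printed p-values of the clinical comparison tables this package's checks
  recompute.
- `chi2_or_fisher` switches to the exact test when any *expected* count is
  below 5 (the standard reading of the "values < 5" convention) and reports
  which branch fired. The χ² branch applies no continuity correction.
- `table1_report` renders mean ± SD + t for continuous variables,
  median (min–max) + Mann-Whitney for counts, and n (%) + χ²/Fisher for
  binaries, with within-group percentages.

## Synthetic cohorts

`generate_cohort` builds β on the logit scale: per-CpG baseline logit(p0)
with p0 ~ U(0.1, 0.9); causal CpGs (baseline restricted to U(0.3, 0.7)) get
group means logit(p0 ± Δ/2) with random sign, so cases and controls differ
by Δ in expectation on the β scale; clock CpGs respond linearly in
normalized age with logit slopes ±U(0.6, 1.0); every CpG receives latent
batch structure (Gaussian loadings × per-sample scores) and residual noise
whose β-scale SD is `noise_sd` (mapped through the local derivative
p(1−p), capped at 0.8 logits). The logistic push-forward guarantees
β ∈ (0, 1) with no clipping, at the cost of a small (~5%) Jensen shrinkage
of the realized β-scale effect relative to Δ — visible in recovery tests and
well within their 20% band.

Defaults mirror a small adolescent cohort: 12 cases / 11 controls,
10,000 CpGs, 8 causal CpGs of Δ = 0.15, two latent components
(loading SD 0.3), ages U(10, 18), 50 clock CpGs, β-scale noise SD 0.05.
Phenotypes depend on group through documented coefficients: GAF
75 − 30·group + N(0, 8); admissions Poisson(0.2 + group); comorbidity count
1 + Poisson(0.6 + 0.6·group); binary symptom flags Bernoulli(expit(b0 +
b1·group)) with b1 between 1.5 and 2.6 (see `_PHENO_LOGIT`); schooling
tracks age. Ages and sex are independent of group so that EWAS covariate
adjustment is testable without confounding by design.

`generate_clock_fixture` shares the clock-CpG random stream with
`generate_cohort` (same seed ⇒ same parameters) and inverts each CpG's
linearized read-out: weight `w_i = slope / (n · p_i(1−p_i) · b_i)` so the
clock's raw output is an unbiased average estimate of (transformed) age.
Horvath-transform fixtures linearize the forward transform across the age
range; the inverse transform then reproduces ages exactly on noiseless
input and with r > 0.99 on simulated cohorts.

What the generator does **not** emulate: Illumina probe chemistry and
type-1/type-2 probe differences, detection failures, cell-type composition,
genome-realistic CpG coordinates or correlation along the chromosome
(annotation positions are random), SNP-contaminated probes, and
ancestry/pubertal covariate structure. Passing tests therefore demonstrate
the statistical machinery is correct under the stated generative model, not
that any particular biological finding replicates.

## Numerical conventions and problem sizes

- M-value offset default 1e-6 (keeps boundary β finite); the β↔M maps are
  exact inverses at equal offset to 1e-10 on [0.01, 0.99].
- Low-variability filter: across-sample SD (ddof = 1) below 0.01 by default;
  the rule is a config value since only its outcome, not its definition, is
  conventionally reported.
- All simulator randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawns (cohort / clock / phenotype streams);
  identical configs are bit-reproducible, and pipeline reruns are
  byte-identical because all floats are written with a fixed format.
- Test and acceptance problem sizes were chosen as the smallest that make
  the stochastic assertions stable across seeds: null calibration at
  5,000 CpGs × 100 samples, effect recovery at 2,000 × 200, stepwise
  properties at n = 100 × 100 replicates, determinism at the default
  10,000 × 23 scale. The full suite runs in well under a minute.

## Known limitations

- The logistic mode loops statsmodels fits per CpG; it is meant for
  candidate sets, not array-scale scans.
- Firth SEs use the Wald approximation; profile-likelihood CIs are not
  implemented.
- `mean_impute` for missing clock CpGs is a crude stand-in for
  training-mean imputation and will bias clocks with many missing probes.
- In-sample MRS association p-values are optimistic by construction; use
  external weights for anything confirmatory.
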