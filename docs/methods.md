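# Methods

## The analysis

`chronoprs` implements a three-part analysis of how a polygenic score for
schizophrenia relates to illness chronicity and case-control prediction
accuracy:

1. **Case-only chronicity association.** For each of four chronicity
   markers — total, inpatient, and outpatient health-care contacts and
   cumulative hospitalization length in days — the marker is annualized by
   follow-up time, variance-stabilized, z-scored, and regressed on the
   standardized genomic risk profile score (GRPS) with ordinary least
   squares, adjusting for ancestry principal components, genotyping batch,
   age at diagnosis, and sex. Sex-stratified fits drop the sex covariate;
   the moderation analysis adds a GRPS × sex product term.
2. **Chronicity enrichment of case-control prediction.** The prediction
   statistic is the incremental Nagelkerke pseudo-R²: NkR²(case ~ PCs +
   GRPS) − NkR²(case ~ PCs), each measured against the intercept-only
   model, with NkR² = Cox–Snell R² divided by its attainable maximum
   1 − exp(2·ll₀/n). Cases are filtered at above-average chronicity
   thresholds (≥27 total contacts, ≥12 inpatient contacts, ≥19 outpatient
   contacts, or ≥640 hospitalization days; controls are never filtered) and
   the matched-subsample permutation test asks whether the filtered
   subsample's incremental NkR² exceeds that of random case subsets of the
   same size: each of n_perm draws replaces the filtered cases with a
   uniform without-replacement case subset, and
   p_perm = (1 + #{perm ≥ observed}) / (n_perm + 1).
3. **Sex prediction gap.** The observed statistic is the male-only minus
   female-only incremental NkR² (each sex's cases and controls); the null
   distribution permutes sex labels across all individuals, and the
   two-sided empirical p uses the same add-one convention.

Design choices where the wording of the underlying procedure is open, all
switchable in code:

- "Admissions weighted by follow-up time" is operationalized as an
  annualized rate outcome, z(log1p(marker / follow-up years)), rather than
  a weighted least-squares or offset scheme (`transform="raw_z"` disables
  it). The log1p tames the heavy right tail of the count markers (their
  registry sds exceed their means).
- The p-value threshold is strict (discovery p < PT); PT ∈ {0.05, 0.1,
  0.01} are reported with 0.05 primary.
- Enrichment p-values are one-sided (the hypothesis is improvement); the
  sex gap is two-sided.
- The case-control null model uses PCs only; batch can be added via
  `include_batch`.
- The four chronicity filters are evaluated one at a time, producing four
  subsamples rather than one union.
- Incremental (difference) NkR² is the primary statistic; the full-model
  NkR² is also reported.

## The synthetic cohort

No individual-level registry or genotype data are public for this design,
so a liability-threshold generator stands in for them and defines the study
conditions:

- M independent biallelic variants with effect-allele frequencies uniform
  on [0.05, 0.5]; true standardized effects β ~ N(0, h²/M), so the genetic
  value G has liability variance h² (default 0.24, a common-SNP estimate
  for schizophrenia). No LD, no imputation noise, no population-structure
  confounding: principal components are pure noise by default.
- The discovery GWAS is emulated at the summary level: estimated per-allele
  effect = true effect + N(0, se²) with se = 1/√(2p(1−p)·n_discovery)
  (default n_discovery = 77,000), p-values two-sided Wald.
- Liability = G + E with E ~ N(0, 1−h²); the female environmental variance
  can be inflated by `female_noise_inflation` (default 1), modelling weaker
  genetic determination of illness in women. Cases exceed the
  (1−prevalence) quantile of the base N(0,1) liability distribution
  (default prevalence 1%).
- Rejection sampling fills the ascertained cohort: 2,457 cases and 2,702
  controls with the registry sex split (897 F / 1,560 M cases, 1,286 F /
  1,416 M controls), within a hard draw budget (default 10⁷ candidates).
- Case chronicity: counts are negative binomial with log-mean
  a + b·g_std (+ sex shift), g_std = G/√h²; hospitalization length is
  log-normal likewise. Outpatient contacts are genetically decoupled
  (b = 0) by default, mirroring the null finding the analysis is designed
  to detect. Follow-up (truncated normal, mean 22 y, sd 8.22) and age at
  diagnosis (mean 28, sd 7.15) are drawn independently of liability.
- Sex shifts: males accumulate longer hospitalizations (+0.336 on the log
  scale) and females more outpatient contacts (+0.127), taken from the
  registry's sex-specific descriptive ratios.

### Calibration

Intercepts a and dispersions are calibrated so one default cohort
reproduces the registry case descriptives: mean total contacts ≈ 27.4,
inpatient ≈ 11.5, outpatient ≈ 18.9, hospitalization length ≈ 642 days
(male ≈ 713, female ≈ 509), follow-up ≈ 22 years. Negative-binomial sizes
(0.82, 0.75, 0.57) and the log-normal sigma (1.0) are back-solved from the
published mean/sd pairs.

The coupling slopes (b = 0.35 for total/inpatient/length, 0 for outpatient)
are set so the *enrichment pattern* of the original study emerges reliably:
chronicity-filtered case subsamples must beat the full sample's incremental
NkR² despite the composition handicap — Nagelkerke R² mechanically falls
when the case fraction drops, so a random case subset scores below the full
sample, and the genetic enrichment must overcome that deficit. Weaker
coupling (slopes that would reproduce the published case-only regression
coefficients of ~0.08 under this independent negative-binomial noise model)
does not clear the handicap; the published enrichment gain itself implies a
stronger effective marker–liability coupling than its case-only
coefficients do under such a model. Consequence: the simulated case-only
GRPS coefficients are ~0.2 per SD of score — the same sign and significance
pattern as the original analysis, but larger in magnitude. The default
score is also stronger than the original study's (full-sample incremental
NkR² ≈ 0.27 versus ≈ 0.13) because the emulated discovery panel has no LD
dilution. Numeric reproduction of the original coefficients is explicitly
not claimed.

### What the generator does not emulate

Linkage disequilibrium and clumping, imputation uncertainty, ancestry
confounding, genotyping batch effects (batch labels are pure noise),
follow-up-dependent marker accumulation (markers are drawn at the cohort
level, not as per-year processes), and registry artefacts such as the
published descriptive table's internally inconsistent outpatient cells.
Passing tests therefore demonstrate the statistical machinery and its
calibration under these idealized conditions, not performance on real
registry data.

## Numerical choices

- Genotypes are drawn as exact Binomial(2, p) via single-uniform quantile
  inversion (fast path for the ~2.5·10⁵ candidate draws the default
  ascertainment needs).
- Logistic models inside permutation loops are fit by an internal
  Newton–Raphson with step-halving (tolerance 1e-12 relative
  log-likelihood change, 60 iterations), intercept-initialized at the
  logit of the case fraction; quasi-complete separation (unbounded linear
  predictor while still improving) and non-convergence raise explicit
  errors. The log-likelihoods agree with statsmodels to <1e-8.
- A GRPS with zero variance is dropped as aliased and contributes an
  incremental NkR² of exactly 0; rank-deficient OLS designs raise an error
  naming the aliased columns (pivoted-QR diagnosis).
- Permutation subsets are sorted before refitting so identical subsets give
  bit-identical statistics (stable tie handling in p_perm).
- All randomness descends from one seed through per-stage child streams
  (sumstats, genotypes, chronicity, demographics, covariates, orientation,
  missingness), so enlarging the variant panel does not perturb the
  phenotype draws.
- Strand-ambiguous variants (A/T, C/G) are dropped by default during
  harmonization; missing dosages are imputed as 2 × target-sample
  effect-allele frequency.

## Problem sizes

The shipped `scaled_down_config` preset (600 cases / 660 controls, 300
variants, discovery n = 20,000, prevalence 4%, 3 PCs) is the package's
desk-scale condition for simulation studies; the type-I-error study uses
200 replicates at 300/330, the enrichment-pattern study 50 replicates at
2,000/2,200 (prevalence 2%, where Monte-Carlo noise no longer masks the
direction of the enrichment gain), the sex-gap study 50 replicates at
1,200/1,320, and the slope-recovery study 100 replicates of 2,000 cases. The registry-scale
default configuration is used for the calibration checks and the
acceptance script.

## Known limitations

- The composition handicap means incremental NkR² values are comparable
  only between samples of similar case fraction; the matched-size
  permutation test is the principled comparison, and the filtered-vs-full
  contrast should be read through it.
- The negative-binomial/log-normal chronicity model is cross-sectional;
  real admission counts are recurrent events over follow-up.
- The internal logistic fit assumes a full-rank null design; batch
  indicators with empty levels in small subsets would need pruning before
  enabling `include_batch` at very small n.
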