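# chronoprs

Polygenic risk-profile scores, illness chronicity, and sex differences in
case-control prediction — as a tested, reusable pipeline on synthetic
liability-threshold cohorts.

## The problem

Genomic risk profile scores (GRPS, a.k.a. polygenic risk scores) for
schizophrenia — weighted allele sums `score_i = Σ_j β_j · dosage_ij` over
discovery-GWAS variants passing a p-value threshold PT — predict
case-control status, but their accuracy depends on who the cases are.
Registry studies report that GRPS associate with illness *chronicity*
(health-care contacts, hospitalization length), that enriching the case
sample for chronic patients raises the variance explained, and that
prediction is markedly better in men than in women. Individual-level
registry and genotype data behind such findings are not public, so this
package pairs the full analysis stack with a calibrated liability-threshold
simulator that reproduces the published cohort's descriptive structure
(2,457 cases / 2,702 controls, registry sex split, case chronicity
marginals, 22-year mean follow-up).

It is aimed at statistical-genetics researchers who want to study the
behaviour of these analyses — composition effects on pseudo-R², power of
matched-subsample permutation tests, sex-differential architectures —
under controlled, reproducible conditions.

## What it computes

- **Scoring** (`chronoprs.scoring`): allele harmonization (keep / flip /
  drop with reasons, strand-ambiguous A/T–C/G filtering), thresholded
  weighted allele sums at PT ∈ {0.05, 0.1, 0.01}, standardization.
- **Case-only association** (`chronoprs.association`): OLS of
  z(log1p(marker / follow-up years)) on the standardized GRPS with PC,
  batch, age-at-diagnosis, and sex adjustment; sex-stratified fits and a
  GRPS × sex interaction.
- **Enrichment and sex gap** (`chronoprs.enrichment`): incremental
  Nagelkerke pseudo-R² of the GRPS over a PC-only logistic null,
  `NkR² = (1 − e^{2(ll₀−ll₁)/n}) / (1 − e^{2ll₀/n})`; chronicity filters
  (≥27 total / ≥12 inpatient / ≥19 outpatient contacts, ≥640 days
  hospitalized); matched-subsample permutation p-values with the add-one
  convention `p = (1 + #{perm ≥ obs})/(n_perm + 1)`; male−female NkR² gap
  with a sex-label permutation null.
- **Simulation** (`chronoprs.simulate`): seeded, calibrated generator for
  discovery summary statistics and ascertained case-control cohorts with
  chronicity coupled to genetic liability (outpatient contacts decoupled).

See `docs/methods.md` for the model, calibration, and design choices.

## Worked example

Run the whole pipeline at desk scale and inspect the report:

```
$ chronoprs run --seed 7 --config examples/scaled.yaml --n-perm 500 --out report/
report written to report/ (config 7cf92b8585e2)

$ column -t report/enrichment.tsv
# config_hash=7cf92b8585e2
# seed=7
subsample         n_cases  nkr2                 p_perm
full              600      0.2335117240420991
n_total           210      0.27757682672758627  0.001996007984031936
n_inpatient       215      0.23534461638189547  0.011976047904191617
n_outpatient      219      0.19549712205813613  0.46706586826347307
hosp_length_days  172      0.24595293425281467  0.001996007984031936
females           219      0.24078552553608418  0.6307385229540918
males             381      0.22106380075336157  0.6307385229540918
```

Reading: on this synthetic cohort the GRPS adds ~0.23 incremental NkR² over
the PCs. Restricting cases to those with ≥27 total contacts (210 of 600
cases) raises it to ~0.28, and random case subsets of the same size beat
that only rarely (p_perm ≈ 0.002); inpatient contacts and hospitalization
length behave the same way. The outpatient filter — genetically decoupled
in the generator — shows no improvement over matched random subsets
(p_perm ≈ 0.47). With equal male and female environmental noise (the
default), the sex gap is small and non-significant (p_perm ≈ 0.63); set
`female_noise_inflation: 2.0` in the config to simulate a sex-differential
architecture and watch the male advantage emerge.

The same stages are available individually (`chronoprs simulate`, `score`,
`associate`, `enrich`, `sexgap`) and as library calls:

```python
from chronoprs import (default_config, simulate_summary_stats, simulate_cohort,
                       score_genotypes, incremental_nkr2)
cfg = default_config(seed=1)
ss = simulate_summary_stats(cfg)
geno, pheno, covars = simulate_cohort(cfg, ss)
grps = score_genotypes(geno, ss, pt=0.05)
print(incremental_nkr2(pheno, grps, covars))
```

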