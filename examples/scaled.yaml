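age_mean: 28.0
age_sd: 7.15
chronicity_links:
  hosp_length_days:
  - 5.23
  - 0.35
  - 1.0
  n_inpatient:
  - 1.965
  - 0.35
  - 0.75
  n_outpatient:
  - 2.884
  - 0.0
  - 0.57
  n_total:
  - 2.82
  - 0.35
  - 0.82
draw_budget: 10000000
female_noise_inflation: 1.0
followup_mean_years: 22.0
followup_sd_years: 8.22
h2_liability: 0.24
maf_range:
- 0.05
- 0.5
missing_rate: 0.0
n_batches: 3
n_cases: 600
n_controls: 660
n_discovery: 20000
n_pcs: 3
n_variants: 300
prevalence: 0.04
prop_female_cases: 0.36507936507936506
prop_female_controls: 0.4759437453737972
seed: 7
sex_shifts:
  hosp_length_days:
  - M
  - 0.336
  n_outpatient:
  - F
  - 0.127
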