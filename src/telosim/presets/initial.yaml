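cohort_size: 140
cutpoints:
- 0.5
- 1.5
demographics:
  age_max: 35
  age_mean: 23.6
  age_min: 18
  age_sd: 3.8
  diet_probs:
  - 0.35
  - 0.45
  - 0.2
  p_female: 0.5
density:
  lower: 150.0
  mean: 185.0
  sd: 28.0
  upper: 220.0
exposure:
  cap: 5.0
  p_nonuser: 0.2
  scale: 0.3919392523364485
  shape: 3.412518628912072
likert:
  item_corr: 0.118
  items_per_domain: 3
  levels: 5
  n_domains: 3
  thresholds:
  - -0.05
  - 0.674
  - 1.227
  - 1.751
outcomes:
  beta_D: 13.0
  beta_S: 0.73
  sigma_eta: 6.0
  sigma_upsilon: 0.1
oxload:
  alpha_diet: 0.25
  alpha_sex: 1.07
  alpha_x: 1.0
  sigma_eps: 1.34
preset: initial
seed: 20240
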