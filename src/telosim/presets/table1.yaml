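cohort_size: 140
cutpoints:
- 0.5
- 1.5
demographics:
  age_max: 35
  age_mean: 26.0
  age_min: 18
  age_sd: 3.0
  diet_probs:
  - 0.35
  - 0.45
  - 0.2
  p_female: 0.4
density:
  lower: 150.0
  mean: 185.0
  sd: 28.0
  upper: 220.0
exposure:
  cap: 5.0
  p_nonuser: 0.2059170627164357
  scale: 0.3943243884777448
  shape: 3.4214131358714033
likert:
  item_corr: 0.13267478495863308
  items_per_domain: 3
  levels: 5
  n_domains: 3
  thresholds:
  - 0.05471380935108457
  - 0.7787138093510846
  - 1.3317138093510847
  - 1.8557138093510845
outcomes:
  beta_D: 12.388608869725712
  beta_S: 0.6400329655021973
  sigma_eta: 3.0000000000000004
  sigma_upsilon: 0.10000000000000002
oxload:
  alpha_diet: 0.15
  alpha_sex: 1.209186983966922
  alpha_x: 1.0
  sigma_eps: 1.3722846061292235
preset: table1
seed: 20240
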