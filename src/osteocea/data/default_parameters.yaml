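# Default model inputs: Chinese postmenopausal osteoporosis cost-effectiveness
# model, all monetary values in 2022 USD (average 2022 exchange rate
# 6.7321 CNY/USD recorded as metadata only; no conversion is performed).
#
# Femoral-neck BMD by starting-age band: survey means/SDs (g/cm^2).
bmd_bands:
  - {age_low: 55, age_high: 59, mean_bmd: 0.73, sd_bmd: 0.13, n: 3152}
  - {age_low: 60, age_high: 64, mean_bmd: 0.66, sd_bmd: 0.12, n: 3155}
  - {age_low: 65, age_high: 69, mean_bmd: 0.58, sd_bmd: 0.11, n: 925}
  - {age_low: 70, age_high: 74, mean_bmd: 0.55, sd_bmd: 0.13, n: 137}

# Relative risks of re-fracture given any prior fracture (meta-analytic,
# log-normal in PSA) and the probability that a hip fracture leads to the
# bedridden state (published range 0.095-0.177 swept in DSA, fixed in PSA).
fracture_risk:
  rr_prior_fracture_hip: 1.97        # 95% CI 1.12-3.48
  rr_prior_fracture_vertebral: 1.91  # 95% CI 1.50-2.43
  rr_prior_fracture_other: 1.91      # 95% CI 1.50-2.43
  p_bedridden_after_hip: 0.136

# Treatment effect: femoral-neck BMD increment attained over a 6-month
# course, and the annual drug acquisition cost (the model charges
# annual_drug_cost x treatment_time by default).
# NOTE: the network meta-analysis behind these inputs reports a femoral-neck
# mean difference of 0.17 (0.06-0.29) for Xianling Gubao; the parameter table
# of the source analysis uses 0.05 (0.01-0.08), which is what ships here.
treatments:
  no_treatment:
    name: "No Treatment"
    bmd_increment: 0.0
    treatment_time: 0.5
    annual_drug_cost: 0.0
  xianling_gubao:
    name: "Xianling Gubao Treatment"
    bmd_increment: 0.05   # range 0.01-0.08, beta on [0, 0.3] g/cm^2
    treatment_time: 0.5
    annual_drug_cost: 93.24
  jintiange:
    name: "Jintiange Treatment"
    bmd_increment: 0.11   # range 0.03-0.19, beta on [0, 0.3] g/cm^2
    treatment_time: 0.5
    annual_drug_cost: 574.82

# Direct medical costs (2022 USD); all swept +/-20%, triangular in PSA.
costs:
  annual_medical_cost: 439.78
  cost_hip_fracture: 7379.82
  cost_vertebral_fracture: 1361.12
  cost_other_fracture: 1758.30
  annual_bedridden_cost: 4948.90

# Utilities: EQ-5D baseline by age band; disutility multipliers by fracture
# site, first year vs later years; flat bedridden utility.
utilities:
  baseline_utility_by_age:
    "55-59": 0.88    # 0.862-0.897
    "60-65": 0.869   # 0.852-0.885
    "66-70": 0.827   # 0.802-0.851
    "71-74": 0.808   # 0.770-0.846
  hip_multiplier_year1: 0.776        # 0.720-0.844
  hip_multiplier_later: 0.855        # 0.800-0.909
  vertebral_multiplier_year1: 0.724  # 0.667-0.779
  vertebral_multiplier_later: 0.868  # 0.827-0.922
  other_multiplier_year1: 0.910      # 0.880-0.940
  other_multiplier_later: 1.0
  bedridden_utility: 0.192

analysis:
  discount_rate_cost: 0.03   # DSA range 0-0.05
  discount_rate_qaly: 0.03   # DSA range 0-0.05
  wtp_threshold: 38223.0     # three times GDP per capita, USD/QALY
  n_individuals: 100000
  n_psa_iterations: 1000
  max_age: 100
  rng_seed: 0
  annual_bmd_decline: 0.0
  medical_cost_all_alive: true
  full_annual_drug_cost: false

metadata:
  currency: "2022 USD"
  cny_per_usd_2022: 6.7321
  fixture: "params_table2_2022usd"
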