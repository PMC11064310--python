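# Default synthetic-cohort configuration: covariate marginals, dietary
# intake model, outcome model, and status-conditional neuropsych model for
# a pooled two-study sample of Malaysian older adults (n = 810).
n: 810
source_counts:
  lrgs_tua: 579
  frgs: 231

covariates:
  age: {mean: 67.9, sd: 4.7, min: 60.0}
  education_years: {mean: 7.7, sd: 4.2, min: 0.0}
  bmi: {mean: 25.6, sd: 4.2, min: 13.0}
  iadl: {mean: 13.0, sd: 1.5, min: 0.0, max: 14.0}
  # log-normal, moment-matched (printed sd exceeds the mean)
  household_income: {mean: 1724.1, sd: 2096.7}
  male: 0.481
  malay: 0.657
  hypertension: 0.373
  diabetes: 0.201
  hyperlipidemia: 0.316
  smoking: 0.263
  # GDS-15 ~ Poisson(lambda) truncated to [0, 15]; lambda solved so
  # P(GDS >= gds_cutoff) matches this prevalence
  depressive_symptoms: 0.078
  gds_cutoff: 5
  dementia: 0.0
  memory_complaint: {mci: 0.90, non_mci: 0.30}

# Weekly intakes per food group ~ Gamma(shape, scale); scale is solved per
# component so the expected component score hits its target mean.
intake_model:
  shape: 2.0
  score_targets:
    whole_grains: 0.12
    green_leafy: 0.73
    other_vegetables: 0.48
    flavonoid_fruits: 0.49
    deep_sea_fish: 0.57
    legumes_soy: 0.30
    poultry: 0.54
    desserts_kuih: 0.77
    butter_margarine: 0.92
    red_meat: 0.91
    fried_fast_foods: 0.59
  total_target: 6.41

# Binary-outcome logistic model; coefficients are log odds ratios, the
# intercept is solved numerically for the target marginal prevalence.
outcome_model:
  prevalence: 0.302
  k_groups: 4
  odds_ratios:
    "group:T2": 0.52
    "group:T3": 0.50
    "group:T4": 0.43
    age: 1.04
    education_years: 0.93
    household_income: 1.00
    smoking: 0.91
    iadl: 0.98
    gds15: 1.20
    hypertension: 1.99
    diabetes: 1.19
    bmi: 1.22

# (mean, sd) per test conditional on outcome status; draws truncated to
# instrument bounds, location solved so the truncated mean hits the target.
neuropsych_model:
  mmse: {non_mci: [25.4, 4.1], mci: [23.1, 2.9], min: 0.0, max: 30.0}
  digit_span: {non_mci: [8.4, 2.4], mci: [8.2, 2.4], min: 0.0}
  ravlt: {non_mci: [4.6, 3.5], mci: [2.9, 2.4], min: 0.0}
  digit_symbol: {non_mci: [6.0, 2.8], mci: [4.7, 2.4], min: 0.0}
  vr1: {non_mci: [26.4, 8.2], mci: [22.4, 7.5], min: 0.0}
  vr2: {non_mci: [19.3, 11.7], mci: [12.9, 10.4], min: 0.0}
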