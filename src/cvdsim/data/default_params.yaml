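# Default model parameters (machine-readable parameter table).
simulation:
  start_year: 2010
  end_year: 2040
  dt: 1.0

diabetes:
  incidence_rate: 0.0328368
  progression_rate_managed: 0.0134
  progression_rate_unmanaged: 0.0556
  regression_rate: 0.193
  uptake_rate: 0.05

hypertension:
  incidence_rate: 0.0237906
  progression_rate_unmanaged:
    female: 0.06975
    male: 0.080125
  progression_effect_managed: 0.33
  regression_rate: 0.25
  uptake_rate: 0.035

smoking:
  initiation_rate: 0.0082388
  relapse_rate: 0.1
  cessation_rate: 0.162

cvd:
  beta_age: {female: 0.0699, male: 0.0488}
  beta_diabetes: {female: 0.5604, male: 0.3492}
  beta_hypertension: {female: 0.0161, male: 0.0152}
  beta_smoking: {female: 0.5419, male: 0.5224}
  beta0:
    none: -11.968
    D: -5.53323
    H: -6.91289
    S: -5.33926
    DH: -6.74229
    DS: -8.09581
    HS: -7.10026
    DHS: -8.18119
  rr_treated_diabetes: 0.8
  rr_treated_hypertension: 0.5
  rr_treated_smoking_cessation: 0.5
  event_death_rate: 0.2
  rr_death_post_cvd: 1.6
  treatment_mortality_effect: 0.13
  fraction_post_cvd_treated: 1.0

calibration:
  # expert-assessed distribution of CVD events across risk groups
  event_distribution:
    none: 0.01
    D: 0.20
    H: 0.10
    S: 0.05
    DH: 0.29
    DS: 0.05
    HS: 0.15
    DHS: 0.15
  loss: relative        # relative | absolute

modes:
  eq10_literal: false               # treated risk multiplier: rr (false) or 1-rr (true)
  partition_mode: independence      # independence | even_split
  hazard_rates: false               # read rates as hazards 1-exp(-r)
  smoking_group_mode: current_plus_former   # current_plus_former | current_only
  regression_applies: both          # both | managed
  uptake_applies_to: both           # pre | disease | both
  managed_dropout_rate: 0.0
  negative_stock: error             # error | clamp

demography:
  fecund_age_min: 15
  fecund_age_max: 49
  fecund_correction: 1.0
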