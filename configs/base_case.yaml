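cancer_care_fee_schedule_share: 0.15
cost_advanced_crc_annual: 150000.0
cost_colonoscopy_dx: 970.0
cost_colonoscopy_polypectomy: 250.0
cost_complication: 8000.0
cost_early_crc_annual: 12000.0
cost_physician: 220.0
cost_purevu_device: 750.0
cost_remission_annual: 1500.0
detection_adequate:
  sensitivity: 0.85
  specificity: 0.97
detection_inadequate:
  sensitivity: 0.55
  specificity: 0.97
discount_rate: 0.03
half_cycle_correction: false
horizon_years: 40
life_expectancy_advanced_crc: 4.8
life_expectancy_early_crc: 23.0
life_expectancy_no_crc: 24.0
p_adenoma_prevalence: 0.2
p_adenoma_prevalence_surveillance: 0.15
p_compliance_screening: 0.6
p_complication: 0.003
p_death_other_annual: 0.028629374085909282
p_early_to_remission: 0.15
p_inadequate_prep_purevu: 0.05
p_inadequate_prep_soc: 0.25
p_lapse_surveillance: 0.8
p_presentation_advanced_screened: 0.05
p_presentation_advanced_unscreened: 0.25
p_progression_adenoma_to_early: 0.0089
p_progression_early_to_advanced: 0.02
p_remission_to_advanced: 0.01
p_repeat_after_inadequate: 0.575
p_surveillance_compliance: null
payer_multiplier: 1.0
psa_distributions:
  cost_advanced_crc_annual:
    kind: gamma
    params:
      scale: 3375.0
      shape: 44.44444444444444
  cost_colonoscopy_dx:
    kind: gamma
    params:
      scale: 21.825
      shape: 44.44444444444444
  cost_colonoscopy_polypectomy:
    kind: gamma
    params:
      scale: 5.625
      shape: 44.44444444444444
  cost_complication:
    kind: gamma
    params:
      scale: 180.0
      shape: 44.44444444444444
  cost_early_crc_annual:
    kind: gamma
    params:
      scale: 270.0
      shape: 44.44444444444444
  cost_physician:
    kind: gamma
    params:
      scale: 4.95
      shape: 44.44444444444444
  detection_adequate.sensitivity:
    kind: beta
    params:
      alpha: 127.5
      beta: 22.500000000000004
    support:
    - 0.5
    - 1.0
  detection_inadequate.sensitivity:
    kind: beta
    params:
      alpha: 82.5
      beta: 67.5
    support:
    - 0.2
    - 0.9
  p_adenoma_prevalence:
    kind: beta
    params:
      alpha: 40.0
      beta: 160.0
    support:
    - 0.1
    - 0.45
  p_compliance_screening:
    kind: beta
    params:
      alpha: 90.0
      beta: 60.0
    support:
    - 0.0
    - 1.0
  p_complication:
    kind: beta
    params:
      alpha: 6.0
      beta: 1994.0
    support:
    - 0.0
    - 1.0
  p_inadequate_prep_purevu:
    kind: beta
    params:
      alpha: 10.0
      beta: 190.0
    support:
    - 0.0
    - 1.0
  p_inadequate_prep_soc:
    kind: beta
    params:
      alpha: 50.0
      beta: 150.0
    support:
    - 0.0
    - 1.0
  p_presentation_advanced_unscreened:
    kind: beta
    params:
      alpha: 37.5
      beta: 112.5
    support:
    - 0.0
    - 1.0
  p_progression_adenoma_to_early:
    kind: beta
    params:
      alpha: 7.12
      beta: 792.88
    support:
    - 0.0
    - 1.0
  p_progression_early_to_advanced:
    kind: beta
    params:
      alpha: 10.0
      beta: 490.0
    support:
    - 0.0
    - 1.0
  p_repeat_after_inadequate:
    kind: beta
    params:
      alpha: 86.25
      beta: 63.75000000000001
    support:
    - 0.0
    - 1.0
  utility_by_state.advanced_crc:
    kind: beta
    params:
      alpha: 165.0
      beta: 135.0
    support:
    - 0.0
    - 1.0
  utility_by_state.early_crc:
    kind: beta
    params:
      alpha: 222.0
      beta: 78.0
    support:
    - 0.0
    - 1.0
  utility_by_state.no_crc:
    kind: beta
    params:
      alpha: 286.755
      beta: 13.245000000000006
    support:
    - 0.0
    - 1.0
repeat_tracks_compliance: true
rr_onset_screened: 0.05
rr_onset_surveillance: 0.05
screening_interval_years: 10
sex_mix: 0.54
start_age: 60.0
surveillance_interval_years: 1
utility_by_state:
  adenoma_surveillance: 0.95585
  advanced_crc: 0.55
  death: 0.0
  early_crc: 0.74
  no_crc: 0.95585
  remission: 0.83
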