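# Default configuration shipped with copdfind.
#
# The code lists below are editable defaults, NOT a canonical clinical
# code set: icd10_lung covers the chronic lower-respiratory block
# J40-J47 plus respiratory failure J96, and atc_lung covers R03 (drugs
# for obstructive airway diseases). Review and replace them with your
# own validated lists before any real use.

code_lists:
  icd10_lung:
    patterns: [J40, J41, J42, J43, J44, J45, J46, J47, J96]
  atc_lung:
    patterns: [R03]

algorithms:
  copd_three_criterion:
    min_age_years: 35
    require_alive: true
    criteria:
      - label: a
        kind: hospital_dx
        code_list: icd10_lung
        lookback_days: 1826   # "preceding 5 years"
        min_count: 1
        distinct_dates: false
      - label: b
        kind: prescription
        code_list: atc_lung
        lookback_days: 365    # "preceding 12 months"
        min_count: 2
        distinct_dates: false # repeat same-day dispensings count
      - label: c
        kind: spirometry
        lookback_days: 365
        min_count: 2
        distinct_dates: true  # must fall on different dates

validation:
  default_algorithm: copd_three_criterion
  overall_prevalence: 0.09
  # Age-band prevalences for standardized PPV. Only 45-54 .. 75-84 are
  # required: 35-44 borrows the 45-54 value and 85+ the 75-84 value.
  prevalence_by_band:
    45-54: 0.0529
    55-64: 0.0953
    65-74: 0.1376
    75-84: 0.1694

generator:
  n_persons: 20000
  seed: 0
  index_date: 2007-01-01
  overall_prevalence: 0.09
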