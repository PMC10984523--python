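# Default configuration. Every value here can be overridden by a user
# config file; `crcburden config show` prints the merged result.

horizon_months: 396   # Jan 2018 .. Dec 2050

population:
  cohort_size: 50000
  random_seed: 0
  precursor_incidence_rate: 0.012      # per person-year before age scaling
  precursor_to_preclinical_rate: 0.06  # per precursor-year
  preclinical_sojourn_mean: 4.0        # years
  annual_upstage_rate: 0.35            # while undiagnosed
  stage_distribution_at_onset: [0.55, 0.30, 0.12, 0.03]
  screening_sensitivity_preclinical: 0.75
  screening_sensitivity_precursor: 0.30
  participation_baseline: 0.60
  age_distribution:
    20-24: 0.085
    25-29: 0.085
    30-34: 0.085
    35-39: 0.080
    40-44: 0.075
    45-49: 0.075
    50-54: 0.070
    55-59: 0.070
    60-64: 0.065
    65-69: 0.060
    70-74: 0.050
    75-79: 0.040
    80-84: 0.030
    85-89: 0.020
    90-94: 0.007
    95-99: 0.003
  age_incidence_multipliers:
    20-24: 0.05
    25-29: 0.10
    30-34: 0.15
    35-39: 0.25
    40-44: 0.40
    45-49: 0.60
    50-54: 1.00
    55-59: 1.30
    60-64: 1.70
    65-69: 2.00
    70-74: 2.30
    75-79: 2.50
    80-84: 2.60
    85-89: 2.60
    90-94: 2.60
    95-99: 2.60
  other_cause_mortality:
    20-24: 0.0010
    25-29: 0.0010
    30-34: 0.0010
    35-39: 0.0015
    40-44: 0.0020
    45-49: 0.0030
    50-54: 0.0040
    55-59: 0.0060
    60-64: 0.0090
    65-69: 0.0140
    70-74: 0.0220
    75-79: 0.0350
    80-84: 0.0600
    85-89: 0.1000
    90-94: 0.1700
    95-99: 0.2800

treatment_mix:
  surgery: 0.7
  chemotherapy: 0.4
  radiotherapy: 0.2

survival_5yr:   # parameterises exponential baseline curves; placeholders
  I: 0.95
  II: 0.85
  III: 0.70
  IV: 0.15
survival_horizon_months: 120

impact:
  hr_per_4_weeks: 1.06
  hr_compounding: continuous
  apply_diagnostic_hr_to_screen_detected: false
  annual_upstage_rate:
    I: 0.30
    II: 0.30
    III: 0.30
    IV: 0.00

queue:
  engine: agent        # agent | aggregate
  timestep_weeks: 2
  discipline: random   # random | fifo

mitigation:
  factor: 0.05
  start: "2022-01"

seeds:
  count: 20
  base: 1000

# Observed relative volume changes used to drive the built-in country
# scenarios. Participation changes apply to screening; the remaining
# records drive queue capacities (diagnostic_procedure records are scaled
# onto diagnoses by the procedures-to-diagnoses factor).
countries:
  canada:
    participation_changes:
      - {period_start: "2020-01", period_kind: year, relative_change: -0.40}
    volume_records:
      - {procedure_type: diagnosis, period_start: "2020-01", period_kind: year, relative_change: -0.102}
      - {procedure_type: diagnosis, period_start: "2021-01", period_kind: year, relative_change: -0.005}
      - {procedure_type: surgery, period_start: "2020-01", period_kind: year, relative_change: -0.051}
      - {procedure_type: surgery, period_start: "2021-01", period_kind: year, relative_change: 0.024}
      - {procedure_type: radiotherapy, period_start: "2020-01", period_kind: year, relative_change: 0.015}
      - {procedure_type: radiotherapy, period_start: "2021-01", period_kind: year, relative_change: 0.215}
      - {procedure_type: chemotherapy, period_start: "2020-01", period_kind: year, relative_change: 0.039}
      - {procedure_type: chemotherapy, period_start: "2021-01", period_kind: year, relative_change: 0.147}
  australia:
    participation_changes:
      - {period_start: "2020-01", period_kind: year, relative_change: -0.063}
      - {period_start: "2021-01", period_kind: year, relative_change: -0.051}
    volume_records:
      - {procedure_type: diagnostic_procedure, period_start: "2020-01", period_kind: year, relative_change: -0.117}
      - {procedure_type: diagnostic_procedure, period_start: "2021-01", period_kind: year, relative_change: -0.034}
      - {procedure_type: surgery, period_start: "2020-01", period_kind: year, relative_change: 0.001}
      - {procedure_type: surgery, period_start: "2021-01", period_kind: year, relative_change: -0.072}
      - {procedure_type: chemotherapy, period_start: "2020-01", period_kind: year, relative_change: 0.001}
      - {procedure_type: chemotherapy, period_start: "2021-01", period_kind: year, relative_change: -0.072}
      - {procedure_type: radiotherapy, period_start: "2020-01", period_kind: year, relative_change: 0.001}
      - {procedure_type: radiotherapy, period_start: "2021-01", period_kind: year, relative_change: -0.072}
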