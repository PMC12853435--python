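# Base-case unit-cost and model configuration.
# All money in GBP (costing year 2022/23). Unit-cost components are
# placeholders calibrated to the published per-course totals.
currency: GBP
costing_year: 2022/23
placeholder_values: true
n_sims: 5000
settings:
  cycle_length_weeks: 2.0
  horizon_cycles: 39
  annual_discount_rate: 0.035
  cycles_per_year: 26.0
  half_cycle_correction: true
intervention_rtms:
  equipment_capital_gbp: 133000.0   # machine + replacement coil/leads + warranty + 2 services
  equipment_lifetime_years: 10.0
  throughput_per_year: 43.0         # elicited average patients/year/machine
  sessions_per_course: 27.0         # elicited average course
  minutes_per_session: 30.0
  staff_cost_per_hour_gbp: 55.0
  training_cost_per_course_gbp: 69.65
  imaging_cost_gbp: 0.0
  discount_rate: 0.035
intervention_itbs:
  equipment_capital_gbp: 133000.0
  equipment_lifetime_years: 10.0
  throughput_per_year: 43.0
  sessions_per_course: 27.0
  minutes_per_session: 30.0
  staff_cost_per_hour_gbp: 55.0
  training_cost_per_course_gbp: 69.65
  imaging_cost_gbp: 256.0           # functional + resting-state MRI targeting
  discount_rate: 0.035
mortality:
  annual_mortality: 0.0025          # placeholder flat life-table rate at age 45
  relative_risk: 1.58               # severe unipolar depression, all-cause
  cohort_age: 45.0
  cohort_female_fraction: 0.55
societal:
  daily_earnings_gbp: 120.0
  employed_fraction: 0.55
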