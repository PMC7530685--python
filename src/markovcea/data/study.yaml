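population:
  claims_population: 1200000
  eligible: 686000
  app_users: 100000
  uptake_fraction: 0.15
  annual_uptake_probability: 0.026
horizon: 20
discount:
  rate: 0.04
  origin: 0
utility_discount:
  rate: 0.0
  origin: 0
accrual_timing: start
combine_insulin_cost: true
app_cost_states:
- insulin_therapy
insulin_to_macro: 0.02675
invert_table1_labels: true
uptake_mode: closed
currency: USD
wtp_thresholds:
  chuikyo: 43478
  who_3x_gdp: 116649
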