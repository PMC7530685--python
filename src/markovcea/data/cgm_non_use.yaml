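states:
- insulin_therapy
- microalbuminuria
- macroalbuminuria
- esrd
- dialysis
- cvd
- death
absorbing:
- death
horizon: 20
discount:
  rate: 0.04
  origin: 0
utility_discount:
  rate: 0.0
  origin: 0
accrual_timing: start
edges:
- from: insulin_therapy
  to: microalbuminuria
  p: 0.048
- from: insulin_therapy
  to: macroalbuminuria
  p: 0.02675
- from: microalbuminuria
  to: macroalbuminuria
  p: 0.028
- from: microalbuminuria
  to: cvd
  p: 0.1
- from: macroalbuminuria
  to: esrd
  p: 0.023
- from: macroalbuminuria
  to: cvd
  p: 0.1
- from: esrd
  to: dialysis
  p: 0.023
- from: esrd
  to: cvd
  p: 0.1
- from: dialysis
  to: death
  p: 0.123
- from: cvd
  to: death
  p: 0.123
costs:
  insulin_therapy: 4891.76
  microalbuminuria: 6784.37
  macroalbuminuria: 8148.17
  esrd: 11456.68
  dialysis: 41739.13
  cvd: 3587.3
  death: 0.0
utilities:
  insulin_therapy: 0.81
  microalbuminuria: 0.81
  macroalbuminuria: 0.81
  esrd: 0.81
  dialysis: 0.68
  cvd: 0.71
  death: 0.0
currency: USD
notes: non_use arm of the packaged CGM-app study; per-state costs are fully composed
  (nephropathy states include the insulin base cost).
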