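scenarios:
- path: edge:insulin_therapy>microalbuminuria
  kind: multiplicative
  low: 0.5
  high: 2.0
- path: edge:insulin_therapy>macroalbuminuria
  kind: multiplicative
  low: 0.5
  high: 2.0
- path: edge:microalbuminuria>macroalbuminuria
  kind: multiplicative
  low: 0.5
  high: 2.0
- path: edge:macroalbuminuria>esrd
  kind: multiplicative
  low: 0.5
  high: 2.0
- path: edge:esrd>dialysis
  kind: multiplicative
  low: 0.5
  high: 2.0
- path: edge:microalbuminuria>cvd
  kind: multiplicative
  low: 0.5
  high: 2.0
- path: edge:macroalbuminuria>cvd
  kind: multiplicative
  low: 0.5
  high: 2.0
- path: edge:esrd>cvd
  kind: multiplicative
  low: 0.5
  high: 2.0
- path: edge:dialysis>death
  kind: multiplicative
  low: 0.5
  high: 2.0
- path: edge:cvd>death
  kind: multiplicative
  low: 0.5
  high: 2.0
- path: cost:insulin_therapy
  kind: relative
  low: -0.1
  high: 0.1
- path: utility:insulin_therapy
  kind: relative
  low: -0.1
  high: 0.1
- path: cost:microalbuminuria
  kind: relative
  low: -0.1
  high: 0.1
- path: utility:microalbuminuria
  kind: relative
  low: -0.1
  high: 0.1
- path: cost:macroalbuminuria
  kind: relative
  low: -0.1
  high: 0.1
- path: utility:macroalbuminuria
  kind: relative
  low: -0.1
  high: 0.1
- path: cost:esrd
  kind: relative
  low: -0.1
  high: 0.1
- path: utility:esrd
  kind: relative
  low: -0.1
  high: 0.1
- path: cost:dialysis
  kind: relative
  low: -0.1
  high: 0.1
- path: utility:dialysis
  kind: relative
  low: -0.1
  high: 0.1
- path: cost:cvd
  kind: relative
  low: -0.1
  high: 0.1
- path: utility:cvd
  kind: relative
  low: -0.1
  high: 0.1
- path: app_cost
  kind: relative
  low: -0.1
  high: 0.1
- path: utility:insulin_therapy
  kind: relative
  low: -0.05
  high: 0.05
  label: utility:insulin_therapy (+/-5%)
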