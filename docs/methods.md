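# Methods

## Model and assumptions

`markovcea` implements a deterministic Markov cohort model: expected
patient counts over mutually exclusive health states, advanced once per
yearly cycle by a constant row-stochastic transition matrix.  The Markov
property (next state depends only on the current state), constant
transition probabilities over the horizon, expected-value (not
individual-level) counts, and an absorbing death state are all modelling
assumptions, not approximations the engine introduces: traces conserve
the cohort to < 1e-6 relative and match the matrix-power closed form to
< 1e-8 relative on randomly generated models.

The packaged study compares two scenarios over 20 years for 686,000
insulin-treated type 2 diabetes patients (a claims-database funnel from
1.2 million insulin users, restricted to patients able to use a CGM app
and free of nephrosis):

* **A — app not available**: all 686,000 on the non-use parameters;
* **B — app available**: a closed stratum of 100,000 users (15 % uptake)
  on the app-arm parameters, the rest on non-use parameters.

States: insulin therapy → {micro-, macroalbuminuria} → ESRD → dialysis,
with cardiovascular disease reachable from each nephropathy state and
death reachable from dialysis and CVD.  Disease improvement is excluded
(no recovery edges), as are neuropathy and retinopathy.

## Parameters

Transition probabilities (annual, both arms unless noted):

| edge | value |
|---|---|
| insulin → microalbuminuria | 4.8 % non-use / 1.6 % app arm |
| insulin → macroalbuminuria (direct) | 2.675 % |
| micro → macroalbuminuria | 2.8 % |
| macro → ESRD, ESRD → dialysis | 2.3 % |
| {micro, macro, ESRD} → CVD | 10.0 % |
| {dialysis, CVD} → death | 12.3 % |

Row remainders go to the self-transition; every completion is logged.
Annual costs (USD per person-year; yen annotations carried as metadata):
insulin therapy 4,891.76; microalbuminuria 1,892.61; macroalbuminuria
3,256.41; ESRD 6,564.92; CVD 3,587.30; dialysis 41,739.13; CGM app
2,827.83 (36 sensors + transmitter).  Utilities: insulin therapy 0.83
(app arm) / 0.81 (non-use), nephropathy states 0.81, CVD 0.71, dialysis
0.68, death 0.  Costs are discounted at 4 %/yr; utilities accrue
undiscounted (see below).  The appraisal thresholds (US $43,478/QALY,
US $116,649/QALY) are config metadata only.

## Structural switches and the frozen calibration

The published tables give per-parameter values but not the full wiring,
discount indexing or accrual timing.  These genuinely open choices are
explicit switches (`StudySettings`), and `markovcea.calibrate.sweep()`
scores all 64 documented combinations — discount origin {0, 1} ×
accrual timing {start, end} × cost composition {standalone, insulin
base folded into nephropathy states} × direct macro-onset edge
{0, 2.675 %} × app-cost scope {insulin-therapy state, all alive states}
× utility discount {0, 4 %} — by mean absolute relative error over the
eight published headline quantities.  The packaged defaults are the
winner, frozen:

* cycle *t* accrues the **start-of-cycle** occupancy discounted *t*
  years (factor `1.04^-t`);
* nephropathy-state costs **include** the insulin base cost (patients
  with albuminuria or ESRD remain on insulin);
* the **direct insulin → macroalbuminuria edge (2.675 %)** is present in
  both arms — without it the published increase in macroalbuminuria
  alongside a decrease in microalbuminuria is unreachable, and the
  widest published sensitivity scenario perturbs exactly this edge;
* the app cost accrues per **insulin-therapy** person-year of the user
  stratum;
* **utilities are undiscounted**: the published text states a 4 % utility
  discount, but the published incremental QALY total (≈ 0.11 per
  eligible patient) is only consistent with rate 0 under every
  combination swept.  The engine supports any utility rate; the packaged
  config sets 0.
* the arm labels on the microalbuminuria onset row are **inverted**
  relative to the published table (1.6 % to the app arm): the published
  results require app use to *reduce* early nephropathy, and the
  directionality test enforces it.  This is asserted by a fixed
  config flag, not swept.

Arm-label inversion aside, the two arms differ only in the
microalbuminuria onset, the insulin-therapy utility (0.83 vs 0.81) and
the app cost; stratum B totals are exactly additive and the ICER is
invariant to the uptake count (linearity), both property-tested.

### What the calibration reproduces, and what it cannot

Within 2 % relative: both scenario cost totals (−0.5 %, −1.0 %) and the
macroalbuminuria-cost sensitivity ICER (−0.7 %); the base ICER lands at
US $32,031/QALY vs the published US $33,039 (−3 %).  Not reachable by
any swept combination, and therefore recorded in
`markovcea.study.KNOWN_DISCREPANCIES` rather than absorbed: incremental
QALYs (+11 %), deaths averted (+84 %), and three sensitivity ICERs
(−9 %, +52 %, −9 %).  The published patient-count changes are internally
inconsistent with the published table values: jointly they imply a
microalbuminuria → CVD flow of roughly 3.5–4 %/yr, a value printed
nowhere, so the count-derived quantities (deaths averted above all)
cannot be matched while the cost totals are.  The published sensitivity
section is also inconsistent with itself (it prints "1.24 %" for half of
a base whose double is 5.35 %).

One-way sensitivity perturbs the **app arm only** by default (the
published analysis describes varying "the app use model parameters");
per-scenario `arms="both"` is available.  A ×1 perturbation reproduces
the shared base-case ICER bit-for-bit, and manifests are
order-invariant — both property-tested.

## Numerical choices

* Expected-value cohort arithmetic in double precision; costs parsed
  from the exact published decimal strings.
* Row-stochasticity tolerance 1e-9; under-specified rows completed via
  self-transition with a log entry, never silently.
* `ΔEffect = 0` yields an explicit `undefined` ICER marker — no division
  by zero, no absolute-value masking of dominance.
* Half-cycle correction exists (`accrual_timing="half"`, the mean of the
  start- and end-of-cycle conventions) but is off everywhere by default.
* Tornado ties in range width break lexicographically by parameter path,
  so scenario order never matters.

## Synthetic models and what the tests show

`markovcea.synthetic` draws random valid models (2–8 states, horizon
1–30, absorbing death, costs in [0, 50,000], utilities in [0, 1]) from a
single seeded generator, and provides nested-loop oracles for the trace
and the accrual that share no code with the engine.  The test suite
checks 500 such models per run against the oracles (1e-8/1e-9 relative).
These fixtures are structural, not clinical: they validate the
arithmetic (conservation, absorption, discount monotonicity, linearity,
ICER algebra), not the epidemiology.  Passing them says the engine
computes the stated model exactly; it says nothing about whether a
constant-probability, no-recovery, age-independent model describes real
diabetes progression — the packaged study inherits all of those
published limitations.

## Known limitations

Constant transition probabilities over 20 years (no ageing), closed
cohorts by default (a 2.6 %/yr dynamic-uptake mode is provided but off),
no probabilistic sensitivity analysis, no microsimulation, no
time-varying matrices, and the calibration residuals listed above.
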