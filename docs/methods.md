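# Methods

This note documents the model as implemented: its structure and
assumptions, the conventions chosen where the source material left the
design open, what the synthetic input tables emulate, and the known
limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model structure

Eleven health states, 2-week cycles, lifetime horizon to age 101. All
patients enter event-free (`No BTH`), except the scenario cohort of
patients stable on up-dosed eculizumab, whose eculizumab arm enters the
up-dose state. Nine living states: the No-BTH/IncC5Inhib-BTH/CAC-BTH
triple, the same triple after a first incomplete-C5-inhibition event
(history states), the permanent up-dose branch (up-dosed, up-dosed with
CAC event), and spontaneous remission. Two absorbing death states
separate background from PNH-attributable mortality. Under ravulizumab
the incomplete-C5 and up-dose states are structurally unreachable (no
such events were observed in the trials), which is asserted as a matrix
invariant.

### Row construction

Each living row of the per-cycle matrix is built in a fixed order:

1. **Death.** The background per-cycle probability comes from the life
   table at the floored current age via the constant-hazard conversion
   `1-(1-q_annual)^(14/365.25)`. BTH states inflate it on the rate
   scale with multiplier `1+(HR-1)·d/14` (HR = 4.8; d = 2 days for
   incomplete-C5 events, 14 for CAC events). The background portion
   flows to background death; exactly the excess flows to PNH death, so
   the two death states are separable in reports.
2. **Remission.** 0.0006 from every living state.
3. **Events.** The published two-weekly probabilities fill the event
   destinations.
4. **Residual.** Whatever remains goes to the row's natural no-event
   destination (event states resolve to the event-free state of their
   history level).

Steps 2–4 are scaled by the survival probability, i.e. the published
values are read as conditional on surviving the cycle (the source is
silent; this keeps them interpretable and rows exactly stochastic).
The residual rule reproduces the published "IncC5Inhib BTH → Hx No BTH"
values (0.6627/0.6642) exactly, which corroborates the convention.

The second-event row is special: the printed 0.9994 flow to permanent
up-dosing and the 0.0006 remission flow are jointly exhaustive. The
implementation therefore uses `1 − remission` for the up-dose flow so
the row stays exhaustive when remission is varied in sensitivity
analyses.

CAC events do not alter the disease course: the CAC state carries the
same onward event risks as its event-free sibling and resolves back to
it after one cycle.

**Risk extrapolation.** Treatment-naive patients who have not yet had an
incomplete-C5 event take on the stable cohort's initial-event risks once
elapsed time reaches 26 weeks (first cycle at or beyond 26·7 days),
reflecting that their first-26-week risk elevation is transient. A
switch disables this (scenario).

**Ages beyond the life table** reuse its last row; at the maximum age
the death probability is forced to 1 (one final forced-death cycle, so
lifetime traces end fully absorbed).

## Accrual conventions

Occupancy-based quantities — drug schedule, administration tariffs and
their societal companions, transfusions, utilities, life-years — accrue
on start-of-cycle occupancy. Event-incidence quantities — the per-event
medical costs and per-event societal costs — are charged on the
transition inflow into event states (which equals next-cycle occupancy
of those states, since event states hold no carried-over occupancy).
No half-cycle correction by default (spreadsheet convention; a switch
enables trapezoidal occupancy for exploration — it moves lifetime QALYs
by well under 1%).

Discounting is continuous in elapsed years (`(1+r)^(-t·14/365.25)`),
1.5%/year for effects and 4%/year for costs. Monetary arithmetic is
double precision carrying the printed decimal values; rounding to whole
euros happens only in reports.

## Dosing and costs

* Eculizumab: naive patients get five weekly 600 mg doses (days 0–28),
  then 900 mg every 14 days from day 35; experienced cohorts 900 mg at
  day 0 of every cycle; up-dosed states 1200 mg. The wording admits
  day 28 as the first maintenance day; `dosing.ecu_maintenance_start_day`
  is the documented toggle.
* Ravulizumab: label weight bands (loading 2400/2700/3000 mg,
  maintenance 3000/3300/3600 mg for <60 / 60–<100 / ≥100 kg; adults
  below 40 kg clipped into the lowest band), loading at entry in every
  cohort, maintenance at day 14 and every 56 days after. Band fractions
  are normal-distribution masses from the weight-by-age table at the
  current age.
* Vials are 300 mg, ceil-rounded per dose, no sharing. Drug cost is
  linear in vial price by construction.
* Per-event medical costs use the published weighted averages (€502.48
  incomplete-C5, €869.14 CAC). The admission mix behind them is not
  published; for the per-event *societal* components the package uses a
  configurable mix calibrated to reproduce those weighted averages from
  the printed unit costs (1 haematologist visit plus 0.5325 / 1.0725
  general-ward days; ICU and dialysis weights default to 0). Ward
  productivity (a 120-h lump) is pro-rated over a 5-day admission.
* **No extra drug charge per incomplete-C5 event by default.** Events
  are clinically treated with an earlier-than-scheduled dose, and a
  toggle (`costs.charge_extra_dose_on_incc5`) can charge one full dose
  (drug + tariff + visit societal costs) per event inflow. The default
  is off: the published scenario arithmetic — removing up-dosing moves
  the incremental cost by roughly +€385k — is only consistent with no
  separate per-event drug charge (with the charge on, recurring second
  events would largely cancel the removed up-dosing costs), and the
  €502.48 weighted event cost clearly contains no €13k dose.
* Societal costs: per infusion visit, 147 round-trip km at €0.19/km
  plus parking for the 50% travelling by car (€29.43 expected), and the
  arm-specific productivity loss (€81.82 eculizumab / €112.51
  ravulizumab per administration). The caregiver uplift ×1.5 applies to
  the car-travelling half, giving an effective ×1.25 (a switch applies
  ×1.5 to everyone). Transfusions and BTH events use the 14-km distance;
  transfusion productivity hours are not published and default to the
  4-h eculizumab-administration loss, exposed as a parameter.
* The funded-homecare knob removes the administration tariff for that
  fraction of ravulizumab infusions; the high-concentration-formulation
  scenario sets ravulizumab's tariff and per-administration productivity
  loss to eculizumab's (its infusion time matches).
* Meningococcal prophylaxis (€142.42 = ACWY €46.43 + B €83.11 +
  ciprofloxacin €12.88) is charged once at entry for naive patients.

## Utilities

State utility = age-banded Dutch reference value (0.935 / 0.890 / 0.890
/ 0.886 for 35–44 / 45–54 / 55–64 / 65–74; nearest band extended
outside) plus a non-positive cohort/arm/state decrement relative to
spontaneous remission. The decrements already net in the 0.070
discrete-choice-experiment increment for the eight-weekly schedule, so
no further increment is added and the reference acts as a cap (inactive
by construction, kept as an explicit switch). Death states carry 0. The
symptom-days knob rescales only the event-attributable part of the
incomplete-C5 decrement (event minus No-BTH decrement) by `days/2`,
treating the published value as a 2-symptom-day cycle average. The
trial-based ("treatment indicator") utility scenario needs a
user-supplied decrement table; those alternative values are not
published.

## Transition estimation

The estimator mirrors the three-step procedure that produced the
transition inputs: organise visit-level panels, fit a multinomial logit
(outcomes: no event / incomplete-C5 BTH / CAC BTH; covariates: intercept
+ treatment indicator; reference: no event) per history stratum by full
information maximum likelihood, and invert to per-arm mean transition
probabilities. Optimisation is L-BFGS on the negative log-likelihood
with analytic gradient. Because the design is saturated (two covariate
patterns, two free parameters per outcome), the interior MLE equals the
per-arm empirical frequencies — which the tests exploit as an
independent oracle, alongside a cross-check against statsmodels'
MNLogit. Structural zeros (e.g. no incomplete-C5 events under
ravulizumab) are detected from the contingency table before
optimisation; such fits are flagged `boundary` and report the empirical
frequencies, the MLE on the boundary of the parameter space. Empty
strata raise.

## Sensitivity analyses

* **Families by domain:** probabilities and utility-scale values → Beta;
  non-negative costs, counts and the hazard ratio → Gamma; decrements
  (support crossing 0) → Normal. Method-of-moments shapes from
  (mean, SE); published SEs are used where printed (transfusion table),
  otherwise SE = 25% of the mean. Structural zeros and zero SEs stay
  fixed. Draws violating hard invariants (sign constraints) are
  re-sampled, not truncated. Parameters are sampled independently.
* **Baseline age is not varied**: no SE is published and the default SE
  rule would produce non-adult ages.
* **Vial list prices are excluded from the PSA by default** (flag
  `psa_include_drug_prices`): prices are administratively known, their
  ±25% noise would swamp every other parameter (the one-way analysis
  shows them moving incremental costs by millions), and only without
  them does the incremental-cost distribution show the documented
  Beta-driven skew in the cost-saving direction. They remain in the
  one-way analysis, flagged `drug_price` so presentation layers can
  separate them.
* OWSA evaluates each parameter at its 2.5th/97.5th percentiles with
  everything else at base, reporting both increments and ranges, sorted
  by cost range. The CEAC is the fraction of draws with positive net
  monetary benefit `WTP·ΔQALY − Δcost` over a WTP grid; it is not forced
  monotone (quadrant mixing can make it non-monotone).
* The PSA's per-draw unit is the aggregate population; per-cohort draws
  are available by flag.

## Synthetic input tables

Two cited inputs are not published as tables and ship as synthetic
stand-ins, generated deterministically:

* **Life table:** Gompertz–Makeham annual hazard `A + B·e^{c·age}` with
  A = 2·10⁻⁴, B = 2.25·10⁻⁵, c = 0.095, chosen once so that remaining
  life expectancy at age 46 is ≈ 37 years — the right magnitude for a
  Western-European general population, on which the absolute lifetime
  totals depend. Probability forced to 1 at age 101.
* **Weight table:** flat 77 ± 13 kg across adult ages, placing most
  mass in the middle ravulizumab dosing band (≈ 9.6% / 86.6% / 3.8%
  across the three bands, 10.94 expected maintenance vials).

**What the fixtures do and do not show.** With them the model
reproduces the published *qualitative* results: ravulizumab dominant in
every cohort and the aggregate, ≥ 90% of savings in drug and
administration costs, QALY gains growing with the horizon, and the
correct direction for every scenario. Absolute euro totals differ from
the published ones because they scale with the life table and,
critically, with the weight mix: at 77 ± 13 kg ravulizumab's
steady-state drug+administration cost sits slightly *below*
eculizumab's non-up-dosed cost (€12,966 vs €13,130 per cycle), whereas
the published figures imply the real national weight-by-age mix puts
enough mass in the heaviest band to tip it slightly above. One visible
consequence: the no-up-dosing scenario here leaves a small residual
saving (≈ −€55k) instead of flipping the incremental cost positive.
Supplying the real life table and weight table as CSVs restores the
exact setting; the remaining conventions that can shift results at the
margin (half-cycle correction, eculizumab maintenance start day, the
per-event extra-dose charge) are all explicit switches.

The visit-panel generator emulates the trials' two-weekly visit
structure with treatment-dependent multinomial outcomes and a history
flag set after the first incomplete-C5 event. It does not emulate
dropout, visit irregularity, or covariate heterogeneity — parameter
recovery on it demonstrates estimator correctness, not robustness to
real-data messiness.

## Numerical choices

Matrix rows sum to 1 to 1e-12 by construction (survival-scaled
residual); traces conserve probability to better than 1e-10 over 1,500+
cycles. Matrices are cached per (integer age, extrapolation phase);
dose-schedule vial counts are cached independently of prices, keeping a
full model evaluation under ~50 ms and a 1,000-draw PSA around a
minute. The acceptance script runs the PSA at 1,000 draws and the
estimation at 5,000 patients × 26 visits — the published analysis
sizes. Beta/Gamma quantile evaluations that return non-finite values at
extreme method-of-moments shapes (vanishing SE) fall back to the point
mass at the mean.

## Known limitations

* Long-term transition probabilities are 26/52-week trial rates held
  constant for life (as in the source analysis).
* No correlation structure in the PSA; no value-of-information
  analysis.
* The per-event societal admission mix and the transfusion productivity
  hours are assumptions exposed as parameters, not published values.
* The "persistence of IncC5Inhib BTH" knob is stored and echoed but has
  no defined semantics in the implemented model (its published meaning
  is not specified); it deliberately does not affect results.
* Plotting is intentionally out of scope: tornado and CEAC results are
  tables.
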