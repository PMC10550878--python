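# pnhcea

A Markov cohort cost-effectiveness model comparing **ravulizumab** with
**eculizumab** for adult patients with paroxysmal nocturnal
hemoglobinuria (PNH), from a Dutch societal perspective. The package is
aimed at health-economics analysts and methodologists who want a tested,
scriptable re-implementation of this decision model — to inspect its
assumptions, rerun its sensitivity analyses, or plug in their own input
tables (national life table, weight-by-age statistics, utility sets,
prices).

## The model

PNH is a rare complement-mediated hemolytic disease treated with C5
inhibitors. Eculizumab requires an infusion every 2 weeks; ravulizumab
every 8 weeks, and no breakthrough hemolysis (BTH) from incomplete C5
inhibition (IncC5Inhib) has been observed under ravulizumab. The model
captures both differences.

A cohort moves through 11 health states in 2-week cycles from the
cohort's starting age to a maximum of 101 years: `No BTH`, IncC5Inhib
and CAC (complement-amplifying condition) BTH event states, post-event
history states, a permanent eculizumab up-dose branch (900 mg → 1200 mg
after a second IncC5Inhib event), spontaneous remission, and two
absorbing death states (background vs PNH-related). Per cycle, for state
occupancy vector `x_t` and transition matrix `P_t`,

    x_{t+1} = x_t P_t,
    QALYs   = Σ_t (x_t · u(age_t)) · (14/365.25) · (1+0.015)^(-t·14/365.25),
    Costs   = Σ_t c_t(x_t) · (1+0.04)^(-t·14/365.25),

with differential discounting (1.5%/year effects, 4%/year costs, the
Dutch convention). Death rows of `P_t` are absorbing; BTH states carry
an excess mortality hazard ratio of 4.8 applied on the rate scale over
the scaled event duration (2 days for IncC5Inhib events, a full cycle
for CAC events). Costs cover vial-based drug costs (no vial sharing),
administration tariffs, per-event medical costs, pRBC transfusions,
meningococcal vaccination for treatment-naive patients, and societal
costs (travel, productivity losses with a caregiver uplift). The
incremental cost-effectiveness ratio (ICER) is Δcost/ΔQALY with the
usual dominance labels.

The package also implements the estimation step that produced the
transition inputs: a full-information maximum-likelihood multinomial
logit of next-visit outcome (no event / IncC5Inhib BTH / CAC BTH) on an
intercept and a treatment indicator, fitted per history stratum on
visit-level panels, with principled handling of structural-zero cells
(boundary fits).

Beyond the deterministic base case there are one-way (tornado) and
probabilistic sensitivity analyses (Beta/Gamma/Normal by domain, method
of moments, SE = 25% of the mean where unpublished, CEAC via net
monetary benefit at a €20,000/QALY threshold) and the named scenario
analyses (horizons, discount rates, up-dosing rules, payer perspective,
no remission, ...).

Two cited inputs are not published as tables and are shipped as
synthetic stand-ins: a Gompertz–Makeham life table and a flat 77±13 kg
weight-by-age table (`pnhcea.synthetic`). Supply the real national
tables as two small CSVs to reproduce the published figures exactly —
see `docs/methods.md` for what the fixtures can and cannot show.

## Worked example

```python
from pnhcea import CostEffectivenessModel, default_parameters
from pnhcea.synthetic import default_tables

life_table, weight_table = default_tables()
model = CostEffectivenessModel(default_parameters(), life_table, weight_table)
results = model.run()
print(results.summary())
```

prints (abridged to the aggregate population):

```
[aggregate]
                                 ravulizumab      eculizumab      difference
Drug and administration            5,107,961       5,539,568        -431,606
Medical costs                          5,547           7,801          -2,253
Societal costs                        17,873          54,078         -36,205
Total costs                        5,131,382       5,601,446        -470,065
Total effects (QALY)                   23.85           22.36            1.50
ICER (EUR/QALY)                                                     dominant
```

Read: over a lifetime horizon a patient switched to ravulizumab costs
€470,065 less and gains 1.50 quality-adjusted life years, so ravulizumab
*dominates* eculizumab (cheaper and more effective); 92% of the savings
sit in drug and administration costs. The absolute totals depend on the
synthetic life/weight tables; the qualitative conclusion (dominance,
drug-cost-driven savings, QALY gain from fewer infusions and absent
IncC5Inhib events) matches the published analysis.

Sensitivity analyses and scenarios hang off the same object:

```python
psa = model.run_psa()                    # 1,000 draws, CEAC
tornado = model.run_owsa()               # 2.5/97.5-percentile bounds
alt = model.run_scenario("no_updosing")  # any named scenario
```

There is also a CLI: `pnhcea run`, `pnhcea psa`, `pnhcea owsa`,
`pnhcea scenario <name>`, `pnhcea simulate-fixtures`
(`pnhcea --help` for the global `--config/--life-table/--weight-table/
--out/--seed` options). User configuration is a flat YAML of dotted
parameter paths, e.g. `costs.vial_ecu: 4000`.

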