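"""Named scenario analyses: each scenario is a pure override of the
base parameter set (or of the cohort mix) followed by a full aggregate
run. Scenario names mirror the published scenario table."""

from __future__ import annotations

from typing import Callable

import pandas as pd

from .params import ParameterSet
from .states import cohort3


def _set(fn: Callable[[ParameterSet], None]) -> Callable[[ParameterSet], ParameterSet]:
    def apply(p: ParameterSet) -> ParameterSet:
        q = p.copy()
        fn(q)
        return q

    return apply


def _discount(rate: float):
    def fn(q: ParameterSet) -> None:
        q.discount_qaly = rate
        q.discount_cost = rate

    return fn


def _horizon(years: float):
    def fn(q: ParameterSet) -> None:
        q.horizon_years = years

    return fn


def _incc5_days(days: float):
    def fn(q: ParameterSet) -> None:
        q.transitions.incc5_event_days = days

    return fn


def _include_cohort3(q: ParameterSet) -> None:
    """20% of the eculizumab-experienced population starts stable on the
    up-dosed 1200 mg maintenance dose."""
    new = []
    for c in q.cohorts:
        if c.id.value == "cohort2":
            from dataclasses import replace

            new.append(replace(c, mix_weight=c.mix_weight * 0.8))
            new.append(cohort3(mix_weight=c.mix_weight * 0.2))
        else:
            new.append(c)
    q.cohorts = new


def _highconc(q: ParameterSet) -> None:
    q.costs.rav_highconc = True


SCENARIOS: dict[str, Callable[[ParameterSet], ParameterSet]] = {
    "base_case": _set(lambda q: None),
    "horizon_10y": _set(_horizon(10.0)),
    "horizon_20y": _set(_horizon(20.0)),
    "discount_0pct": _set(_discount(0.0)),
    "discount_6pct": _set(_discount(0.06)),
    "incc5_duration_1d": _set(_incc5_days(1.0)),
    "incc5_duration_3d": _set(_incc5_days(3.0)),
    "incc5_duration_7d": _set(_incc5_days(7.0)),
    "rav_high_concentration": _set(_highconc),
    "include_cohort3": _set(_include_cohort3),
    "no_utility_cap": _set(lambda q: setattr(q.utilities, "apply_utility_cap", False)),
    "no_updosing": _set(lambda q: setattr(q.transitions, "updosing_enabled", False)),
    "updose_after_first_event": _set(
        lambda q: setattr(q.transitions, "updose_after_first_event", True)),
    "excess_mortality_hr_1.20": _set(
        lambda q: setattr(q.transitions, "excess_mortality_hr", 1.20)),
    "excess_mortality_hr_0": _set(
        lambda q: setattr(q.transitions, "excess_mortality_hr", 0.0)),
    "homecare_100pct": _set(
        lambda q: setattr(q.costs, "homecare_fraction_rav", 1.0)),
    "no_26wk_extrapolation": _set(
        lambda q: setattr(q.transitions, "extrapolate", False)),
    "symptom_days_4": _set(
        lambda q: setattr(q.utilities, "symptom_days_incc5", 4.0)),
    "cac_updosing": _set(
        lambda q: setattr(q.transitions, "cac_counts_toward_updose", True)),
    "payer_perspective": _set(lambda q: setattr(q, "include_societal", False)),
    "no_spontaneous_remission": _set(
        lambda q: setattr(q.transitions, "remission_per_cycle", 0.0)),
}

#: scenarios that need user-supplied inputs (e.g. the trial-based
#: treatment-indicator utility decrements, which are not published)
OVERRIDE_SCENARIOS = ("utility_decrement_override",)


def run_scenario(name: str, p: ParameterSet, life_table, weight_table,
                 decrement_table: pd.DataFrame | None = None):
    """Apply a named scenario and run the full aggregate analysis."""
    from .engine import CostEffectivenessModel
    from .utilities import decrement_override_from_frame

    if name in SCENARIOS:
        q = SCENARIOS[name](p)
    elif name in OVERRIDE_SCENARIOS:
        if decrement_table is None:
            raise ValueError(
                f"scenario {name!r} needs a user-supplied decrement table "
                "(columns: cohort, arm, state, decrement); the alternative "
                "utility values are not published"
            )
        q = decrement_override_from_frame(p, decrement_table)
    else:
        known = sorted(list(SCENARIOS) + list(OVERRIDE_SCENARIOS))
        raise KeyError(f"unknown scenario {name!r}; known: {known}")
    return CostEffectivenessModel(q, life_table, weight_table).run()


def scenario_table(p: ParameterSet, life_table, weight_table,
                   names=None) -> pd.DataFrame:
    """Run a list of scenarios (default: all parameter-only ones) and
    tabulate incremental costs/QALYs and the outcome label."""
    rows = []
    for name in names or SCENARIOS:
        res = run_scenario(name, p, life_table, weight_table).aggregate
        icer = res.icer
        rows.append({
            "scenario": name,
            "delta_cost": res.delta_cost,
            "delta_qalys": res.delta_qalys,
            "icer": icer if isinstance(icer, float) else float("nan"),
            "outcome": icer if isinstance(icer, str) else "icer",
        })
    return pd.DataFrame(rows)
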