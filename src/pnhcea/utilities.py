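"""State utilities and discounted QALY accrual.

Utility of a living state = age-banded Dutch general-population
reference value plus a (non-positive) cohort/arm/state decrement
relative to spontaneous remission. The decrements already net in the
0.070 utility increment for the eight-weekly ravulizumab schedule
measured in a discrete choice experiment, so the ravulizumab columns
are simply less negative. Death states carry utility 0. QALYs are
discounted at 1.5% per year; costs elsewhere at 4% (the Dutch
differential-discounting convention).
"""

from __future__ import annotations

import numpy as np

from .params import DAYS_PER_YEAR, ParameterSet, UtilityParams
from .states import Arm, Cohort, HealthState, LIVING_STATES, N_STATES

S = HealthState

_INCC5_STATES = (S.INCC5_BTH, S.HX_INCC5_BTH)


def reference_utility(age: float, u: UtilityParams) -> float:
    """Age-banded general-population utility; ages below the first band
    use the first band's value, ages above the last use the last's."""
    bands = u.age_reference
    if age < bands[0][0]:
        return bands[0][2]
    for lo, hi, val in bands:
        if lo <= age <= hi:
            return val
    return bands[-1][2]


def state_utility(
    state: HealthState,
    arm: Arm,
    cohort: Cohort,
    age: float,
    u: UtilityParams,
) -> float:
    """Utility of one state at one age.

    The symptom-days knob rescales only the event-attributable part of
    the incomplete-C5 decrement (event decrement minus the arm's No-BTH
    decrement) by symptom_days/2, treating the published value as a
    2-symptom-day cycle average."""
    if state in (S.DEATH_BACKGROUND, S.DEATH_PNH):
        return 0.0
    ref = reference_utility(age, u)
    if state == S.REMISSION:
        return ref
    dec = u.decrement(state, cohort.param_cohort, arm)
    if state in _INCC5_STATES and u.symptom_days_incc5 != 2.0:
        base = u.decrement(S.NO_BTH, cohort.param_cohort, arm)
        dec = base + (dec - base) * (u.symptom_days_incc5 / 2.0)
    value = ref + dec
    if u.apply_utility_cap:
        value = min(value, ref)
    return max(value, -1.0)


def utility_vector(
    arm: Arm, cohort: Cohort, age: float, u: UtilityParams
) -> np.ndarray:
    """Utilities for all 11 states at one age; states a treatment arm can
    never occupy (incomplete-C5/up-dose states under ravulizumab) are set
    to 0 — they receive no occupancy by construction."""
    out = np.zeros(N_STATES)
    for state in LIVING_STATES:
        try:
            out[state] = state_utility(state, arm, cohort, age, u)
        except KeyError:
            out[state] = 0.0
    return out


def discount_factor(annual_rate: float, elapsed_years: float) -> float:
    """(1 + r)^(-t) with continuously interpolated elapsed years."""
    return float((1.0 + annual_rate) ** (-elapsed_years))


def cycle_qalys(
    occupancy: np.ndarray,
    utilities: np.ndarray,
    cycle_days: float,
    factor: float = 1.0,
) -> float:
    """QALYs accrued in one cycle: occupancy-weighted utility times the
    cycle length in years times the discount factor."""
    return float(occupancy @ utilities) * (cycle_days / DAYS_PER_YEAR) * factor


def decrement_override_from_frame(p: ParameterSet, df) -> ParameterSet:
    """Apply a decrement override table (columns cohort, arm, state,
    decrement) — the hook for scenarios whose alternative utility sets
    are supplied by the user (e.g. trial-based treatment-indicator
    utilities or a different QLQ-C30 mapping)."""
    from .params import _STATE_KEYS  # state -> key name

    key_by_name = {v: v for v in _STATE_KEYS.values()}
    q = p.copy()
    for _, row in df.iterrows():
        state_key = key_by_name[str(row["state"]).lower()]
        q.utilities.decrements[str(row["cohort"]).lower()][str(row["arm"]).lower()][
            state_key
        ] = float(row["decrement"])
    return q
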