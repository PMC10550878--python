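"""Per-cycle transition matrices for the 11-state PNH Markov model.

Construction order for each living-state row: (1) the cycle death
probability from the background life table, inflated on the rate scale
by the excess breakthrough-haemolysis (BTH) hazard ratio over the scaled
event duration for BTH states, with the excess over background assigned
to the PNH death state; (2) the spontaneous-remission flow; (3) the
event transition probabilities; (4) the residual to the row's natural
no-event destination. Event and remission flows are conditional on
surviving the cycle, so rows sum to exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import DAYS_PER_YEAR, ParameterSet, TransitionParams
from .states import Arm, Cohort, CohortId, HealthState, N_STATES

S = HealthState


# --------------------------------------------------------------------------
# life table
# --------------------------------------------------------------------------

@dataclass
class LifeTable:
    """Annual death probabilities by integer age.

    Ages beyond the last row reuse the last row's probability; at or
    beyond the model's maximum age the death probability is forced to 1
    by the matrix builder (model cap), not by the table itself.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx = np.asarray(self.qx, dtype=float)
        if len(self.ages) != len(self.qx) or len(self.ages) == 0:
            raise ValueError("life table requires matching, non-empty age/qx columns")
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("life-table ages must be contiguous integers")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValueError("life-table probabilities must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        cols = {c.lower(): c for c in df.columns}
        try:
            age_col = cols["age"]
            q_col = cols["annual_death_probability"]
        except KeyError:
            raise ValueError(
                "life table needs columns 'age' and 'annual_death_probability'"
            ) from None
        df = df.sort_values(age_col)
        return cls(df[age_col].to_numpy(), df[q_col].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "annual_death_probability": self.qx})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def annual_q(self, age: float) -> float:
        """Annual death probability at (floored) age, clamped to the span."""
        idx = int(math.floor(age)) - int(self.ages[0])
        idx = min(max(idx, 0), len(self.qx) - 1)
        return float(self.qx[idx])


# --------------------------------------------------------------------------
# probability/rate conversions
# --------------------------------------------------------------------------

def annual_prob_to_cycle_prob(q_annual: float, cycle_days: float) -> float:
    """Convert an annual death probability to a per-cycle probability
    under a constant hazard within the year: 1 - (1-q)^(days/365.25)."""
    if q_annual >= 1.0:
        return 1.0
    return 1.0 - (1.0 - q_annual) ** (cycle_days / DAYS_PER_YEAR)


def bth_adjusted_death_prob(
    q_bg_cycle: float, hr: float, event_days: float, cycle_days: float
) -> float:
    """Inflate a per-cycle death probability by an excess hazard ratio
    acting over ``event_days`` of the cycle.

    Works on the rate scale: the cycle rate is multiplied by
    ``1 + (hr - 1) * event_days / cycle_days`` and converted back."""
    if q_bg_cycle >= 1.0:
        return 1.0
    rate = -math.log(1.0 - q_bg_cycle)
    mult = 1.0 + (hr - 1.0) * event_days / cycle_days
    return 1.0 - math.exp(-rate * mult)


# --------------------------------------------------------------------------
# matrix construction
# --------------------------------------------------------------------------

def _event_probs(tp: TransitionParams, cohort_key: str, arm: Arm, extrapolated: bool):
    """Resolve the per-row event probabilities for a cohort/arm, applying
    the 26-week risk extrapolation (naive cohort takes on the stable
    cohort's initial-event risks once elapsed time crosses the threshold)."""
    a = arm.value
    entry_key = CohortId.COHORT2.value if extrapolated else cohort_key
    return {
        "no_to_incc5": tp.p_no_bth_to_incc5[entry_key][a],
        "no_to_cac": tp.p_no_bth_to_cac[entry_key][a],
        "second_incc5": tp.p_second_incc5_after_first[cohort_key][a],
        "incc5_to_cac": tp.p_incc5_to_cac[cohort_key][a],
        "hx_to_incc5": tp.p_hx_no_bth_to_incc5[cohort_key][a],
        "updose_cac": tp.p_updose_cac[cohort_key][a],
    }


def _fill_row(
    M: np.ndarray,
    state: HealthState,
    events: dict[HealthState, float],
    natural: HealthState,
    q_bg: float,
    q_death: float,
    remission: float,
) -> None:
    row = M[state]
    row[S.DEATH_BACKGROUND] = min(q_bg, q_death)
    row[S.DEATH_PNH] = q_death - min(q_bg, q_death)
    surv = 1.0 - q_death
    total_event = 0.0
    for dest, pr in events.items():
        row[dest] += surv * pr
        total_event += pr
    row[S.REMISSION] += surv * remission
    residual = 1.0 - total_event - remission
    if residual < -1e-12:
        raise ValueError(
            f"event probabilities from {state.name} exceed 1 (residual {residual:.3g})"
        )
    row[natural] += surv * max(residual, 0.0)


def build_transition_matrix(
    cohort: Cohort,
    arm: Arm,
    cycle_index: int,
    p: ParameterSet,
    lt: LifeTable,
) -> np.ndarray:
    """The 11x11 stochastic matrix for one cohort/arm/cycle."""
    age = cohort.start_age + cycle_index * p.cycle_days / DAYS_PER_YEAR
    tp = p.transitions
    extrapolated = (
        tp.extrapolate
        and cohort.param_cohort == CohortId.COHORT1
        and arm == Arm.ECULIZUMAB
        and cycle_index * p.cycle_days >= tp.extrapolate_after_weeks * 7.0
    )
    if age >= p.max_age:
        q_bg = 1.0
    else:
        q_bg = annual_prob_to_cycle_prob(lt.annual_q(age), p.cycle_days)
    return matrix_for_conditions(cohort.param_cohort.value, arm, extrapolated, q_bg, p)


def matrix_for_conditions(
    cohort_key: str,
    arm: Arm,
    extrapolated: bool,
    q_bg: float,
    p: ParameterSet,
) -> np.ndarray:
    """Matrix as a function of the model conditions only (no age lookup);
    the engine caches on (cohort, arm, extrapolated, q_bg)."""
    tp = p.transitions
    ev = _event_probs(tp, cohort_key, arm, extrapolated)
    rem = tp.remission_per_cycle
    hr = tp.excess_mortality_hr
    is_rav = arm == Arm.RAVULIZUMAB
    # the printed 0.9994 up-dose flow and the 0.0006 remission flow are
    # jointly exhaustive; keep the row exhaustive when remission is varied
    updose_flow = 0.0 if (is_rav or not tp.updosing_enabled) else max(0.0, 1.0 - rem)

    q_incc5 = bth_adjusted_death_prob(q_bg, hr, tp.incc5_event_days, p.cycle_days)
    q_cac = bth_adjusted_death_prob(q_bg, hr, tp.cac_event_days, p.cycle_days)

    # CAC events advance the up-dosing ladder only under eculizumab (the
    # ladder does not exist for ravulizumab)
    cac_ladder = tp.cac_counts_toward_updose and not is_rav
    first_cac_dest = S.HX_CAC_BTH if cac_ladder else S.CAC_BTH

    M = np.zeros((N_STATES, N_STATES))
    # no-event, no-history states
    _fill_row(M, S.NO_BTH,
              {S.INCC5_BTH: ev["no_to_incc5"], first_cac_dest: ev["no_to_cac"]},
              S.NO_BTH, q_bg, q_bg, rem)
    # ongoing CAC event without history: same initial-event risks, resolves
    # to No BTH (a CAC event does not alter the further disease course)
    _fill_row(M, S.CAC_BTH,
              {S.INCC5_BTH: ev["no_to_incc5"], first_cac_dest: ev["no_to_cac"]},
              S.NO_BTH, q_bg, q_cac, rem)
    # first incomplete-C5 event
    if updose_flow and tp.updose_after_first_event:
        _fill_row(M, S.INCC5_BTH, {S.UPDOSE: updose_flow},
                  S.UPDOSE, q_bg, q_incc5, rem)
    else:
        _fill_row(M, S.INCC5_BTH,
                  {S.HX_INCC5_BTH: ev["second_incc5"], S.HX_CAC_BTH: ev["incc5_to_cac"]},
                  S.HX_NO_BTH, q_bg, q_incc5, rem)
    # history, currently event-free
    hx_cac_dest = S.HX_INCC5_BTH if cac_ladder else S.HX_CAC_BTH
    _fill_row(M, S.HX_NO_BTH,
              {S.HX_INCC5_BTH: ev["hx_to_incc5"], hx_cac_dest: ev["incc5_to_cac"]},
              S.HX_NO_BTH, q_bg, q_bg, rem)
    # second incomplete-C5 event: permanent up-dose (the 0.9994 flow and
    # the 0.0006 remission flow are jointly exhaustive)
    if updose_flow:
        _fill_row(M, S.HX_INCC5_BTH, {S.UPDOSE: updose_flow},
                  S.UPDOSE, q_bg, q_incc5, rem)
    else:
        _fill_row(M, S.HX_INCC5_BTH, {}, S.HX_NO_BTH, q_bg, q_incc5, rem)
    # CAC event with history
    _fill_row(M, S.HX_CAC_BTH,
              {S.HX_INCC5_BTH: ev["hx_to_incc5"], hx_cac_dest: ev["incc5_to_cac"]},
              S.HX_NO_BTH, q_bg, q_cac, rem)
    # permanently up-dosed branch: only CAC events remain possible
    _fill_row(M, S.UPDOSE, {S.UPDOSE_CAC_BTH: ev["updose_cac"]},
              S.UPDOSE, q_bg, q_bg, rem)
    _fill_row(M, S.UPDOSE_CAC_BTH, {S.UPDOSE_CAC_BTH: ev["updose_cac"]},
              S.UPDOSE, q_bg, q_cac, rem)
    # remission: only background death can end it
    M[S.REMISSION, S.DEATH_BACKGROUND] = q_bg
    M[S.REMISSION, S.REMISSION] = 1.0 - q_bg
    # absorbing death states
    M[S.DEATH_BACKGROUND, S.DEATH_BACKGROUND] = 1.0
    M[S.DEATH_PNH, S.DEATH_PNH] = 1.0
    return M
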