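"""Transition-matrix construction: stochasticity, published event
probabilities, mortality integration, extrapolation and absorption."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pnhcea import default_parameters
from pnhcea.states import Arm, CohortId, HealthState as S, cohort3
from pnhcea.transitions import (
    LifeTable,
    annual_prob_to_cycle_prob,
    bth_adjusted_death_prob,
    build_transition_matrix,
    matrix_for_conditions,
)

ARMS = (Arm.ECULIZUMAB, Arm.RAVULIZUMAB)


# --------------------------------------------------------------------------
# probability/rate conversion oracles
# --------------------------------------------------------------------------

@pytest.mark.parametrize("q,days,expected", [
    (0.0, 14, 0.0),
    (0.5, 365.25, 0.5),  # identity over a whole year
    # closed form 1 - 0.95**(14/365.25), frozen from 30-digit arithmetic
    (0.05, 14, 0.00196413596525),
])
def test_annual_to_cycle_probability(q, days, expected):
    assert annual_prob_to_cycle_prob(q, days) == pytest.approx(expected, abs=1e-9)


def test_annual_to_cycle_is_monotone_and_caps_at_one():
    qs = np.linspace(0, 0.999, 50)
    out = [annual_prob_to_cycle_prob(q, 14) for q in qs]
    assert all(b > a for a, b in zip(out, out[1:]))
    assert annual_prob_to_cycle_prob(1.0, 14) == 1.0


@pytest.mark.parametrize("q,hr,days,expected", [
    (0.0005, 1.0, 2, 0.0005),  # unit hazard ratio leaves q unchanged
    (0.0005, 4.8, 0, 0.0005),  # zero event duration leaves q unchanged
    # oracle: -ln(1-q)*(1 + 3.8*(2/14)) then 1-exp(-.)
    (0.0005, 4.8, 2, 1.0 - math.exp(math.log(1.0 - 0.0005) * (1.0 + 3.8 * 2.0 / 14.0))),
])
def test_bth_adjusted_death_probability(q, hr, days, expected):
    got = bth_adjusted_death_prob(q, hr, days, 14)
    assert got == pytest.approx(expected, rel=1e-12)
    assert got >= q - 1e-15 or hr < 1  # float-exact up to one ulp


def test_bth_adjustment_magnitude_matches_hand_calculation():
    # 0.0005 inflated by HR 4.8 over 2 of 14 days is about 7.71e-4
    assert bth_adjusted_death_prob(0.0005, 4.8, 2, 14) == pytest.approx(7.71e-4, rel=5e-3)


# --------------------------------------------------------------------------
# matrix structure
# --------------------------------------------------------------------------

def _cohort(p, cid):
    return next(c for c in p.cohorts if c.id == cid)


@pytest.mark.parametrize("cid", [CohortId.COHORT1, CohortId.COHORT2])
@pytest.mark.parametrize("arm", ARMS)
@pytest.mark.parametrize("cycle", [0, 5, 13, 14, 100, 700, 1300])
def test_rows_are_stochastic(life_table, cid, arm, cycle):
    p = default_parameters()
    M = build_transition_matrix(_cohort(p, cid), arm, cycle, p, life_table)
    assert np.all(M >= 0)
    np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
    # death rows are identity
    for d in (S.DEATH_BACKGROUND, S.DEATH_PNH):
        assert M[d, d] == 1.0


@settings(max_examples=50, deadline=None)
@given(q_bg=st.floats(0.0, 0.999), extrapolated=st.booleans(),
       arm=st.sampled_from(ARMS))
def test_rows_stochastic_for_any_background_mortality(q_bg, extrapolated, arm):
    p = default_parameters()
    M = matrix_for_conditions("cohort1", arm, extrapolated, q_bg, p)
    assert np.all(M >= -1e-15)
    np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)


def test_published_event_masses_before_mortality(life_table):
    """The pre-mortality transition masses equal the published two-weekly
    probabilities (rows are scaled by survival, so divide it back out)."""
    p = default_parameters()
    c1 = _cohort(p, CohortId.COHORT1)
    M = build_transition_matrix(c1, Arm.ECULIZUMAB, 0, p, life_table)
    surv = 1.0 - M[S.NO_BTH, S.DEATH_BACKGROUND] - M[S.NO_BTH, S.DEATH_PNH]
    assert M[S.NO_BTH, S.INCC5_BTH] / surv == pytest.approx(0.0031)
    assert M[S.NO_BTH, S.CAC_BTH] / surv == pytest.approx(0.0054)
    surv_e = 1.0 - M[S.INCC5_BTH, S.DEATH_BACKGROUND] - M[S.INCC5_BTH, S.DEATH_PNH]
    assert M[S.INCC5_BTH, S.HX_INCC5_BTH] / surv_e == pytest.approx(0.3313)
    assert M[S.INCC5_BTH, S.HX_CAC_BTH] / surv_e == pytest.approx(0.0054)
    # residual reproduces the published 0.6627 "to Hx: No BTH" row exactly
    assert M[S.INCC5_BTH, S.HX_NO_BTH] / surv_e == pytest.approx(0.6627)
    assert M[S.INCC5_BTH, S.REMISSION] / surv_e == pytest.approx(0.0006)


def test_naive_cohort_takes_on_stable_risk_after_26_weeks(life_table):
    p = default_parameters()
    c1 = _cohort(p, CohortId.COHORT1)
    # week 28 (cycle 14) is past the 26-week threshold: cohort-2 risks apply
    M = build_transition_matrix(c1, Arm.ECULIZUMAB, 14, p, life_table)
    surv = 1.0 - M[S.NO_BTH, S.DEATH_BACKGROUND] - M[S.NO_BTH, S.DEATH_PNH]
    assert M[S.NO_BTH, S.INCC5_BTH] / surv == pytest.approx(0.0010)
    assert M[S.NO_BTH, S.CAC_BTH] / surv == pytest.approx(0.0031)
    # cycle 12 (week 24) still uses cohort-1 risks
    M = build_transition_matrix(c1, Arm.ECULIZUMAB, 12, p, life_table)
    surv = 1.0 - M[S.NO_BTH, S.DEATH_BACKGROUND] - M[S.NO_BTH, S.DEATH_PNH]
    assert M[S.NO_BTH, S.INCC5_BTH] / surv == pytest.approx(0.0031)
    # the switch can be disabled
    p.transitions.extrapolate = False
    M = build_transition_matrix(c1, Arm.ECULIZUMAB, 14, p, life_table)
    surv = 1.0 - M[S.NO_BTH, S.DEATH_BACKGROUND] - M[S.NO_BTH, S.DEATH_PNH]
    assert M[S.NO_BTH, S.INCC5_BTH] / surv == pytest.approx(0.0031)


@pytest.mark.parametrize("cid", [CohortId.COHORT1, CohortId.COHORT2])
@pytest.mark.parametrize("cycle", [0, 50, 500])
def test_ravulizumab_never_enters_incc5_or_updose(life_table, cid, cycle):
    """No mass flows into incomplete-C5 or up-dose states from outside the
    (unreachable) up-dose branch under ravulizumab."""
    p = default_parameters()
    M = build_transition_matrix(_cohort(p, cid), Arm.RAVULIZUMAB, cycle, p, life_table)
    blocked = [S.INCC5_BTH, S.HX_INCC5_BTH, S.UPDOSE, S.UPDOSE_CAC_BTH]
    sources = [s for s in S if s not in (S.UPDOSE, S.UPDOSE_CAC_BTH)]
    assert M[np.ix_(sources, blocked)].sum() == 0.0


def test_remission_admits_only_background_death_exit(life_table):
    p = default_parameters()
    M = build_transition_matrix(_cohort(p, CohortId.COHORT1), Arm.ECULIZUMAB,
                                0, p, life_table)
    row = M[S.REMISSION].copy()
    row[S.REMISSION] = 0.0
    row[S.DEATH_BACKGROUND] = 0.0
    assert row.sum() == 0.0


def test_cohort3_enters_updosed_on_eculizumab_only():
    c3 = cohort3()
    assert c3.entry_state_for(Arm.ECULIZUMAB) == S.UPDOSE
    assert c3.entry_state_for(Arm.RAVULIZUMAB) == S.NO_BTH
    assert c3.param_cohort == CohortId.COHORT2


def test_age_cap_forces_death(life_table):
    p = default_parameters()
    c1 = _cohort(p, CohortId.COHORT1)
    # a cycle at or beyond the maximum age sends every living state to death
    cycle_at_cap = int(np.ceil((p.max_age - c1.start_age) * 365.25 / 14))
    M = build_transition_matrix(c1, Arm.ECULIZUMAB, cycle_at_cap, p, life_table)
    living = [s for s in S if s not in (S.DEATH_BACKGROUND, S.DEATH_PNH)]
    assert M[living][:, [S.DEATH_BACKGROUND, S.DEATH_PNH]].sum(axis=1) == pytest.approx(
        np.ones(len(living)))


def test_absorption_into_death_without_remission():
    """With remission off and an aged-out life table, all occupancy is
    absorbed into the death states."""
    p = default_parameters()
    p.transitions.remission_per_cycle = 0.0
    M = matrix_for_conditions("cohort1", Arm.ECULIZUMAB, False,
                              annual_prob_to_cycle_prob(0.9, 14), p)
    x = np.zeros(11)
    x[S.NO_BTH] = 1.0
    x = x @ np.linalg.matrix_power(M, 600)
    assert x[S.DEATH_BACKGROUND] + x[S.DEATH_PNH] == pytest.approx(1.0, abs=1e-10)


def test_higher_excess_hazard_never_decreases_pnh_deaths():
    p = default_parameters()
    cum = []
    for hr in (1.0, 2.0, 4.8, 10.0):
        q = p.copy()
        q.transitions.excess_mortality_hr = hr
        M = matrix_for_conditions("cohort1", Arm.ECULIZUMAB, False, 0.002, q)
        x = np.zeros(11)
        x[S.NO_BTH] = 1.0
        x = x @ np.linalg.matrix_power(M, 300)
        cum.append(x[S.DEATH_PNH])
    assert all(b >= a for a, b in zip(cum, cum[1:]))


def test_pnh_death_receives_exactly_the_excess_over_background():
    p = default_parameters()
    q_bg = 0.002
    M = matrix_for_conditions("cohort2", Arm.ECULIZUMAB, False, q_bg, p)
    q_adj = bth_adjusted_death_prob(q_bg, 4.8, 14.0, 14.0)
    assert M[S.CAC_BTH, S.DEATH_BACKGROUND] == pytest.approx(q_bg)
    assert M[S.CAC_BTH, S.DEATH_PNH] == pytest.approx(q_adj - q_bg)
    # non-event states carry no PNH-death flow
    assert M[S.NO_BTH, S.DEATH_PNH] == 0.0


# --------------------------------------------------------------------------
# life table
# --------------------------------------------------------------------------

def test_life_table_validation_and_lookup():
    lt = LifeTable(ages=np.arange(18, 30), qx=np.linspace(0.001, 0.01, 12))
    assert lt.annual_q(18.7) == pytest.approx(0.001)
    assert lt.annual_q(17) == pytest.approx(0.001)  # clamped below
    assert lt.annual_q(99) == pytest.approx(0.01)  # last row reused
    with pytest.raises(ValueError, match="contiguous"):
        LifeTable(ages=np.array([18, 20]), qx=np.array([0.1, 0.1]))
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        LifeTable(ages=np.array([18, 19]), qx=np.array([0.1, 1.2]))


def test_life_table_csv_round_trip(tmp_path, life_table):
    path = tmp_path / "lt.csv"
    life_table.to_csv(path)
    back = LifeTable.from_csv(path)
    np.testing.assert_array_equal(back.ages, life_table.ages)
    np.testing.assert_allclose(back.qx, life_table.qx)
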