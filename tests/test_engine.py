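"""Trace propagation, accrual, ICER logic and aggregation."""

import numpy as np
import pytest

from pnhcea import CostEffectivenessModel, aggregate, compute_icer, default_parameters
from pnhcea.engine import DOMINANT, DOMINATED
from pnhcea.states import Arm, CohortId, HealthState as S
from pnhcea.transitions import LifeTable, annual_prob_to_cycle_prob, matrix_for_conditions


def _cohort(p, cid):
    return next(c for c in p.cohorts if c.id == cid)


def _zero_events(p):
    for name in ("p_no_bth_to_incc5", "p_no_bth_to_cac",
                 "p_second_incc5_after_first", "p_incc5_to_cac",
                 "p_hx_no_bth_to_incc5", "p_updose_cac"):
        table = getattr(p.transitions, name)
        for ck in table:
            for a in table[ck]:
                table[ck][a] = 0.0
    p.transitions.remission_per_cycle = 0.0


def test_trace_rows_conserve_probability(base_model, params):
    for cid in (CohortId.COHORT1, CohortId.COHORT2):
        for arm in (Arm.ECULIZUMAB, Arm.RAVULIZUMAB):
            tr = base_model.run_trace(_cohort(params, cid), arm)
            np.testing.assert_allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-10)
            assert tr.occupancy[0, _cohort(params, cid).entry_state_for(arm)] == 1.0


def test_trace_conservation_over_1500_cycles(life_table, weight_table):
    p = default_parameters()
    p.max_age = 105.0  # stretch the horizon past 1,500 two-week cycles
    m = CostEffectivenessModel(p, life_table, weight_table)
    tr = m.run_trace(_cohort(p, CohortId.COHORT1), Arm.ECULIZUMAB)
    assert tr.n_cycles >= 1500
    np.testing.assert_allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-10)


def test_everybody_dead_at_the_age_cap(base_model, params):
    tr = base_model.run_trace(_cohort(params, CohortId.COHORT2), Arm.ECULIZUMAB)
    assert tr.occupancy[-1, [S.DEATH_BACKGROUND, S.DEATH_PNH]].sum() == pytest.approx(
        1.0, abs=1e-10)


def test_no_events_no_mortality_stays_in_entry_state(weight_table):
    p = default_parameters()
    _zero_events(p)
    lt = LifeTable(ages=np.arange(18, 102), qx=np.zeros(84))
    m = CostEffectivenessModel(p, lt, weight_table)
    tr = m.run_trace(_cohort(p, CohortId.COHORT2), Arm.ECULIZUMAB)
    # full mass stays put until the age cap forces death
    assert np.all(tr.occupancy[:-1, S.NO_BTH] == 1.0)


def test_three_state_reduction_matches_matrix_power_oracle(weight_table):
    """With all event flows zeroed the model reduces to alive/remission/
    dead; the engine trace must equal the explicit matrix-power solution
    to 1e-12 after 100 cycles."""
    p = default_parameters()
    _zero_events(p)
    p.transitions.remission_per_cycle = 0.0006
    q_annual = 0.01
    lt = LifeTable(ages=np.arange(18, 102), qx=np.full(84, q_annual))
    m = CostEffectivenessModel(p, lt, weight_table)
    c2 = _cohort(p, CohortId.COHORT2)
    tr = m.run_trace(c2, Arm.ECULIZUMAB)

    M = matrix_for_conditions("cohort2", Arm.ECULIZUMAB, False,
                              annual_prob_to_cycle_prob(q_annual, 14.0), p)
    x0 = np.zeros(11)
    x0[S.NO_BTH] = 1.0
    oracle = x0 @ np.linalg.matrix_power(M, 100)
    np.testing.assert_allclose(tr.occupancy[100], oracle, atol=1e-12)
    # and the occupancy really lives on only three states
    occupied = {s for s in S if tr.occupancy[100, s] > 0}
    assert occupied <= {S.NO_BTH, S.REMISSION, S.DEATH_BACKGROUND}


def test_one_cycle_drug_cost_arithmetic(life_table, weight_table):
    """One eculizumab maintenance cycle with every other cost off:
    3 x 4316 + 182.29 = 13,130.29."""
    p = default_parameters()
    p.horizon_years = 14.0 / 365.25
    from dataclasses import fields

    for f in fields(p.costs):
        v = getattr(p.costs, f.name)
        if isinstance(v, float) and f.name not in ("vial_ecu", "admin_ecu",
                                                   "pct_by_car"):
            setattr(p.costs, f.name, 0.0)
    p.include_societal = False
    m = CostEffectivenessModel(p, life_table, weight_table)
    res = m.run_arm(_cohort(p, CohortId.COHORT2), Arm.ECULIZUMAB)
    assert res.undiscounted["drug_admin"] == pytest.approx(13130.29)
    assert res.undiscounted["medical"] == 0.0


def test_zero_cost_parameters_zero_totals(life_table, weight_table):
    from dataclasses import fields

    p = default_parameters()
    for f in fields(p.costs):
        if isinstance(getattr(p.costs, f.name), float):
            setattr(p.costs, f.name, 0.0)
    m = CostEffectivenessModel(p, life_table, weight_table)
    for arm in (Arm.ECULIZUMAB, Arm.RAVULIZUMAB):
        res = m.run_arm(_cohort(p, CohortId.COHORT1), arm)
        assert res.total_cost == 0.0
        assert res.qalys > 0  # QALYs untouched by cost zeroing


def test_zero_discount_rates_make_discounted_equal_undiscounted(life_table, weight_table):
    p = default_parameters()
    p.discount_cost = 0.0
    p.discount_qaly = 0.0
    m = CostEffectivenessModel(p, life_table, weight_table)
    res = m.run_arm(_cohort(p, CohortId.COHORT2), Arm.RAVULIZUMAB)
    assert res.drug_admin == pytest.approx(res.undiscounted["drug_admin"], rel=1e-12)
    assert res.qalys == pytest.approx(res.undiscounted["qalys"], rel=1e-12)


def test_discounted_never_exceeds_undiscounted(base_results):
    for res in base_results.by_cohort.values():
        for arm_res in res.arms.values():
            assert arm_res.total_cost <= sum(
                arm_res.undiscounted[k] for k in ("drug_admin", "medical", "societal"))
            assert arm_res.qalys <= arm_res.undiscounted["qalys"]


def test_life_years_equal_across_arms_without_excess_mortality(life_table, weight_table):
    """Mortality-only limit: with the BTH hazard ratio at 1 and
    arm-independent transitions, survival is identical in both arms."""
    p = default_parameters()
    _zero_events(p)
    p.transitions.excess_mortality_hr = 1.0
    m = CostEffectivenessModel(p, life_table, weight_table)
    c = _cohort(p, CohortId.COHORT2)
    ly = {arm: m.run_arm(c, arm).life_years for arm in (Arm.ECULIZUMAB, Arm.RAVULIZUMAB)}
    assert ly[Arm.ECULIZUMAB] == pytest.approx(ly[Arm.RAVULIZUMAB], rel=1e-12)


@pytest.mark.parametrize("dc,dq,expected", [
    (-266833.0, 1.57, DOMINANT),
    (100.0, 2.0, 50.0),
    (100.0, -1.0, DOMINATED),
    (-100.0, -2.0, 50.0),  # south-west quadrant: a ratio, not a label
    (100.0, 0.0, float("inf")),
    (-100.0, 0.0, float("-inf")),
])
def test_icer_quadrant_logic(dc, dq, expected):
    assert compute_icer(dc, dq) == expected


def test_aggregate_of_identical_cohorts_is_identity(base_results):
    r = base_results.by_cohort["cohort2"]
    agg = aggregate({"cohort2": r, "clone": r}, {"cohort2": 0.5, "clone": 0.5})
    assert agg.delta_cost == pytest.approx(r.delta_cost)
    assert agg.delta_qalys == pytest.approx(r.delta_qalys)


def test_aggregate_increment_is_weighted_sum_of_cohort_increments(base_results):
    w = {"cohort1": 0.083 / 0.999, "cohort2": 0.916 / 0.999}
    expected = sum(w[k] * base_results.by_cohort[k].delta_cost for k in w)
    assert base_results.aggregate.delta_cost == pytest.approx(expected, abs=1e-9)


def test_results_summary_and_frame(base_results):
    text = base_results.summary()
    assert "aggregate" in text and "ICER" in text
    df = base_results.to_frame()
    assert {"population", "arm", "quantity", "value"} <= set(df.columns)
    assert set(df["population"]) == {"cohort1", "cohort2", "aggregate"}


def test_invalid_parameters_rejected_at_model_construction(life_table, weight_table):
    p = default_parameters()
    p.costs.vial_ecu = -5.0
    with pytest.raises(ValueError, match="vial_ecu"):
        CostEffectivenessModel(p, life_table, weight_table)


def test_half_cycle_correction_changes_little_but_something(life_table, weight_table):
    p = default_parameters()
    base = CostEffectivenessModel(p, life_table, weight_table).run_arm(
        _cohort(p, CohortId.COHORT2), Arm.ECULIZUMAB)
    q = default_parameters()
    q.half_cycle_correction = True
    hcc = CostEffectivenessModel(q, life_table, weight_table).run_arm(
        _cohort(q, CohortId.COHORT2), Arm.ECULIZUMAB)
    assert hcc.qalys != base.qalys
    assert hcc.qalys == pytest.approx(base.qalys, rel=0.01)
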