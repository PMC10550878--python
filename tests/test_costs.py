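"""Dosing calendars, vial counting and per-cycle cost components."""

import numpy as np
import pytest

from pnhcea import default_parameters
from pnhcea.costs import (
    WeightTable,
    doses_in_cycle,
    drug_admin_cost_per_cycle,
    event_and_transfusion_cost_per_cycle,
    infusion_societal_per_admin,
    societal_cost_per_cycle,
    travel_cost_per_visit,
    vaccination_cost,
    vials_for_dose,
)
from pnhcea.states import Arm, CohortId, HealthState as S, cohort3


def _cohort(p, cid):
    return next(c for c in p.cohorts if c.id == cid)


@pytest.mark.parametrize("mg,expected", [(900, 3), (1200, 4), (3300, 11), (2400, 8), (100, 1)])
def test_vials_for_dose_ceiling(mg, expected):
    assert vials_for_dose(mg) == expected


def test_vials_rejects_non_positive_dose():
    with pytest.raises(ValueError):
        vials_for_dose(0)


# --------------------------------------------------------------------------
# dosing calendars
# --------------------------------------------------------------------------

def test_eculizumab_experienced_cohort_gets_one_maintenance_dose_per_cycle(params):
    c2 = _cohort(params, CohortId.COHORT2)
    for cycle in (0, 1, 7, 100):
        doses = doses_in_cycle(Arm.ECULIZUMAB, c2, cycle, params.dosing)
        assert doses == [(0.0, 900.0)]


def test_eculizumab_updosed_cohort3_starts_at_1200mg(params):
    doses = doses_in_cycle(Arm.ECULIZUMAB, cohort3(), 0, params.dosing, up_dosed=True)
    assert doses == [(0.0, 1200.0)]


def test_eculizumab_naive_loading_calendar(params):
    """Five weekly 600 mg doses (days 0-28), then 900 mg every 14 days
    from day 35."""
    c1 = _cohort(params, CohortId.COHORT1)
    cal = []
    for cycle in range(5):
        for off, mg in doses_in_cycle(Arm.ECULIZUMAB, c1, cycle, params.dosing):
            cal.append((cycle * 14 + off, mg))
    assert cal == [(0.0, 600.0), (7.0, 600.0), (14.0, 600.0), (21.0, 600.0),
                   (28.0, 600.0), (35.0, 900.0), (49.0, 900.0), (63.0, 900.0)]


def test_ravulizumab_maintenance_every_fourth_cycle(params):
    """Loading at entry, maintenance at day 14 and then every 56 days:
    exactly one dose in every fourth cycle."""
    c2 = _cohort(params, CohortId.COHORT2)
    counts = [len(doses_in_cycle(Arm.RAVULIZUMAB, c2, t, params.dosing,
                                 weight_band="b")) for t in range(14)]
    assert counts == [1, 1, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0, 1]
    _, mg = doses_in_cycle(Arm.RAVULIZUMAB, c2, 5, params.dosing, weight_band="b")[0]
    assert mg == 3300.0


def test_steady_state_administration_frequencies(params):
    """Over any steady-state 56-day window: exactly 1 ravulizumab and
    exactly 4 eculizumab administrations (26 versus about 6.5 per year)."""
    c2 = _cohort(params, CohortId.COHORT2)
    for start in (20, 21, 22, 23, 300):
        rav = sum(len(doses_in_cycle(Arm.RAVULIZUMAB, c2, t, params.dosing,
                                     weight_band="b"))
                  for t in range(start, start + 4))
        ecu = sum(len(doses_in_cycle(Arm.ECULIZUMAB, c2, t, params.dosing))
                  for t in range(start, start + 4))
        assert rav == 1
        assert ecu == 4


# --------------------------------------------------------------------------
# drug / administration costs
# --------------------------------------------------------------------------

def test_eculizumab_maintenance_drug_cost(params):
    c2 = _cohort(params, CohortId.COHORT2)
    drug, admin = drug_admin_cost_per_cycle(S.NO_BTH, Arm.ECULIZUMAB, c2, 10, params)
    assert drug == pytest.approx(3 * 4316)  # = 12,948
    assert admin == pytest.approx(182.29)


def test_updosed_state_uses_four_vials(params):
    c2 = _cohort(params, CohortId.COHORT2)
    drug, _ = drug_admin_cost_per_cycle(S.UPDOSE, Arm.ECULIZUMAB, c2, 10, params)
    assert drug == pytest.approx(4 * 4316)  # = 17,264


@pytest.mark.parametrize("state", [S.REMISSION, S.DEATH_BACKGROUND, S.DEATH_PNH])
def test_untreated_states_cost_nothing(params, state):
    c2 = _cohort(params, CohortId.COHORT2)
    assert drug_admin_cost_per_cycle(state, Arm.ECULIZUMAB, c2, 3, params) == (0.0, 0.0)
    assert societal_cost_per_cycle(state, Arm.ECULIZUMAB, c2, 3, params) == (0.0, 0.0)


def test_drug_cost_is_linear_in_vial_price(params):
    c2 = _cohort(params, CohortId.COHORT2)
    base, _ = drug_admin_cost_per_cycle(S.NO_BTH, Arm.ECULIZUMAB, c2, 4, params)
    params.costs.vial_ecu *= 2
    doubled, _ = drug_admin_cost_per_cycle(S.NO_BTH, Arm.ECULIZUMAB, c2, 4, params)
    assert doubled == pytest.approx(2 * base)


def test_ravulizumab_weight_mix_expectation(params):
    c2 = _cohort(params, CohortId.COHORT2)
    mix = {"a": 0.25, "b": 0.5, "c": 0.25}
    drug, admin = drug_admin_cost_per_cycle(
        S.NO_BTH, Arm.RAVULIZUMAB, c2, 5, params, weight_mix=mix)
    expected = (0.25 * 10 + 0.5 * 11 + 0.25 * 12) * 4709
    assert drug == pytest.approx(expected)
    assert admin == pytest.approx(334.22)


def test_homecare_fraction_waives_ravulizumab_admin_tariff(params):
    c2 = _cohort(params, CohortId.COHORT2)
    params.costs.homecare_fraction_rav = 1.0
    _, admin = drug_admin_cost_per_cycle(
        S.NO_BTH, Arm.RAVULIZUMAB, c2, 5, params, weight_mix={"b": 1.0})
    assert admin == 0.0


def test_high_concentration_formulation_uses_eculizumab_tariff(params):
    params.costs.rav_highconc = True
    assert params.costs.admin_cost(Arm.RAVULIZUMAB) == 182.29
    assert params.costs.admin_productivity(Arm.RAVULIZUMAB) == 81.82


# --------------------------------------------------------------------------
# events, transfusions, societal
# --------------------------------------------------------------------------

def test_event_medical_costs(params):
    c1 = _cohort(params, CohortId.COHORT1)
    med, _ = event_and_transfusion_cost_per_cycle(
        S.INCC5_BTH, Arm.ECULIZUMAB, c1, params.costs, params.transfusions)
    assert med == pytest.approx(502.48)
    med, _ = event_and_transfusion_cost_per_cycle(
        S.CAC_BTH, Arm.ECULIZUMAB, c1, params.costs, params.transfusions)
    assert med == pytest.approx(869.14)


def test_transfusion_cost_cohort1_no_bth(params):
    # 0.09 x (225.26 + 1.59 x 230.60) ~= 53.27
    c1 = _cohort(params, CohortId.COHORT1)
    _, transf = event_and_transfusion_cost_per_cycle(
        S.NO_BTH, Arm.ECULIZUMAB, c1, params.costs, params.transfusions)
    assert transf == pytest.approx(53.27, abs=0.01)


def test_stable_ravulizumab_bth_transfusions_cost_nothing(params):
    c2 = _cohort(params, CohortId.COHORT2)
    _, transf = event_and_transfusion_cost_per_cycle(
        S.CAC_BTH, Arm.RAVULIZUMAB, c2, params.costs, params.transfusions)
    assert transf == 0.0


def test_travel_cost_per_infusion_visit(params):
    # 147 x 0.19 + 0.5 x 3 = 29.43
    assert travel_cost_per_visit(params.costs, 147) == pytest.approx(29.43)


def test_infusion_productivity_uses_effective_caregiver_multiplier(params):
    _, prod = infusion_societal_per_admin(Arm.ECULIZUMAB, params.costs)
    assert prod == pytest.approx(81.82 * 1.25)
    params.costs.caregiver_applies_to_all = True
    _, prod = infusion_societal_per_admin(Arm.ECULIZUMAB, params.costs)
    assert prod == pytest.approx(81.82 * 1.5)


def test_vaccination_only_for_naive_cohort(params):
    assert vaccination_cost(_cohort(params, CohortId.COHORT1), params.costs) == 142.42
    assert vaccination_cost(_cohort(params, CohortId.COHORT2), params.costs) == 0.0
    assert vaccination_cost(cohort3(), params.costs) == 0.0


def test_zero_unit_costs_zero_everything(params):
    from dataclasses import fields

    for f in fields(params.costs):
        if isinstance(getattr(params.costs, f.name), float):
            setattr(params.costs, f.name, 0.0)
    c1 = _cohort(params, CohortId.COHORT1)
    for state in S:
        assert drug_admin_cost_per_cycle(state, Arm.ECULIZUMAB, c1, 2, params) == (0, 0)
        med, tr = event_and_transfusion_cost_per_cycle(
            state, Arm.ECULIZUMAB, c1, params.costs, params.transfusions)
        assert med == 0 and tr == 0


# --------------------------------------------------------------------------
# weight table
# --------------------------------------------------------------------------

def test_band_fractions_sum_to_one_and_are_positive():
    wt = WeightTable(ages=np.arange(18, 102),
                     mean_kg=np.full(84, 75.0), sd_kg=np.full(84, 12.0))
    f = wt.band_fractions(50)
    assert sum(f.values()) == pytest.approx(1.0, abs=1e-12)
    assert all(v > 0 for v in f.values())


def test_degenerate_weight_distribution_is_a_point_mass():
    wt = WeightTable(ages=np.arange(18, 102),
                     mean_kg=np.full(84, 75.0), sd_kg=np.zeros(84))
    assert wt.band_fractions(40) == {"a": 0.0, "b": 1.0, "c": 0.0}


def test_weight_table_rejects_non_adult_means():
    with pytest.raises(ValueError, match="40 kg"):
        WeightTable(ages=np.arange(18, 20), mean_kg=np.array([39.0, 80.0]),
                    sd_kg=np.array([1.0, 1.0]))
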