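"""Model parameters: domain types, published defaults, and validation.

Every numeric default in this module is a published model input for the
Dutch cost-effectiveness comparison of ravulizumab versus eculizumab in
paroxysmal nocturnal hemoglobinuria (PNH): two-weekly transition
probabilities between breakthrough-haemolysis (BTH) states per starting
cohort and arm, transfusion requirements, utility decrements against the
age-adjusted Dutch general-population reference, and 2020 unit costs
from a societal perspective. Monetary values are euros (price year
2020); probabilities are per 2-week cycle unless stated otherwise.

Dict-valued fields are keyed by cohort id ("cohort1"/"cohort2") and arm
("eculizumab"/"ravulizumab") so that configuration overrides address any
scalar by a dotted path, e.g.
``transitions.p_no_bth_to_incc5.cohort1.eculizumab``.
"""

from __future__ import annotations

import copy
import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Any

from .states import Arm, Cohort, CohortId, HealthState, default_cohorts

ECU = Arm.ECULIZUMAB.value
RAV = Arm.RAVULIZUMAB.value
C1 = CohortId.COHORT1.value
C2 = CohortId.COHORT2.value

DAYS_PER_YEAR = 365.25


# --------------------------------------------------------------------------
# transition inputs
# --------------------------------------------------------------------------

def _default_transition_probs() -> dict[str, dict[str, dict[str, float]]]:
    # {field: {cohort: {arm: p}}}; ravulizumab has no incomplete-C5 events
    return {
        "p_no_bth_to_incc5": {C1: {ECU: 0.0031, RAV: 0.0}, C2: {ECU: 0.0010, RAV: 0.0}},
        "p_no_bth_to_cac": {C1: {ECU: 0.0054, RAV: 0.0026}, C2: {ECU: 0.0031, RAV: 0.0001}},
        "p_second_incc5_after_first": {C1: {ECU: 0.3313, RAV: 0.0}, C2: {ECU: 0.3321, RAV: 0.0}},
        "p_incc5_to_cac": {C1: {ECU: 0.0054, RAV: 0.0}, C2: {ECU: 0.0031, RAV: 0.0}},
        "p_hx_no_bth_to_incc5": {C1: {ECU: 0.1420, RAV: 0.0}, C2: {ECU: 0.3321, RAV: 0.0}},
        "p_updose_cac": {C1: {ECU: 0.0054, RAV: 0.0}, C2: {ECU: 0.0031, RAV: 0.0}},
    }


@dataclass
class TransitionParams:
    """Two-weekly BTH transition probabilities and mortality modifiers."""

    p_no_bth_to_incc5: dict = field(default_factory=lambda: _default_transition_probs()["p_no_bth_to_incc5"])
    p_no_bth_to_cac: dict = field(default_factory=lambda: _default_transition_probs()["p_no_bth_to_cac"])
    p_second_incc5_after_first: dict = field(default_factory=lambda: _default_transition_probs()["p_second_incc5_after_first"])
    p_incc5_to_cac: dict = field(default_factory=lambda: _default_transition_probs()["p_incc5_to_cac"])
    p_hx_no_bth_to_incc5: dict = field(default_factory=lambda: _default_transition_probs()["p_hx_no_bth_to_incc5"])
    p_updose_cac: dict = field(default_factory=lambda: _default_transition_probs()["p_updose_cac"])
    #: second-event state moves to permanent up-dose with this probability;
    #: the 0.0006 remainder is the spontaneous-remission flow (they sum to 1)
    p_incc5_to_updose: float = 0.9994
    #: any living state -> spontaneous remission, per cycle
    remission_per_cycle: float = 0.0006
    #: incomplete-C5 BTH events are treated at once and scaled over 2 days
    incc5_event_days: float = 2.0
    #: CAC-triggered BTH events last the full cycle
    cac_event_days: float = 14.0
    #: cohort-1 naive patients without an event take on cohort-2 risks after
    #: this many weeks of treatment (risk extrapolation beyond the trial)
    extrapolate_after_weeks: float = 26.0
    extrapolate: bool = True
    #: excess mortality hazard ratio during the scaled BTH event window
    excess_mortality_hr: float = 4.8
    #: scenario switch: no permanent up-dosing after a second event
    updosing_enabled: bool = True
    #: scenario switch: up-dose already after the first incomplete-C5 event
    updose_after_first_event: bool = False
    #: scenario switch: CAC events advance the up-dosing ladder too
    cac_counts_toward_updose: bool = False

    def prob(self, name: str, cohort: CohortId | str, arm: Arm | str) -> float:
        cohort = getattr(cohort, "value", cohort)
        arm = getattr(arm, "value", arm)
        return getattr(self, name)[cohort][arm]


# --------------------------------------------------------------------------
# transfusion inputs
# --------------------------------------------------------------------------

@dataclass
class TransfusionParams:
    """Per-cycle transfusion probability and pRBC units per transfusion,
    by cohort/arm and BTH status; SEs as published (0 means held fixed in
    sensitivity analyses). Stable ravulizumab patients with BTH received
    no transfusions in the stable-switch trial, hence the zero row."""

    prob: dict = field(default_factory=lambda: {
        "no_bth": {C1: {ECU: 0.09, RAV: 0.06}, C2: {ECU: 0.02, RAV: 0.02}},
        "bth": {C1: {ECU: 0.30, RAV: 0.17}, C2: {ECU: 0.38, RAV: 0.0}},
    })
    prob_se: dict = field(default_factory=lambda: {
        "no_bth": {C1: {ECU: 0.01, RAV: 0.01}, C2: {ECU: 0.0, RAV: 0.0}},
        "bth": {C1: {ECU: 0.10, RAV: 0.11}, C2: {ECU: 0.17, RAV: 0.0}},
    })
    units: dict = field(default_factory=lambda: {
        "no_bth": {C1: {ECU: 1.59, RAV: 1.68}, C2: {ECU: 1.57, RAV: 1.58}},
        "bth": {C1: {ECU: 1.83, RAV: 1.50}, C2: {ECU: 2.33, RAV: 0.0}},
    })
    units_se: dict = field(default_factory=lambda: {
        "no_bth": {C1: {ECU: 0.07, RAV: 0.09}, C2: {ECU: 0.12, RAV: 0.12}},
        "bth": {C1: {ECU: 0.17, RAV: 0.50}, C2: {ECU: 0.88, RAV: 0.0}},
    })


# --------------------------------------------------------------------------
# utility inputs
# --------------------------------------------------------------------------

_STATE_KEYS = {
    HealthState.NO_BTH: "no_bth",
    HealthState.INCC5_BTH: "incc5_bth",
    HealthState.CAC_BTH: "cac_bth",
    HealthState.HX_NO_BTH: "hx_no_bth",
    HealthState.HX_INCC5_BTH: "hx_incc5_bth",
    HealthState.HX_CAC_BTH: "hx_cac_bth",
    HealthState.UPDOSE: "updose",
    HealthState.UPDOSE_CAC_BTH: "updose_cac_bth",
}


def _default_decrements() -> dict[str, dict[str, dict[str, float]]]:
    # {cohort: {arm: {state_key: decrement}}}; ravulizumab cannot occupy
    # incomplete-C5 or up-dose states, so only its reachable states appear.
    ecu1 = {
        "no_bth": -0.097, "cac_bth": -0.180, "incc5_bth": -0.117,
        "hx_no_bth": -0.097, "hx_incc5_bth": -0.107, "hx_cac_bth": -0.180,
        "updose": -0.097, "updose_cac_bth": -0.180,
    }
    ecu2 = {
        "no_bth": -0.071, "cac_bth": -0.289, "incc5_bth": -0.122,
        "hx_no_bth": -0.071, "hx_incc5_bth": -0.095, "hx_cac_bth": -0.289,
        "updose": -0.071, "updose_cac_bth": -0.289,
    }
    rav1 = {"no_bth": -0.026, "cac_bth": -0.104}
    rav2 = {"no_bth": -0.002, "cac_bth": -0.194}
    return {C1: {ECU: ecu1, RAV: rav1}, C2: {ECU: ecu2, RAV: rav2}}


@dataclass
class UtilityParams:
    """State utilities = age-banded Dutch reference value + decrement.

    Decrements are relative to spontaneous remission and already net of
    the 0.070 discrete-choice-experiment increment for the eight-weekly
    ravulizumab schedule, so no further increment is added."""

    #: (age_lo, age_hi, utility); bands extend to the nearest band outside 35-74
    age_reference: list = field(default_factory=lambda: [
        [35, 44, 0.935], [45, 54, 0.890], [55, 64, 0.890], [65, 74, 0.886],
    ])
    decrements: dict = field(default_factory=_default_decrements)
    #: informational: the infusion-frequency utility increment already
    #: folded into the ravulizumab decrements
    dce_increment: float = 0.070
    #: scenario knob: days per cycle with incomplete-C5 BTH symptoms; the
    #: event-specific extra decrement scales by symptom_days/2
    symptom_days_incc5: float = 2.0
    #: cap state utilities at the age-banded reference (decrements <= 0
    #: make the cap inactive by construction; kept as an explicit switch)
    apply_utility_cap: bool = True

    def decrement(self, state: HealthState, cohort: CohortId | str, arm: Arm | str) -> float:
        cohort = getattr(cohort, "value", cohort)
        arm = getattr(arm, "value", arm)
        key = _STATE_KEYS[state]
        try:
            return self.decrements[cohort][arm][key]
        except KeyError:
            raise KeyError(
                f"no utility decrement for state {state.name} under {arm} in {cohort}"
            ) from None


# --------------------------------------------------------------------------
# cost inputs
# --------------------------------------------------------------------------

@dataclass
class DoseSchedule:
    """Dosing calendars. Eculizumab: five weekly 600 mg doses for naive
    patients, then 900 mg every 14 days (1200 mg when up-dosed).
    Ravulizumab: weight-band loading dose at entry, maintenance 14 days
    later and every 56 days thereafter."""

    ecu_initial_mg: float = 600.0
    ecu_initial_doses: int = 5
    ecu_maintenance_mg: float = 900.0
    ecu_updosed_mg: float = 1200.0
    ecu_interval_days: float = 14.0
    #: day of first maintenance dose for naive patients (toggle: the
    #: published wording also admits day 28; see methods note)
    ecu_maintenance_start_day: float = 35.0
    rav_loading_mg: dict = field(default_factory=lambda: {"a": 2400.0, "b": 2700.0, "c": 3000.0})
    rav_maintenance_mg: dict = field(default_factory=lambda: {"a": 3000.0, "b": 3300.0, "c": 3600.0})
    #: weight-band edges in kg: band a >=40-<60 (lighter adults clipped in),
    #: band b >=60-<100, band c >=100
    band_edges_kg: list = field(default_factory=lambda: [60.0, 100.0])
    rav_interval_days: float = 56.0
    rav_first_maintenance_day: float = 14.0
    vial_mg: float = 300.0


def _default_event_mix() -> dict[str, dict[str, float]]:
    # admission mix per BTH event backing the societal per-event costs;
    # chosen to reproduce the published weighted medical event costs from
    # the printed unit costs (ward day 678.99, haematologist visit 140.92):
    # incomplete-C5: 140.92 + 0.5325*678.99 ~= 502.48
    # CAC:           140.92 + 1.0725*678.99 ~= 869.14
    return {
        "incc5": {"ward_days": 0.5325, "icu_days": 0.0, "dialysis_periods": 0.0,
                  "hematologist_visits": 1.0, "travel_trips": 1.0},
        "cac": {"ward_days": 1.0725, "icu_days": 0.0, "dialysis_periods": 0.0,
                "hematologist_visits": 1.0, "travel_trips": 1.0},
    }


@dataclass
class CostParams:
    """Unit costs in 2020 euros (societal perspective)."""

    vial_ecu: float = 4316.0
    vial_rav: float = 4709.0
    admin_ecu: float = 182.29
    admin_rav: float = 334.22
    ward_day: float = 678.99
    icu_day: float = 2151.0
    dialysis_2wk: float = 5955.0
    hematologist_visit: float = 140.92
    incc5_event_medical: float = 502.48
    cac_event_medical: float = 869.14
    transfusion_admin: float = 225.26
    prbc_unit: float = 230.60
    vaccine_acwy: float = 46.43
    vaccine_b: float = 83.11
    ciprofloxacin: float = 12.88
    meningococcal_total: float = 142.42
    travel_per_km: float = 0.19
    parking: float = 3.00
    pct_by_car: float = 0.50
    km_infusion: float = 147.0
    km_event: float = 14.0
    productivity_ecu_admin: float = 81.82
    productivity_rav_admin: float = 112.51
    productivity_ward: float = 2811.0
    productivity_icu: float = 15930.0
    productivity_dialysis: float = 749.65
    productivity_hematologist: float = 187.41
    #: transfusion productivity hours are not published; default 4 h at the
    #: hourly rate implied by the eculizumab administration loss (81.82/4 h)
    productivity_transfusion: float = 81.82
    #: in-patient days the general-ward productivity lump (120 h) covers;
    #: used to pro-rate the lump over fractional admission days
    ward_admission_days: float = 5.0
    caregiver_multiplier: float = 1.5
    #: default: the caregiver uplift applies to the car-travelling half of
    #: patients (effective x1.25); switch to apply x1.5 to everyone
    caregiver_applies_to_all: bool = False
    #: fraction of ravulizumab infusions given as funded homecare (no
    #: administration tariff charged); scenario knob
    homecare_fraction_rav: float = 0.0
    #: high-concentration ravulizumab formulation: infusion time matches
    #: eculizumab, so administration tariff and productivity loss do too
    rav_highconc: bool = False
    #: charge one earlier-than-scheduled eculizumab dose (drug + admin +
    #: infusion-visit societal costs) per incomplete-C5 event; off by
    #: default — the published scenario arithmetic implies event costs
    #: carry no separate drug charge (see methods note)
    charge_extra_dose_on_incc5: bool = False
    event_mix: dict = field(default_factory=_default_event_mix)

    @property
    def effective_caregiver_multiplier(self) -> float:
        if self.caregiver_applies_to_all:
            return self.caregiver_multiplier
        return 1.0 + (self.caregiver_multiplier - 1.0) * self.pct_by_car

    def admin_cost(self, arm: Arm) -> float:
        if arm == Arm.RAVULIZUMAB:
            return self.admin_ecu if self.rav_highconc else self.admin_rav
        return self.admin_ecu

    def admin_productivity(self, arm: Arm) -> float:
        if arm == Arm.RAVULIZUMAB:
            return (self.productivity_ecu_admin if self.rav_highconc
                    else self.productivity_rav_admin)
        return self.productivity_ecu_admin


# --------------------------------------------------------------------------
# the assembled parameter set
# --------------------------------------------------------------------------

@dataclass
class ParameterSet:
    """The complete, validated collection of model inputs."""

    transitions: TransitionParams = field(default_factory=TransitionParams)
    transfusions: TransfusionParams = field(default_factory=TransfusionParams)
    utilities: UtilityParams = field(default_factory=UtilityParams)
    costs: CostParams = field(default_factory=CostParams)
    dosing: DoseSchedule = field(default_factory=DoseSchedule)
    discount_qaly: float = 0.015
    discount_cost: float = 0.04
    cycle_days: float = 14.0
    max_age: float = 101.0
    wtp: float = 20000.0
    #: optional horizon in years; None means lifetime (to max_age)
    horizon_years: float | None = None
    half_cycle_correction: bool = False
    include_societal: bool = True
    #: persistence of incomplete-C5 BTH, user-defined pass-through knob
    #: (no main-text semantics; stored and echoed, not consumed)
    incc5_persistence: float | None = None
    cohorts: list = field(default_factory=default_cohorts)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    @property
    def cycles_per_year(self) -> float:
        return DAYS_PER_YEAR / self.cycle_days

    def normalized_weights(self) -> dict[str, float]:
        """Cohort mix weights renormalised by their sum."""
        total = sum(c.mix_weight for c in self.cohorts)
        if total <= 0:
            raise ValueError("cohort mix weights sum to zero")
        return {c.id.value: c.mix_weight / total for c in self.cohorts}


@dataclass
class UncertaintyConfig:
    """Settings for probabilistic and one-way sensitivity analyses."""

    n_draws: int = 1000
    seed: int = 2020
    default_se_fraction: float = 0.25
    #: list prices are known with certainty; they enter the one-way
    #: analysis (flagged) but not the probabilistic one by default
    psa_include_drug_prices: bool = False
    owsa_bounds: tuple = (0.025, 0.975)
    wtp_grid: list = field(default_factory=lambda: [
        0, 5_000, 10_000, 20_000, 30_000, 40_000, 50_000, 80_000, 100_000,
    ])


def default_parameters() -> ParameterSet:
    """The published base-case parameter set."""
    return ParameterSet()


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def _walk_scalars(obj: Any, prefix: str):
    """Yield (dotted_path, value) for every scalar leaf of a parameter object."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        for f in dataclasses.fields(obj):
            yield from _walk_scalars(getattr(obj, f.name), f"{prefix}{f.name}.")
    elif isinstance(obj, dict):
        for k, v in obj.items():
            yield from _walk_scalars(v, f"{prefix}{k}.")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            yield from _walk_scalars(v, f"{prefix}{i}.")
    else:
        yield prefix[:-1], obj


_PROBABILITY_PREFIXES = (
    "transitions.p_", "transitions.remission_per_cycle",
    "transfusions.prob.", "costs.pct_by_car", "costs.homecare_fraction_rav",
)


def validate_parameters(p: ParameterSet) -> list[str]:
    """Check every invariant; violations are returned, never raised.

    Cohort mix weights that do not sum to 1 are not a violation (they are
    renormalised) but do emit a warning record."""
    v: list[str] = []
    for path, value in _walk_scalars(p, ""):
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            continue
        if any(path.startswith(pre) for pre in _PROBABILITY_PREFIXES):
            if not (0.0 <= value <= 1.0):
                v.append(f"{path}={value}: probability must lie in [0, 1]")
        elif path.startswith("costs.") and value < 0:
            v.append(f"{path}={value}: unit cost must be non-negative")
        elif path.startswith("transfusions.units") and value < 0:
            v.append(f"{path}={value}: pRBC units must be non-negative")
        elif path.startswith("utilities.decrements") and value > 0:
            v.append(f"{path}={value}: utility decrement must be <= 0")
    for rate_name in ("discount_qaly", "discount_cost"):
        r = getattr(p, rate_name)
        if not (0.0 <= r < 1.0):
            v.append(f"{rate_name}={r}: annual rate must lie in [0, 1)")
    if p.cycle_days <= 0:
        v.append(f"cycle_days={p.cycle_days}: must be positive")
    if p.transitions.incc5_event_days > p.cycle_days:
        v.append(
            f"transitions.incc5_event_days={p.transitions.incc5_event_days}: "
            f"must not exceed cycle_days={p.cycle_days}"
        )
    for lo, hi, u in p.utilities.age_reference:
        if not (0.0 <= u <= 1.0):
            v.append(f"utilities.age_reference[{lo}-{hi}]={u}: utility must lie in [0, 1]")
    for c in p.cohorts:
        if c.start_age < 18:
            v.append(f"cohorts.{c.id.value}.start_age={c.start_age}: must be >= 18 (adult model)")
    total_weight = sum(c.mix_weight for c in p.cohorts)
    if total_weight <= 0:
        v.append("cohorts: mix weights must have a positive sum")
    elif abs(total_weight - 1.0) > 5e-3:
        # the published 0.083/0.916 split sums to 0.999 (rounding); only
        # clearly non-normalised mixes warrant a warning record
        warnings.warn(
            f"cohort mix weights sum to {total_weight:.6g}; renormalising by their sum",
            UserWarning,
            stacklevel=2,
        )
    return v
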