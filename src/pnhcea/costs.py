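"""Per-cycle cost components: drug and administration, medical events,
transfusions, vaccination, and societal (travel + productivity) costs.

Drug costs are vial-based with no vial sharing: a 900 mg eculizumab
maintenance dose is three 300 mg vials, the permanent up-dose adds one
vial (1200 mg), and ravulizumab doses follow the label's weight bands.
Weight-band fractions come from an age-indexed normal weight
distribution; adults lighter than 40 kg are clipped into the lowest
band (the model covers adults only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .params import CostParams, DoseSchedule, ParameterSet, TransfusionParams
from .states import (
    Arm,
    BTH_STATES,
    Cohort,
    HealthState,
    LIVING_STATES,
    UPDOSED_STATES,
)

S = HealthState
BANDS = ("a", "b", "c")


def vials_for_dose(dose_mg: float, vial_mg: float = 300.0) -> int:
    """Whole vials needed for a dose; no vial sharing between patients."""
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    return math.ceil(dose_mg / vial_mg)


# --------------------------------------------------------------------------
# weight table and dosing bands
# --------------------------------------------------------------------------

@dataclass
class WeightTable:
    """Mean/SD of body weight (kg) by integer age; the ravulizumab dose
    bands are the normal-distribution mass in [<60), [60, 100), [>=100)."""

    ages: np.ndarray
    mean_kg: np.ndarray
    sd_kg: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.mean_kg = np.asarray(self.mean_kg, dtype=float)
        self.sd_kg = np.asarray(self.sd_kg, dtype=float)
        if np.any(self.mean_kg <= 40):
            raise ValueError("adult mean weight must exceed 40 kg")
        if np.any(self.sd_kg < 0):
            raise ValueError("weight SD must be non-negative")

    @classmethod
    def from_csv(cls, path) -> "WeightTable":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WeightTable":
        cols = {c.lower(): c for c in df.columns}
        try:
            return cls(
                df[cols["age"]].to_numpy(),
                df[cols["mean_kg"]].to_numpy(),
                df[cols["sd_kg"]].to_numpy(),
            )
        except KeyError:
            raise ValueError(
                "weight table needs columns 'age', 'mean_kg', 'sd_kg'"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "mean_kg": self.mean_kg, "sd_kg": self.sd_kg}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def band_fractions(self, age: float, edges=(60.0, 100.0)) -> dict[str, float]:
        """Fractions of patients in each ravulizumab dosing band at an age.

        Patients below 40 kg are clipped into band a, so band a is all
        mass below the first edge."""
        idx = int(np.clip(math.floor(age) - self.ages[0], 0, len(self.ages) - 1))
        mu, sd = self.mean_kg[idx], self.sd_kg[idx]
        if sd == 0:
            f_a = 1.0 if mu < edges[0] else 0.0
            f_c = 1.0 if mu >= edges[1] else 0.0
            return {"a": f_a, "b": 1.0 - f_a - f_c, "c": f_c}
        p_lo = norm.cdf(edges[0], mu, sd)
        p_hi = norm.cdf(edges[1], mu, sd)
        return {"a": float(p_lo), "b": float(p_hi - p_lo), "c": float(1.0 - p_hi)}


# --------------------------------------------------------------------------
# dosing calendars
# --------------------------------------------------------------------------

def doses_in_cycle(
    arm: Arm,
    cohort: Cohort,
    cycle_index: int,
    dosing: DoseSchedule,
    up_dosed: bool = False,
    weight_band: str = "b",
    cycle_days: float = 14.0,
) -> list[tuple[float, float]]:
    """Administrations (day offset within the cycle, dose in mg) falling
    inside ``[cycle_index*cycle_days, (cycle_index+1)*cycle_days)``.

    Eculizumab for naive patients: five weekly 600 mg doses from day 0,
    then maintenance every 14 days from day 35. Experienced cohorts:
    maintenance at day 0 of every cycle. Ravulizumab: weight-band loading
    at day 0, first maintenance at day 14, then every 56 days.
    """
    start = cycle_index * cycle_days
    end = start + cycle_days
    doses: list[tuple[float, float]] = []
    if arm == Arm.ECULIZUMAB:
        maint_mg = dosing.ecu_updosed_mg if up_dosed else dosing.ecu_maintenance_mg
        if cohort.eculizumab_loading_phase:
            for k in range(dosing.ecu_initial_doses):
                d = 7.0 * k
                if start <= d < end:
                    doses.append((d - start, dosing.ecu_initial_mg))
            d = dosing.ecu_maintenance_start_day
            while d < end:
                if d >= start:
                    doses.append((d - start, maint_mg))
                d += dosing.ecu_interval_days
        else:
            d = 0.0
            while d < end:
                if d >= start:
                    doses.append((d - start, maint_mg))
                d += dosing.ecu_interval_days
    else:
        if start <= 0 < end:
            doses.append((0.0, dosing.rav_loading_mg[weight_band]))
        d = dosing.rav_first_maintenance_day
        while d < end:
            if d >= start:
                doses.append((d - start, dosing.rav_maintenance_mg[weight_band]))
            d += dosing.rav_interval_days
    return doses


# --------------------------------------------------------------------------
# per-cycle cost components
# --------------------------------------------------------------------------

def drug_admin_cost_per_cycle(
    state: HealthState,
    arm: Arm,
    cohort: Cohort,
    cycle_index: int,
    p: ParameterSet,
    weight_mix: dict[str, float] | None = None,
) -> tuple[float, float]:
    """Expected (drug €, administration €) for a cycle spent in a state.

    Remission and death states cost nothing (treatment stops); up-dosed
    states use the 1200 mg eculizumab dose. For ravulizumab the cost is
    the weight-band mixture expectation, and the funded-homecare fraction
    waives the administration tariff.
    """
    if state not in LIVING_STATES or state == S.REMISSION:
        return (0.0, 0.0)
    c = p.costs
    if arm == Arm.ECULIZUMAB:
        doses = doses_in_cycle(
            arm, cohort, cycle_index, p.dosing,
            up_dosed=state in UPDOSED_STATES, cycle_days=p.cycle_days,
        )
        drug = sum(vials_for_dose(mg, p.dosing.vial_mg) * c.vial_ecu for _, mg in doses)
        admin = len(doses) * c.admin_cost(arm)
        return (drug, admin)
    weight_mix = weight_mix or {"b": 1.0}
    drug = 0.0
    n_admin = 0.0
    for band, frac in weight_mix.items():
        if frac == 0.0:
            continue
        doses = doses_in_cycle(
            arm, cohort, cycle_index, p.dosing,
            weight_band=band, cycle_days=p.cycle_days,
        )
        drug += frac * sum(
            vials_for_dose(mg, p.dosing.vial_mg) * c.vial_rav for _, mg in doses
        )
        n_admin += frac * len(doses)
    admin = n_admin * c.admin_cost(arm) * (1.0 - c.homecare_fraction_rav)
    return (drug, admin)


def administration_count(
    arm: Arm, cohort: Cohort, cycle_index: int, p: ParameterSet
) -> float:
    """Number of infusion visits in a cycle (band-independent)."""
    return float(len(doses_in_cycle(arm, cohort, cycle_index, p.dosing,
                                    cycle_days=p.cycle_days)))


def _transfusion_class(state: HealthState) -> str | None:
    if state in BTH_STATES:
        return "bth"
    if state in LIVING_STATES and state != S.REMISSION:
        return "no_bth"
    return None


def event_and_transfusion_cost_per_cycle(
    state: HealthState,
    arm: Arm,
    cohort: Cohort,
    c: CostParams,
    t: TransfusionParams,
) -> tuple[float, float]:
    """(per-event medical €, expected transfusion €) for a state.

    The medical component is the published weighted cost per breakthrough
    event and is charged by the engine on the inflow into the event
    state; the transfusion component is an expectation per cycle of
    occupancy (probability x [administration + units x pRBC price])."""
    medical = 0.0
    if state in (S.INCC5_BTH, S.HX_INCC5_BTH):
        medical = c.incc5_event_medical
    elif state in (S.CAC_BTH, S.HX_CAC_BTH, S.UPDOSE_CAC_BTH):
        medical = c.cac_event_medical
    cls = _transfusion_class(state)
    transfusion = 0.0
    if cls is not None:
        key, a = cohort.param_cohort.value, arm.value
        prob = t.prob[cls][key][a]
        units = t.units[cls][key][a]
        transfusion = prob * (c.transfusion_admin + units * c.prbc_unit)
    return (medical, transfusion)


def travel_cost_per_visit(c: CostParams, km: float) -> float:
    """Round-trip travel cost of one visit; half of patients drive and pay
    parking."""
    return km * c.travel_per_km + c.pct_by_car * c.parking


def infusion_societal_per_admin(arm: Arm, c: CostParams) -> tuple[float, float]:
    """(travel €, productivity €) per infusion visit."""
    travel = travel_cost_per_visit(c, c.km_infusion)
    productivity = c.admin_productivity(arm) * c.effective_caregiver_multiplier
    return (travel, productivity)


def event_societal_cost(event_type: str, c: CostParams) -> tuple[float, float]:
    """(travel €, productivity €) per breakthrough event, from the
    admission mix behind the weighted per-event medical costs."""
    mix = c.event_mix[event_type]
    trips = mix["travel_trips"] + 7.0 * mix["dialysis_periods"]
    travel = trips * travel_cost_per_visit(c, c.km_event)
    ward_days = c.ward_admission_days if c.ward_admission_days > 0 else 1.0
    productivity = (
        mix["ward_days"] / ward_days * c.productivity_ward
        + mix["icu_days"] * c.productivity_icu
        + mix["dialysis_periods"] * c.productivity_dialysis
        + mix["hematologist_visits"] * c.productivity_hematologist
    ) * c.effective_caregiver_multiplier
    return (travel, productivity)


def transfusion_societal_per_cycle(
    state: HealthState, arm: Arm, cohort: Cohort, c: CostParams, t: TransfusionParams
) -> tuple[float, float]:
    """Expected (travel €, productivity €) per cycle from transfusions."""
    cls = _transfusion_class(state)
    if cls is None:
        return (0.0, 0.0)
    prob = t.prob[cls][cohort.param_cohort.value][arm.value]
    travel = prob * travel_cost_per_visit(c, c.km_event)
    productivity = prob * c.productivity_transfusion * c.effective_caregiver_multiplier
    return (travel, productivity)


def societal_cost_per_cycle(
    state: HealthState,
    arm: Arm,
    cohort: Cohort,
    cycle_index: int,
    p: ParameterSet,
) -> tuple[float, float]:
    """Occupancy-based (travel €, productivity €) for a cycle in a state:
    infusion visits plus expected transfusions. Per-event societal costs
    are charged separately on event-state inflow."""
    if state not in LIVING_STATES or state == S.REMISSION:
        return (0.0, 0.0)
    c = p.costs
    n_admin = administration_count(arm, cohort, cycle_index, p)
    tr_a, pr_a = infusion_societal_per_admin(arm, c)
    tr_t, pr_t = transfusion_societal_per_cycle(state, arm, cohort, c, p.transfusions)
    return (n_admin * tr_a + tr_t, n_admin * pr_a + pr_t)


def extra_dose_cost_on_incc5(arm: Arm, c: CostParams, dosing: DoseSchedule) -> tuple[float, float, float, float]:
    """(drug, administration, travel, productivity) of the one
    earlier-than-scheduled eculizumab dose given at an incomplete-C5
    event; zero if the toggle is off or the arm is ravulizumab (which
    has no such events)."""
    if arm == Arm.RAVULIZUMAB or not c.charge_extra_dose_on_incc5:
        return (0.0, 0.0, 0.0, 0.0)
    drug = vials_for_dose(dosing.ecu_maintenance_mg, dosing.vial_mg) * c.vial_ecu
    admin = c.admin_ecu
    travel, productivity = infusion_societal_per_admin(Arm.ECULIZUMAB, c)
    return (drug, admin, travel, productivity)


def vaccination_cost(cohort: Cohort, c: CostParams) -> float:
    """Meningococcal prophylaxis bundle, once at entry for naive patients."""
    return c.meningococcal_total if cohort.vaccinate_at_entry else 0.0
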