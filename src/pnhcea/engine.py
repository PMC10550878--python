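"""The Markov cohort engine and the model/results objects.

`CostEffectivenessModel` is built from a parameter set plus the two
external data tables (background life table, weight-by-age table); its
`run()` evaluates the deterministic base case for every cohort and the
aggregate population and returns a `CEAResults` object carrying the
discounted cost breakdown, QALYs, increments and dominance label, with
a `summary()` table. Probabilistic and one-way sensitivity analyses and
the named scenarios hang off the same object (see `uncertainty` and
`scenarios`).

Accrual conventions: occupancy-based quantities (drug schedule,
utilities, transfusions, infusion societal costs) accrue on the
start-of-cycle state occupancy; event-incidence quantities (per-event
medical cost, the earlier-than-scheduled eculizumab dose, per-event
travel and productivity) are charged on the transition inflow into the
event states. No half-cycle correction by default (switchable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costs import (
    WeightTable,
    doses_in_cycle,
    event_societal_cost,
    extra_dose_cost_on_incc5,
    infusion_societal_per_admin,
    event_and_transfusion_cost_per_cycle,
    transfusion_societal_per_cycle,
    vaccination_cost,
    vials_for_dose,
)
from .params import DAYS_PER_YEAR, ParameterSet
from .states import (
    Arm,
    Cohort,
    HealthState,
    LIVING_STATES,
    N_STATES,
    ON_TREATMENT_STATES,
    UPDOSED_STATES,
)
from .transitions import LifeTable, annual_prob_to_cycle_prob, matrix_for_conditions
from .utilities import utility_vector

S = HealthState

_INCC5_EVENT = (S.INCC5_BTH, S.HX_INCC5_BTH)
_CAC_EVENT = (S.CAC_BTH, S.HX_CAC_BTH, S.UPDOSE_CAC_BTH)


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class Trace:
    """Cohort occupancy per state per cycle; row 0 is model entry."""

    occupancy: np.ndarray  # (n_cycles + 1, 11)
    ages: np.ndarray  # age at the start of each cycle, length n_cycles + 1
    cohort: Cohort = None
    arm: Arm = None

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


@dataclass
class ArmResult:
    """Discounted totals per treatment arm, with undiscounted twins."""

    drug_admin: float
    medical: float
    societal: float
    qalys: float
    life_years: float
    undiscounted: dict = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        return self.drug_admin + self.medical + self.societal

    def as_dict(self) -> dict:
        return {
            "drug_admin_costs": self.drug_admin,
            "medical_costs": self.medical,
            "societal_costs": self.societal,
            "total_costs": self.total_cost,
            "qalys": self.qalys,
            "life_years": self.life_years,
        }


DOMINANT = "dominant"
DOMINATED = "dominated"


def compute_icer(delta_cost: float, delta_qaly: float):
    """Quadrant logic: cheaper and more effective is dominant, costlier
    and less effective is dominated, otherwise the cost/QALY ratio
    (signed infinity when QALYs are exactly tied)."""
    if delta_cost < 0 and delta_qaly > 0:
        return DOMINANT
    if delta_cost > 0 and delta_qaly < 0:
        return DOMINATED
    if delta_qaly == 0:
        return math.inf if delta_cost > 0 else (-math.inf if delta_cost < 0 else 0.0)
    return delta_cost / delta_qaly


@dataclass
class CEAResult:
    """Cost-effectiveness comparison for one population: both arms,
    increments (ravulizumab minus eculizumab) and the ICER/dominance
    label."""

    label: str
    arms: dict  # arm value -> ArmResult

    @property
    def delta_cost(self) -> float:
        return (self.arms[Arm.RAVULIZUMAB.value].total_cost
                - self.arms[Arm.ECULIZUMAB.value].total_cost)

    @property
    def delta_qalys(self) -> float:
        return (self.arms[Arm.RAVULIZUMAB.value].qalys
                - self.arms[Arm.ECULIZUMAB.value].qalys)

    @property
    def icer(self):
        return compute_icer(self.delta_cost, self.delta_qalys)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm, res in self.arms.items():
            for k, v in res.as_dict().items():
                rows.append({"population": self.label, "arm": arm,
                             "quantity": k, "value": v})
        rows.append({"population": self.label, "arm": "difference",
                     "quantity": "total_costs", "value": self.delta_cost})
        rows.append({"population": self.label, "arm": "difference",
                     "quantity": "qalys", "value": self.delta_qalys})
        icer = self.icer
        rows.append({"population": self.label, "arm": "difference",
                     "quantity": "icer",
                     "value": icer if isinstance(icer, float) else np.nan})
        rows.append({"population": self.label, "arm": "difference",
                     "quantity": "outcome_label",
                     "value": icer if isinstance(icer, str) else "icer"})
        return pd.DataFrame(rows)


def aggregate(results: dict[str, CEAResult], weights: dict[str, float]) -> CEAResult:
    """Mix per-cohort results by renormalised weights; every cost and
    QALY component is a weighted mean and the ICER is recomputed from
    the aggregated increments (ratio of means, never mean of ratios)."""
    total = sum(weights[k] for k in results)
    arms = {}
    for arm in (Arm.ECULIZUMAB.value, Arm.RAVULIZUMAB.value):
        agg = {}
        und = {}
        for key in ("drug_admin", "medical", "societal", "qalys", "life_years"):
            agg[key] = sum(
                weights[k] / total * getattr(results[k].arms[arm], key)
                for k in results
            )
        for key in next(iter(results.values())).arms[arm].undiscounted:
            und[key] = sum(
                weights[k] / total * results[k].arms[arm].undiscounted[key]
                for k in results
            )
        arms[arm] = ArmResult(**agg, undiscounted=und)
    return CEAResult(label="aggregate", arms=arms)


class CEAResults:
    """Results of a deterministic model run: one `CEAResult` per cohort
    plus the weighted aggregate population."""

    def __init__(self, by_cohort: dict[str, CEAResult], agg: CEAResult,
                 params: ParameterSet):
        self.by_cohort = by_cohort
        self.aggregate = agg
        self.params = params

    def to_frame(self) -> pd.DataFrame:
        frames = [r.to_frame() for r in self.by_cohort.values()]
        frames.append(self.aggregate.to_frame())
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = ["Cost-effectiveness of ravulizumab vs eculizumab",
                 "(discounted; costs in 2020 EUR, rounded to whole euros)", ""]
        fmt = "{:<28}{:>16}{:>16}{:>16}"
        for label, res in {**self.by_cohort, "aggregate": self.aggregate}.items():
            lines.append(f"[{label}]")
            lines.append(fmt.format("", "ravulizumab", "eculizumab", "difference"))
            rav = res.arms[Arm.RAVULIZUMAB.value]
            ecu = res.arms[Arm.ECULIZUMAB.value]
            for name, attr in [("Drug and administration", "drug_admin"),
                               ("Medical costs", "medical"),
                               ("Societal costs", "societal")]:
                r, e = getattr(rav, attr), getattr(ecu, attr)
                lines.append(fmt.format(name, f"{r:,.0f}", f"{e:,.0f}", f"{r - e:,.0f}"))
            lines.append(fmt.format("Total costs", f"{rav.total_cost:,.0f}",
                                    f"{ecu.total_cost:,.0f}",
                                    f"{res.delta_cost:,.0f}"))
            lines.append(fmt.format("Total effects (QALY)", f"{rav.qalys:.2f}",
                                    f"{ecu.qalys:.2f}", f"{res.delta_qalys:.2f}"))
            icer = res.icer
            icer_str = icer if isinstance(icer, str) else f"{icer:,.0f}"
            lines.append(fmt.format("ICER (EUR/QALY)", "", "", icer_str))
            lines.append("")
        return "\n".join(lines)


_schedule_cache: dict[tuple, tuple] = {}


def _dosing_key(p: ParameterSet) -> tuple:
    d = p.dosing
    return (
        d.ecu_initial_mg, d.ecu_initial_doses, d.ecu_maintenance_mg,
        d.ecu_updosed_mg, d.ecu_interval_days, d.ecu_maintenance_start_day,
        tuple(sorted(d.rav_loading_mg.items())),
        tuple(sorted(d.rav_maintenance_mg.items())),
        tuple(d.band_edges_kg), d.rav_interval_days,
        d.rav_first_maintenance_day, d.vial_mg, p.cycle_days,
    )


def _dose_schedule_arrays(arm: Arm, cohort: Cohort, T: int, p: ParameterSet,
                          weight_table: WeightTable, ages: np.ndarray):
    """Per-cycle expected vial counts (normal / up-dosed maintenance) and
    administration counts; memoised because vial counts are independent
    of prices and of every sampled parameter."""
    key = (arm.value, cohort.id.value, cohort.eculizumab_loading_phase,
           round(float(cohort.start_age), 6), T, _dosing_key(p),
           id(weight_table))
    hit = _schedule_cache.get(key)
    if hit is not None:
        return hit
    vials_normal = np.zeros(T)
    vials_updosed = np.zeros(T)
    n_admin = np.zeros(T)
    if arm == Arm.ECULIZUMAB:
        for t in range(T):
            doses = doses_in_cycle(arm, cohort, t, p.dosing,
                                   up_dosed=False, cycle_days=p.cycle_days)
            vials_normal[t] = sum(
                vials_for_dose(mg, p.dosing.vial_mg) for _, mg in doses)
            doses_u = doses_in_cycle(arm, cohort, t, p.dosing,
                                     up_dosed=True, cycle_days=p.cycle_days)
            vials_updosed[t] = sum(
                vials_for_dose(mg, p.dosing.vial_mg) for _, mg in doses_u)
            n_admin[t] = len(doses)
    else:
        band_cache: dict[int, dict[str, float]] = {}
        for t in range(T):
            age_key = int(math.floor(ages[t]))
            mix = band_cache.get(age_key)
            if mix is None:
                mix = weight_table.band_fractions(
                    ages[t], tuple(p.dosing.band_edges_kg))
                band_cache[age_key] = mix
            count = 0.0
            vials = 0.0
            for band, frac in mix.items():
                if frac == 0.0:
                    continue
                doses = doses_in_cycle(arm, cohort, t, p.dosing,
                                       weight_band=band,
                                       cycle_days=p.cycle_days)
                vials += frac * sum(
                    vials_for_dose(mg, p.dosing.vial_mg) for _, mg in doses)
                count += frac * len(doses)
            vials_normal[t] = vials
            vials_updosed[t] = vials
            n_admin[t] = count
    if len(_schedule_cache) > 64:
        _schedule_cache.clear()
    _schedule_cache[key] = (vials_normal, vials_updosed, n_admin)
    return vials_normal, vials_updosed, n_admin


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

class CostEffectivenessModel:
    """Markov cohort model of C5-inhibitor treatment in PNH.

    Parameters
    ----------
    params : ParameterSet
        Validated model inputs (defaults are the published base case).
    life_table : LifeTable
        Background annual mortality by age.
    weight_table : WeightTable
        Body-weight mean/SD by age, for the ravulizumab dose bands.
    """

    def __init__(self, params: ParameterSet, life_table: LifeTable,
                 weight_table: WeightTable):
        from .params import validate_parameters

        violations = validate_parameters(params)
        if violations:
            raise ValueError("invalid parameters:\n" + "\n".join(violations))
        self.params = params
        self.life_table = life_table
        self.weight_table = weight_table

    # -- horizon ----------------------------------------------------------

    def _n_cycles(self, cohort: Cohort) -> int:
        p = self.params
        # +1: the final cycle at or beyond the maximum age forces death
        cycles_to_cap = math.ceil(
            (p.max_age - cohort.start_age) * DAYS_PER_YEAR / p.cycle_days
        ) + 1
        if p.horizon_years is not None:
            return min(cycles_to_cap,
                       math.floor(p.horizon_years * DAYS_PER_YEAR / p.cycle_days
                                  + 1e-9))
        return cycles_to_cap

    # -- trace ------------------------------------------------------------

    def run_trace(self, cohort: Cohort, arm: Arm) -> Trace:
        p = self.params
        tp = p.transitions
        T = self._n_cycles(cohort)
        ages = cohort.start_age + np.arange(T + 1) * p.cycle_days / DAYS_PER_YEAR
        occ = np.zeros((T + 1, N_STATES))
        occ[0, cohort.entry_state_for(arm)] = 1.0
        cache: dict[tuple, np.ndarray] = {}
        cohort_key = cohort.param_cohort.value
        for t in range(T):
            age = ages[t]
            extrapolated = (
                tp.extrapolate
                and cohort_key == "cohort1"
                and arm == Arm.ECULIZUMAB
                and t * p.cycle_days >= tp.extrapolate_after_weeks * 7.0
            )
            if age >= p.max_age:
                key = ("cap", extrapolated)
                q_bg = 1.0
            else:
                key = (int(math.floor(age)), extrapolated)
                q_bg = None
            M = cache.get(key)
            if M is None:
                if q_bg is None:
                    q_bg = annual_prob_to_cycle_prob(
                        self.life_table.annual_q(age), p.cycle_days
                    )
                M = matrix_for_conditions(cohort_key, arm, extrapolated, q_bg, p)
                cache[key] = M
            occ[t + 1] = occ[t] @ M
        return Trace(occupancy=occ, ages=ages, cohort=cohort, arm=arm)

    # -- accrual ----------------------------------------------------------

    def accumulate(self, trace: Trace) -> ArmResult:
        p = self.params
        cohort, arm = trace.cohort, trace.arm
        T = trace.n_cycles
        cyc_years = p.cycle_days / DAYS_PER_YEAR
        t_years = np.arange(T) * cyc_years
        dfc = (1.0 + p.discount_cost) ** (-t_years)
        dfq = (1.0 + p.discount_qaly) ** (-t_years)

        X = trace.occupancy
        O = 0.5 * (X[:-1] + X[1:]) if p.half_cycle_correction else X[:-1]
        I = X[1:]  # inflow into event states equals next-cycle occupancy

        # ---- per-cycle drug/administration schedule (vial counts cached;
        # the schedule itself is price-independent) ----
        vials_normal, vials_updosed, n_admin = _dose_schedule_arrays(
            arm, cohort, T, p, self.weight_table, trace.ages)
        vial_price = p.costs.vial_rav if arm == Arm.RAVULIZUMAB else p.costs.vial_ecu
        drug_normal = vials_normal * vial_price
        drug_updosed = vials_updosed * vial_price

        admin_tariff = p.costs.admin_cost(arm)
        if arm == Arm.RAVULIZUMAB:
            admin_tariff *= 1.0 - p.costs.homecare_fraction_rav

        on_treat = np.array([s in ON_TREATMENT_STATES for s in HealthState])
        updosed = np.array([s in UPDOSED_STATES for s in HealthState])
        occ_treat = O[:, on_treat & ~updosed].sum(axis=1)
        occ_updosed = O[:, updosed].sum(axis=1)
        occ_on = occ_treat + occ_updosed

        drug_admin_cycle = (
            occ_treat * drug_normal + occ_updosed * drug_updosed
            + occ_on * n_admin * admin_tariff
        )

        # earlier-than-scheduled dose per incomplete-C5 event inflow
        xd_drug, xd_admin, xd_travel, xd_prod = extra_dose_cost_on_incc5(
            arm, p.costs, p.dosing)
        incc5_inflow = I[:, list(_INCC5_EVENT)].sum(axis=1)
        drug_admin_cycle = drug_admin_cycle + incc5_inflow * (xd_drug + xd_admin)

        # ---- medical: transfusions (occupancy) + events (inflow) ----
        transf_state = np.zeros(N_STATES)
        event_medical = np.zeros(N_STATES)
        for s in HealthState:
            med, transf = event_and_transfusion_cost_per_cycle(
                s, arm, cohort, p.costs, p.transfusions)
            transf_state[s] = transf
            event_medical[s] = med
        medical_cycle = O @ transf_state + I @ event_medical

        # ---- societal ----
        if p.include_societal:
            tr_adm, pr_adm = infusion_societal_per_admin(arm, p.costs)
            transf_soc = np.zeros(N_STATES)
            for s in HealthState:
                tr_t, pr_t = transfusion_societal_per_cycle(
                    s, arm, cohort, p.costs, p.transfusions)
                transf_soc[s] = tr_t + pr_t
            event_soc = np.zeros(N_STATES)
            tr_i, pr_i = event_societal_cost("incc5", p.costs)
            tr_c, pr_c = event_societal_cost("cac", p.costs)
            for s in _INCC5_EVENT:
                event_soc[s] = tr_i + pr_i
            for s in _CAC_EVENT:
                event_soc[s] = tr_c + pr_c
            societal_cycle = (
                occ_on * n_admin * (tr_adm + pr_adm)
                + O @ transf_soc
                + I @ event_soc
                + incc5_inflow * (xd_travel + xd_prod)
            )
        else:
            societal_cycle = np.zeros(T)

        # ---- QALYs and life-years ----
        uvec_cache: dict[float, np.ndarray] = {}
        qaly_cycle = np.zeros(T)
        for t in range(T):
            age = trace.ages[t]
            band_key = int(math.floor(age))
            u = uvec_cache.get(band_key)
            if u is None:
                u = utility_vector(arm, cohort, age, p.utilities)
                uvec_cache[band_key] = u
            qaly_cycle[t] = O[t] @ u * cyc_years
        living = np.array([s in LIVING_STATES for s in HealthState])
        ly_cycle = O[:, living].sum(axis=1) * cyc_years

        vacc = vaccination_cost(cohort, p.costs)
        medical_disc = float(medical_cycle @ dfc) + vacc
        medical_und = float(medical_cycle.sum()) + vacc

        und = {
            "drug_admin": float(drug_admin_cycle.sum()),
            "medical": medical_und,
            "societal": float(societal_cycle.sum()),
            "qalys": float(qaly_cycle.sum()),
            "life_years": float(ly_cycle.sum()),
        }
        return ArmResult(
            drug_admin=float(drug_admin_cycle @ dfc),
            medical=medical_disc,
            societal=float(societal_cycle @ dfc),
            qalys=float(qaly_cycle @ dfq),
            life_years=float(ly_cycle @ dfq),
            undiscounted=und,
        )

    # -- runs -------------------------------------------------------------

    def run_arm(self, cohort: Cohort, arm: Arm) -> ArmResult:
        return self.accumulate(self.run_trace(cohort, arm))

    def run_cohort(self, cohort: Cohort) -> CEAResult:
        arms = {
            arm.value: self.run_arm(cohort, arm)
            for arm in (Arm.ECULIZUMAB, Arm.RAVULIZUMAB)
        }
        return CEAResult(label=cohort.id.value, arms=arms)

    def run(self) -> CEAResults:
        by_cohort = {c.id.value: self.run_cohort(c) for c in self.params.cohorts}
        weights = self.params.normalized_weights()
        agg = aggregate(by_cohort, weights)
        return CEAResults(by_cohort, agg, self.params)

    # -- sensitivity / scenarios (delegation) -----------------------------

    def run_psa(self, config=None, progress: bool = False):
        from .uncertainty import run_psa

        return run_psa(self.params, config, self.life_table, self.weight_table,
                       progress=progress)

    def run_owsa(self, config=None, parameters=None):
        from .uncertainty import run_owsa

        return run_owsa(self.params, config, self.life_table, self.weight_table,
                        parameters=parameters)

    def run_scenario(self, name: str, **kwargs) -> CEAResults:
        from .scenarios import run_scenario

        return run_scenario(name, self.params, self.life_table,
                            self.weight_table, **kwargs)
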