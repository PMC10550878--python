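"""Parameter uncertainty: distributions, probabilistic and one-way
sensitivity analyses.

Families follow the usual health-economics domain rule: probabilities
and utility-scale quantities draw from Beta, non-negative costs and
counts from Gamma, decrements (support crossing zero) from Normal.
Shape parameters come from the method of moments on (mean, SE); where
no SE is published the default rule SE = 25% of the mean applies.
Parameters are sampled independently; draws that violate a hard
invariant are re-sampled rather than truncated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .params import ParameterSet, UncertaintyConfig
from .states import Arm

ARMS = (Arm.ECULIZUMAB.value, Arm.RAVULIZUMAB.value)
COHORT_KEYS = ("cohort1", "cohort2")


# --------------------------------------------------------------------------
# dotted-path access on a ParameterSet
# --------------------------------------------------------------------------

def get_param(p, path: str):
    obj = p
    for part in path.split("."):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            obj = getattr(obj, part)
        elif isinstance(obj, dict):
            obj = obj[part]
        elif isinstance(obj, (list, tuple)):
            obj = obj[int(part)]
        else:
            raise KeyError(path)
    return obj


def set_param(p, path: str, value) -> None:
    parts = path.split(".")
    obj = p
    for part in parts[:-1]:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            obj = getattr(obj, part)
        elif isinstance(obj, dict):
            obj = obj[part]
        elif isinstance(obj, (list, tuple)):
            obj = obj[int(part)]
        else:
            raise KeyError(path)
    last = parts[-1]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        setattr(obj, last, value)
    elif isinstance(obj, dict):
        obj[last] = value
    elif isinstance(obj, list):
        obj[int(last)] = value
    else:
        raise KeyError(path)


# --------------------------------------------------------------------------
# distributions
# --------------------------------------------------------------------------

@dataclass
class ParameterDistribution:
    """One sampled parameter: its dotted path, family and moments."""

    path: str
    family: str  # normal | beta | gamma
    mean: float
    se: float
    #: hard invariant for re-sampling: (lo, hi) closed bounds or None
    bounds: tuple | None = None
    #: drug-price rows are flagged: the published tornado omits them for
    #: presentation while reporting their values in the text
    drug_price: bool = False

    def __post_init__(self):
        if self.family == "beta":
            var_max = self.mean * (1.0 - self.mean)
            if self.se**2 >= var_max > 0:
                # method of moments needs se^2 < m(1-m); shrink to the
                # largest admissible SE
                self.se = 0.999 * var_max**0.5

    @property
    def fixed(self) -> bool:
        return self.se == 0.0 or (self.family == "beta" and self.mean in (0.0, 1.0)) \
            or (self.family == "gamma" and self.mean == 0.0)

    def _frozen(self):
        m, s = self.mean, self.se
        if self.family == "beta":
            nu = m * (1.0 - m) / s**2 - 1.0
            return stats.beta(m * nu, (1.0 - m) * nu)
        if self.family == "gamma":
            return stats.gamma((m / s) ** 2, scale=s**2 / m)
        return stats.norm(m, s)

    def percentile(self, q: float) -> float:
        if self.fixed:
            return self.mean
        x = float(self._frozen().ppf(q))
        # extreme method-of-moments shapes (vanishing SE) can defeat the
        # quantile routine; the distribution is then a point mass
        return x if np.isfinite(x) else self.mean

    def sample(self, rng: np.random.Generator) -> float:
        if self.fixed:
            return self.mean
        dist = self._frozen()
        for _ in range(100):
            x = float(dist.ppf(rng.uniform()))
            if not np.isfinite(x):
                return self.mean  # point-mass limit, see percentile()
            if self.bounds is None:
                return x
            lo, hi = self.bounds
            if (lo is None or x >= lo) and (hi is None or x <= hi):
                return x
        return self.mean  # pathological distribution: fall back to the mean


_TRANSITION_PROB_FIELDS = (
    "p_no_bth_to_incc5", "p_no_bth_to_cac", "p_second_incc5_after_first",
    "p_incc5_to_cac", "p_hx_no_bth_to_incc5", "p_updose_cac",
)

_COST_GAMMA_FIELDS = (
    "vial_ecu", "vial_rav", "admin_ecu", "admin_rav", "ward_day", "icu_day",
    "dialysis_2wk", "hematologist_visit", "incc5_event_medical",
    "cac_event_medical", "transfusion_admin", "prbc_unit",
    "meningococcal_total", "travel_per_km", "parking",
    "productivity_ecu_admin", "productivity_rav_admin", "productivity_ward",
    "productivity_icu", "productivity_dialysis", "productivity_hematologist",
    "productivity_transfusion",
)


def build_distributions(
    p: ParameterSet, u: UncertaintyConfig | None = None
) -> list[ParameterDistribution]:
    """Assign a distribution to every varied parameter.

    Structural zeros (e.g. incomplete-C5 probabilities under ravulizumab)
    and published zero SEs stay fixed. Baseline age is not varied: no SE
    is published and the default SE rule would produce non-adult ages.
    """
    u = u or UncertaintyConfig()
    f = u.default_se_fraction
    dists: list[ParameterDistribution] = []

    for name in _TRANSITION_PROB_FIELDS:
        table = getattr(p.transitions, name)
        for ck in COHORT_KEYS:
            for a in ARMS:
                m = table[ck][a]
                dists.append(ParameterDistribution(
                    path=f"transitions.{name}.{ck}.{a}", family="beta",
                    mean=m, se=f * m))
    dists.append(ParameterDistribution(
        path="transitions.remission_per_cycle", family="beta",
        mean=p.transitions.remission_per_cycle,
        se=f * p.transitions.remission_per_cycle))
    dists.append(ParameterDistribution(
        path="transitions.excess_mortality_hr", family="gamma",
        mean=p.transitions.excess_mortality_hr,
        se=f * p.transitions.excess_mortality_hr, bounds=(0.0, None)))

    for cls in ("no_bth", "bth"):
        for ck in COHORT_KEYS:
            for a in ARMS:
                m = p.transfusions.prob[cls][ck][a]
                se = p.transfusions.prob_se[cls][ck][a]
                dists.append(ParameterDistribution(
                    path=f"transfusions.prob.{cls}.{ck}.{a}",
                    family="beta", mean=m, se=se))
                m = p.transfusions.units[cls][ck][a]
                se = p.transfusions.units_se[cls][ck][a]
                dists.append(ParameterDistribution(
                    path=f"transfusions.units.{cls}.{ck}.{a}",
                    family="gamma", mean=m, se=se, bounds=(0.0, None)))

    for ck, by_arm in p.utilities.decrements.items():
        for a, by_state in by_arm.items():
            for sk, m in by_state.items():
                dists.append(ParameterDistribution(
                    path=f"utilities.decrements.{ck}.{a}.{sk}",
                    family="normal", mean=m, se=f * abs(m),
                    bounds=(None, 0.0)))
    for i, (_lo, _hi, val) in enumerate(p.utilities.age_reference):
        dists.append(ParameterDistribution(
            path=f"utilities.age_reference.{i}.2", family="beta",
            mean=val, se=f * val))

    for name in _COST_GAMMA_FIELDS:
        m = getattr(p.costs, name)
        dists.append(ParameterDistribution(
            path=f"costs.{name}", family="gamma", mean=m, se=f * m,
            bounds=(0.0, None), drug_price=name in ("vial_ecu", "vial_rav")))
    return dists


def distribution_manifest(dists: list[ParameterDistribution]) -> pd.DataFrame:
    return pd.DataFrame([
        {"path": d.path, "family": d.family, "mean": d.mean, "se": d.se,
         "fixed": d.fixed, "drug_price": d.drug_price}
        for d in dists
    ])


def sample_parameters(
    dists: list[ParameterDistribution],
    base: ParameterSet,
    rng: np.random.Generator,
) -> ParameterSet:
    """One independent joint draw of all varied parameters."""
    draw = base.copy()
    for d in dists:
        set_param(draw, d.path, d.sample(rng))
    return draw


# --------------------------------------------------------------------------
# PSA
# --------------------------------------------------------------------------

@dataclass
class PSAResult:
    """Per-draw incremental costs/QALYs for the aggregate population,
    summary statistics and the cost-effectiveness acceptability curve."""

    draws: pd.DataFrame  # columns draw, delta_cost, delta_qalys
    ceac: pd.DataFrame  # columns wtp, probability
    summary: dict
    per_cohort: dict = field(default_factory=dict)

    def prob_cost_effective(self, wtp: float) -> float:
        nmb = wtp * self.draws["delta_qalys"] - self.draws["delta_cost"]
        return float((nmb > 0).mean())


def _ceac(draws: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    rows = []
    dq = draws["delta_qalys"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    for w in wtp_grid:
        rows.append({"wtp": w, "probability": float((w * dq - dc > 0).mean())})
    return pd.DataFrame(rows)


def run_psa(
    p: ParameterSet,
    config: UncertaintyConfig | None,
    life_table,
    weight_table,
    per_cohort: bool = False,
    progress: bool = False,
) -> PSAResult:
    """Monte-Carlo evaluation of the full aggregate model under joint
    parameter uncertainty; seed-reproducible."""
    from .engine import CostEffectivenessModel

    cfg = config or UncertaintyConfig()
    dists = build_distributions(p, cfg)
    if not cfg.psa_include_drug_prices:
        dists = [d for d in dists if not d.drug_price]
    rng = np.random.default_rng(cfg.seed)
    rows = []
    cohort_rows: dict[str, list] = {c.id.value: [] for c in p.cohorts}
    for i in range(cfg.n_draws):
        draw = sample_parameters(dists, p, rng)
        model = CostEffectivenessModel(draw, life_table, weight_table)
        res = model.run()
        rows.append({
            "draw": i,
            "delta_cost": res.aggregate.delta_cost,
            "delta_qalys": res.aggregate.delta_qalys,
        })
        if per_cohort:
            for ck, r in res.by_cohort.items():
                cohort_rows[ck].append({
                    "draw": i, "delta_cost": r.delta_cost,
                    "delta_qalys": r.delta_qalys,
                })
        if progress and (i + 1) % 100 == 0:
            print(f"  PSA draw {i + 1}/{cfg.n_draws}")
    draws = pd.DataFrame(rows)
    lo, hi = 2.5, 97.5
    summary = {
        "n_draws": cfg.n_draws,
        "mean_delta_cost": float(draws["delta_cost"].mean()),
        "ci_delta_cost": [float(np.percentile(draws["delta_cost"], lo)),
                          float(np.percentile(draws["delta_cost"], hi))],
        "mean_delta_qalys": float(draws["delta_qalys"].mean()),
        "ci_delta_qalys": [float(np.percentile(draws["delta_qalys"], lo)),
                           float(np.percentile(draws["delta_qalys"], hi))],
    }
    ceac = _ceac(draws, cfg.wtp_grid)
    result = PSAResult(draws=draws, ceac=ceac, summary=summary)
    if per_cohort:
        result.per_cohort = {
            ck: pd.DataFrame(v) for ck, v in cohort_rows.items() if v
        }
    summary["prob_cost_effective_at_wtp"] = result.prob_cost_effective(p.wtp)
    return result


# --------------------------------------------------------------------------
# OWSA (tornado)
# --------------------------------------------------------------------------

def run_owsa(
    p: ParameterSet,
    config: UncertaintyConfig | None,
    life_table,
    weight_table,
    parameters: list[str] | None = None,
) -> pd.DataFrame:
    """One parameter at a time at its 2.5th/97.5th percentile, all else
    at base; rows sorted by incremental-cost range, descending."""
    from .engine import CostEffectivenessModel

    cfg = config or UncertaintyConfig()
    dists = build_distributions(p, cfg)
    if parameters is not None:
        wanted = set(parameters)
        dists = [d for d in dists if d.path in wanted]
    base_model = CostEffectivenessModel(p, life_table, weight_table)
    base = base_model.run().aggregate
    lo_q, hi_q = cfg.owsa_bounds
    rows = []
    for d in dists:
        if d.fixed:
            rows.append({
                "parameter": d.path, "low_value": d.mean, "high_value": d.mean,
                "delta_cost_low": base.delta_cost, "delta_cost_high": base.delta_cost,
                "delta_qalys_low": base.delta_qalys, "delta_qalys_high": base.delta_qalys,
                "cost_range": 0.0, "qaly_range": 0.0, "drug_price": d.drug_price,
            })
            continue
        out = {}
        for tag, q in (("low", lo_q), ("high", hi_q)):
            trial = p.copy()
            set_param(trial, d.path, d.percentile(q))
            res = CostEffectivenessModel(trial, life_table, weight_table).run()
            out[tag] = res.aggregate
        rows.append({
            "parameter": d.path,
            "low_value": d.percentile(lo_q), "high_value": d.percentile(hi_q),
            "delta_cost_low": out["low"].delta_cost,
            "delta_cost_high": out["high"].delta_cost,
            "delta_qalys_low": out["low"].delta_qalys,
            "delta_qalys_high": out["high"].delta_qalys,
            "cost_range": abs(out["high"].delta_cost - out["low"].delta_cost),
            "qaly_range": abs(out["high"].delta_qalys - out["low"].delta_qalys),
            "drug_price": d.drug_price,
        })
    df = pd.DataFrame(rows).sort_values("cost_range", ascending=False)
    return df.reset_index(drop=True)
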