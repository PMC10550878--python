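"""Synthetic stand-ins for the model inputs that are cited but not
published: an adult background life table, a weight-by-age table, and
trial-like visit panels for exercising the transition estimator.

The default life table is a Gompertz-Makeham hazard calibrated once so
that remaining life expectancy at age 46 is about 37 years — the right
magnitude for a Western-European general population, which the absolute
lifetime cost/QALY totals depend on. The default weight distribution is
a flat 77 +/- 13 kg across adult ages, placing most mass in the middle
ravulizumab dosing band. These fixtures emulate the shape of the real
tables, not their exact values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .costs import WeightTable
from .transitions import LifeTable


@dataclass
class LifeTableSpec:
    """Gompertz-Makeham annual hazard A + B*exp(c*age) over an age span;
    the annual death probability is 1 - exp(-hazard), forced to 1 at the
    model's maximum age."""

    makeham: float = 2.0e-4
    baseline: float = 2.25e-5
    slope: float = 0.095
    age_min: int = 18
    age_max: int = 101


@dataclass
class WeightTableSpec:
    mean_kg: float = 77.0
    sd_kg: float = 13.0
    age_min: int = 18
    age_max: int = 101


@dataclass
class PanelSpec:
    """Trial-like visit panel: per-visit multinomial event draws with
    treatment-dependent probabilities; the history flag is set after the
    first incomplete-C5 event."""

    n_patients: int = 5000
    n_visits: int = 26
    p_incc5: dict = field(default_factory=lambda: {"eculizumab": 0.003, "ravulizumab": 0.0})
    p_cac: dict = field(default_factory=lambda: {"eculizumab": 0.005, "ravulizumab": 0.0026})
    treatment_fraction_rav: float = 0.5
    seed: int = 12345


def generate_life_table(spec: LifeTableSpec | None = None, out_path=None) -> LifeTable:
    spec = spec or LifeTableSpec()
    ages = np.arange(spec.age_min, spec.age_max + 1)
    hazard = spec.makeham + spec.baseline * np.exp(spec.slope * ages)
    q = 1.0 - np.exp(-hazard)
    q = np.clip(q, 0.0, 1.0)
    q[-1] = 1.0  # model cap: nobody outlives the maximum age
    lt = LifeTable(ages=ages, qx=q)
    if out_path is not None:
        lt.to_csv(out_path)
    return lt


def generate_weight_table(spec: WeightTableSpec | None = None, out_path=None) -> WeightTable:
    spec = spec or WeightTableSpec()
    ages = np.arange(spec.age_min, spec.age_max + 1)
    wt = WeightTable(
        ages=ages,
        mean_kg=np.full(len(ages), spec.mean_kg),
        sd_kg=np.full(len(ages), spec.sd_kg),
    )
    if out_path is not None:
        wt.to_csv(out_path)
    return wt


def generate_visit_panel(spec: PanelSpec | None = None) -> pd.DataFrame:
    """Simulate a visit-level panel (columns patient_id, visit_index,
    state_at_visit, history_flag, treatment); seeded and reproducible."""
    spec = spec or PanelSpec()
    rng = np.random.default_rng(spec.seed)
    n, v = spec.n_patients, spec.n_visits
    n_rav = int(round(n * spec.treatment_fraction_rav))
    is_rav = np.arange(n) < n_rav
    p1 = np.where(is_rav, spec.p_incc5["ravulizumab"], spec.p_incc5["eculizumab"])
    p2 = np.where(is_rav, spec.p_cac["ravulizumab"], spec.p_cac["eculizumab"])
    u = rng.uniform(size=(n, v))
    # outcome drawn at each visit decides the state recorded at the next;
    # visit 0 always starts event-free
    states = np.zeros((n, v), dtype=np.int8)  # 0 no_bth, 1 incc5, 2 cac
    history = np.zeros((n, v), dtype=bool)
    for t in range(1, v):
        draw = u[:, t - 1]
        states[:, t] = np.where(draw < p1, 1, np.where(draw < p1 + p2, 2, 0))
        history[:, t] = history[:, t - 1] | (states[:, t - 1] == 1)
    state_names = np.array(["no_bth", "incc5_bth", "cac_bth"])
    arm_names = np.where(is_rav, "ravulizumab", "eculizumab")
    return pd.DataFrame({
        "patient_id": np.repeat(np.arange(n), v),
        "visit_index": np.tile(np.arange(v), n),
        "state_at_visit": state_names[states.ravel()],
        "history_flag": history.ravel(),
        "treatment": np.repeat(arm_names, v),
    })


DEFAULT_CONFIG_TEXT = """\
# pnhcea run configuration: defaults are the published base case; any
# parameter can be overridden by its dotted path, e.g.
# discount_cost: 0.06
# costs.vial_ecu: 4000
"""


def generate_fixture_bundle(seed: int = 0, out_dir="fixtures") -> dict:
    """Write the life table, weight table and a default config so the
    pipeline runs end to end with no external data; returns a manifest.
    The tables are deterministic; the seed is recorded for the panel
    generators that downstream tooling may invoke."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    lt_path = out / "life_table.csv"
    generate_life_table(out_path=lt_path)
    files["life_table"] = str(lt_path)
    wt_path = out / "weight_table.csv"
    generate_weight_table(out_path=wt_path)
    files["weight_table"] = str(wt_path)
    cfg_path = out / "config.yaml"
    cfg_path.write_text(DEFAULT_CONFIG_TEXT)
    files["config"] = str(cfg_path)
    manifest = {"seed": seed, "files": files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def default_tables() -> tuple[LifeTable, WeightTable]:
    """The in-memory fixture tables (no files written)."""
    return generate_life_table(), generate_weight_table()
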