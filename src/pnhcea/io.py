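"""Configuration files and tabular output writers.

The configuration format is a flat YAML mapping whose keys are dotted
parameter paths mirroring the field structure, e.g.::

    discount_cost: 0.06
    costs.vial_ecu: 4000
    transitions.p_no_bth_to_incc5.cohort1.eculizumab: 0.004
    cohorts.cohort1.mix_weight: 0.10
    uncertainty.n_draws: 500

Every default is overridable; unknown keys are rejected with the
offending key named, and out-of-range values are rejected with the
violated constraint named.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .params import (
    ParameterSet,
    UncertaintyConfig,
    _walk_scalars,
    default_parameters,
    validate_parameters,
)
from .uncertainty import get_param, set_param


class ConfigError(ValueError):
    pass


def _flatten(mapping: dict, prefix: str = "") -> dict:
    """Allow nested YAML mappings as well as dotted keys."""
    out = {}
    for k, v in mapping.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


def load_config(path) -> tuple[ParameterSet, UncertaintyConfig]:
    """Defaults overridden by the user's configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a YAML mapping")
    flat = _flatten(raw)
    p = default_parameters()
    u = UncertaintyConfig()
    cohorts_by_id = {c.id.value: c for c in p.cohorts}
    for key, value in flat.items():
        if key.startswith("uncertainty."):
            attr = key.split(".", 1)[1]
            if not hasattr(u, attr):
                raise ConfigError(f"unknown configuration key: {key}")
            setattr(u, attr, type(getattr(u, attr))(value)
                    if not isinstance(getattr(u, attr), (list, tuple)) else value)
            continue
        if key.startswith("cohorts."):
            parts = key.split(".")
            if len(parts) != 3 or parts[1] not in cohorts_by_id:
                raise ConfigError(f"unknown configuration key: {key}")
            cid, attr = parts[1], parts[2]
            cohort = cohorts_by_id[cid]
            if not hasattr(cohort, attr):
                raise ConfigError(f"unknown configuration key: {key}")
            cohorts_by_id[cid] = dataclasses.replace(cohort, **{attr: value})
            continue
        try:
            current = get_param(p, key)
        except (KeyError, AttributeError, IndexError, TypeError):
            raise ConfigError(f"unknown configuration key: {key}") from None
        if isinstance(current, bool) and not isinstance(value, bool):
            raise ConfigError(f"{key}: expected a boolean, got {value!r}")
        if isinstance(current, (int, float)) and not isinstance(value, (int, float)):
            raise ConfigError(f"{key}: expected a number, got {value!r}")
        set_param(p, key, value)
    p.cohorts = list(cohorts_by_id.values())
    violations = validate_parameters(p)
    if violations:
        raise ConfigError("configuration violates constraints:\n"
                          + "\n".join(violations))
    return p, u


def save_config(p: ParameterSet, path, u: UncertaintyConfig | None = None) -> None:
    """Write a full flat configuration; loading it back reproduces every
    numeric value exactly."""
    flat: dict[str, object] = {}
    for dotted, value in _walk_scalars(p, ""):
        if dotted.startswith("cohorts."):
            continue
        if isinstance(value, (bool, int, float, str)) and value is not None:
            flat[dotted] = value
    for c in p.cohorts:
        flat[f"cohorts.{c.id.value}.start_age"] = c.start_age
        flat[f"cohorts.{c.id.value}.mix_weight"] = c.mix_weight
    if u is not None:
        flat["uncertainty.n_draws"] = u.n_draws
        flat["uncertainty.seed"] = u.seed
        flat["uncertainty.default_se_fraction"] = u.default_se_fraction
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=True))


# --------------------------------------------------------------------------
# result writers
# --------------------------------------------------------------------------

def write_results(result, out_dir) -> list[str]:
    """Write a results object as CSV/JSON files with deterministic column
    order; returns the manifest of files written."""
    from .engine import CEAResults
    from .uncertainty import PSAResult

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(str(path))

    def _write_json(obj, name: str) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=2, default=float) + "\n")
        written.append(str(path))

    if isinstance(result, CEAResults):
        _write_csv(result.to_frame(), "base_case.csv")
        agg = result.aggregate
        icer = agg.icer
        _write_json({
            "delta_cost": agg.delta_cost,
            "delta_qalys": agg.delta_qalys,
            "icer": icer if isinstance(icer, (int, float)) else None,
            "outcome": icer if isinstance(icer, str) else "icer",
        }, "base_case.json")
    elif isinstance(result, PSAResult):
        _write_csv(result.draws, "draws.csv")
        _write_csv(result.ceac, "ceac.csv")
        _write_json(result.summary, "summary.json")
    elif isinstance(result, pd.DataFrame):
        # tornado table (already sorted by impact range, descending)
        _write_csv(result, "owsa.csv")
    else:
        raise TypeError(f"cannot write results of type {type(result).__name__}")
    manifest = {"files": list(written)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return written
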