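"""Run configuration: schema-validated YAML/JSON loading with defaults."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from ..kinetics import Params

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Schema violation; message lists every offending field."""


_SIMULATE_KEYS = {"nx": int, "ny": int, "t_end": float, "dt": float,
                  "snapshot_times": list, "ic_spec": str,
                  "background": float, "square_value": float,
                  "noise_amp": float, "v_init": float, "diag_every": int}
_INVERT_KEYS = {"tol": float, "max_iter": int, "restart": int,
                "floor": float, "smooth_sigma": float, "frame_dt": float}
_ODE4_KEYS = {"b_min": float, "b_max": float, "steps": int,
              "scan_max": float, "n_grid": int}
_PHASES_KEYS = {"pos": list, "on": str}


@dataclass
class RunConfig:
    """Validated configuration for every CLI subcommand."""

    params: Params = field(default_factory=Params)
    simulate: dict = field(default_factory=dict)
    invert: dict = field(default_factory=dict)
    ode4: dict = field(default_factory=dict)
    phases: dict = field(default_factory=dict)
    seed: int = 0
    verbosity: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        return d


def _check_block(name: str, block: dict, schema: dict, errors: list) -> dict:
    if not isinstance(block, dict):
        errors.append(f"{name}: expected a mapping, got {type(block).__name__}")
        return {}
    out = {}
    for key, val in block.items():
        if key not in schema:
            errors.append(f"{name}.{key}: unknown key")
            continue
        want = schema[key]
        try:
            out[key] = val if want is list else want(val)
        except (TypeError, ValueError):
            errors.append(f"{name}.{key}: cannot coerce {val!r} to {want.__name__}")
    return out


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON config; unknown keys are rejected.

    An empty file yields the full defaults (the standard parameter set
    with gamma = 0.25).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text) if text.strip() else {}
    else:
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")

    errors: list[str] = []
    known = {"params", "simulate", "invert", "ode4", "phases", "seed", "verbosity"}
    for key in raw:
        if key not in known:
            errors.append(f"{key}: unknown top-level key")

    params = Params()
    if "params" in raw:
        try:
            merged = {**params.to_dict(), **(raw["params"] or {})}
            params = Params.from_dict(merged)
        except (ValueError, TypeError) as exc:
            errors.append(f"params: {exc}")

    blocks = {}
    for name, schema in (("simulate", _SIMULATE_KEYS), ("invert", _INVERT_KEYS),
                         ("ode4", _ODE4_KEYS), ("phases", _PHASES_KEYS)):
        blocks[name] = _check_block(name, raw.get(name, {}) or {}, schema, errors)

    seed = raw.get("seed", 0)
    verbosity = raw.get("verbosity", 0)
    if not isinstance(seed, int):
        errors.append(f"seed: expected int, got {seed!r}")
    if not isinstance(verbosity, int):
        errors.append(f"verbosity: expected int, got {verbosity!r}")

    if errors:
        raise ConfigError("invalid config:\n  " + "\n  ".join(errors))
    return RunConfig(params=params, seed=seed, verbosity=verbosity, **blocks)


def load_params(path) -> Params:
    """Load a bare Params mapping (exactly the keys a,b,c,e,du,dv,gamma,h)."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must contain a mapping of parameter names")
    return Params.from_dict(raw)


def save_params(params: Params, path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def write_equilibria_csv(equilibria, path) -> None:
    """Equilibrium report: one row (u, v, eig1, eig2, label) per state."""
    import csv

    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["u", "v", "eig1", "eig2", "label"])
        for eq in equilibria:
            w.writerow([eq.u, eq.v, *eq.eigenvalues, eq.label])


def save_config(cfg: RunConfig, path) -> None:
    """Write a RunConfig back out; round-trips through load_config."""
    path = Path(path)
    d = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
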