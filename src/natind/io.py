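"""Configuration files, run summaries, and CSV traces.

Config files are JSON with sections ``{scenario, network, protocol,
dynamics, output, seed}``.  Every key has a documented default; unknown keys
are rejected by name so typos cannot silently fall back to defaults.  The
fully-resolved configuration is echoed into every run summary
(schema-versioned "natind/1").
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import SimulationConfig
from .protocols import MemoryResult, RunResult

__all__ = ["load_config", "save_config", "run_summary", "write_trace", "LoadedConfig"]

SCHEMA = "natind/1"

_DYNAMICS_KEYS = {
    "damping": float,
    "step_size": float,
    "equilibrium_tolerance": float,
    "max_displacement": float,
    "max_settle_steps": int,
}
_PROTOCOL_KEYS = {
    "n_resets": int,
    "learning_rate": float,
    "box_size": float,
    "n_samples": int,
}
_SECTIONS = {"scenario", "network", "protocol", "dynamics", "output", "seed"}
_SCENARIOS = {"memory", "s1", "s2a", "s2b"}


@dataclasses.dataclass
class LoadedConfig:
    config: SimulationConfig
    scenario: str | None
    network: dict
    output: dict
    n_samples: int | None = None  # memory-experiment sample count

    def to_dict(self) -> dict:
        sim = dataclasses.asdict(self.config)
        protocol = {
            "n_resets": sim.pop("n_resets"),
            "learning_rate": sim.pop("learning_rate"),
            "box_size": sim.pop("box_size"),
        }
        if self.n_samples is not None:
            protocol["n_samples"] = self.n_samples
        seed = sim.pop("seed")
        out: dict = {
            "dynamics": {k: v for k, v in sim.items() if v is not None},
            "protocol": {k: v for k, v in protocol.items() if v is not None},
        }
        if self.scenario is not None:
            out["scenario"] = self.scenario
        if self.network:
            out["network"] = self.network
        if self.output:
            out["output"] = self.output
        if seed is not None:
            out["seed"] = seed
        return out


def _coerce(section: str, key: str, value, typ):
    if value is None:
        return None
    try:
        return typ(value)
    except (TypeError, ValueError):
        raise ConfigError(
            f"config key {section}.{key} has invalid value {value!r} "
            f"(expected {typ.__name__})"
        ) from None


def parse_config(doc: dict) -> LoadedConfig:
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a JSON object")
    unknown = set(doc) - _SECTIONS
    if unknown:
        raise ConfigError(f"unknown config section(s): {', '.join(sorted(unknown))}")

    kwargs: dict = {}
    dyn = doc.get("dynamics", {})
    for key in set(dyn) - set(_DYNAMICS_KEYS):
        raise ConfigError(f"unknown config key dynamics.{key}")
    for key, typ in _DYNAMICS_KEYS.items():
        if key in dyn:
            kwargs[key] = _coerce("dynamics", key, dyn[key], typ)

    n_samples = None
    proto = doc.get("protocol", {})
    for key in set(proto) - set(_PROTOCOL_KEYS):
        raise ConfigError(f"unknown config key protocol.{key}")
    for key, typ in _PROTOCOL_KEYS.items():
        if key in proto:
            val = _coerce("protocol", key, proto[key], typ)
            if key == "n_samples":
                n_samples = val
            else:
                kwargs[key] = val

    seed = doc.get("seed")
    if seed is not None:
        kwargs["seed"] = _coerce("", "seed", seed, int)

    scenario = doc.get("scenario")
    if scenario is not None and scenario not in _SCENARIOS:
        raise ConfigError(
            f"unknown scenario {scenario!r}; expected one of {sorted(_SCENARIOS)}"
        )
    network = doc.get("network", {})
    if not isinstance(network, dict):
        raise ConfigError("config section 'network' must be an object")
    output = doc.get("output", {})
    if not isinstance(output, dict):
        raise ConfigError("config section 'output' must be an object")

    try:
        config = SimulationConfig(**kwargs)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
    return LoadedConfig(
        config=config,
        scenario=scenario,
        network=dict(network),
        output=dict(output),
        n_samples=n_samples,
    )


def load_config(path) -> LoadedConfig:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: not valid JSON ({exc})") from exc
    return parse_config(doc)


def save_config(loaded: LoadedConfig, path) -> None:
    Path(path).write_text(
        json.dumps(loaded.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    return value


def run_summary(result: RunResult | MemoryResult, assay_scores: dict | None = None) -> dict:
    """Schema-versioned JSON document describing a completed run."""
    doc: dict = {"schema": SCHEMA}
    if isinstance(result, MemoryResult):
        doc.update(
            scenario="memory",
            n_samples=len(result.baseline_records),
            convergence_fraction=result.convergence_fraction,
            creep_iters=result.creep_iters,
            held_energy=result.held_record.energy_current,
        )
    else:
        e_cur = result.energies_current
        doc.update(
            scenario=result.scenario,
            seed=result.seed,
            config=dataclasses.asdict(result.config),
            n_resets=len(result.records),
            energy_current_final=float(e_cur[-1]) if e_cur.size else None,
        )
        e_orig = result.energies_original
        if e_orig.size and not np.all(np.isnan(e_orig)):
            doc["min_energy_original"] = float(np.nanmin(e_orig))
        if result.baseline_energies is not None:
            doc["baseline_min"] = float(result.baseline_energies.min())
            doc["baseline_mean"] = float(result.baseline_energies.mean())
        if result.final_record is not None:
            doc["final_phase_iters"] = result.final_phase_iters
            doc["final_phase_converged"] = result.final_phase_converged
        for key, val in result.extras.items():
            doc[key] = _jsonable(val)
    if assay_scores:
        for key, val in assay_scores.items():
            doc[key] = _jsonable(val)
    return doc


def write_trace(result: RunResult, path) -> None:
    """Per-reset CSV trace: reset_index, settle_steps, energy_current,
    energy_original (blank when not assayed)."""
    rows = {
        "reset_index": [r.reset_index for r in result.records],
        "settle_steps": [r.settle_steps for r in result.records],
        "energy_current": [r.energy_current for r in result.records],
        "energy_original": [r.energy_original for r in result.records],
    }
    if result.baseline_energies is not None:
        rows["energy_baseline"] = list(result.baseline_energies)
    pd.DataFrame(rows).to_csv(path, index=False)
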