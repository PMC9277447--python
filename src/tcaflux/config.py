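"""Run configuration: nested key-value files (YAML) and deterministic
artifact serialization.

Sections: [tracer] enrichment / glycolytic_inflow / natural_abundance;
[network] variant; [solver] tolerance / max_iterations; [fit] n_starts /
include_lactate; [scenario] condition / fluxes / n_replicates / noise_sd /
flux_cv. Every stochastic command takes an explicit seed; artifacts embed
the config hash and seed so identical config + seed reproduce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .network import FluxParameters, TracerSpec

__all__ = ["RunConfig", "load_config", "config_hash", "write_json", "jsonify"]

_DEFAULTS = {
    "tracer": {"enrichment": 1.0, "glycolytic_inflow": 2.0, "natural_abundance": 0.0},
    "network": {"variant": "full"},
    "solver": {"tolerance": 1e-10, "max_iterations": 10_000},
    "fit": {"n_starts": 10, "include_lactate": True},
    "scenario": {},
}


@dataclass(frozen=True)
class RunConfig:
    tracer: TracerSpec
    variant: str
    solver_tolerance: float
    solver_max_iterations: int
    n_starts: int
    include_lactate: bool
    scenario: dict
    raw: dict = field(repr=False)

    def flux_start(self) -> FluxParameters | None:
        fl = self.scenario.get("fluxes")
        return FluxParameters(**fl) if fl else None


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration, merging file values over defaults."""
    merged = {k: dict(v) for k, v in _DEFAULTS.items()}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        for section, values in loaded.items():
            if section not in merged:
                raise ValueError(f"unknown config section [{section}]")
            merged[section].update(values or {})
    for section, values in (overrides or {}).items():
        merged[section].update({k: v for k, v in values.items() if v is not None})
    tracer = TracerSpec(**merged["tracer"])
    tracer.validate()
    return RunConfig(
        tracer=tracer,
        variant=merged["network"]["variant"],
        solver_tolerance=float(merged["solver"]["tolerance"]),
        solver_max_iterations=int(merged["solver"]["max_iterations"]),
        n_starts=int(merged["fit"]["n_starts"]),
        include_lactate=bool(merged["fit"]["include_lactate"]),
        scenario=merged["scenario"],
        raw=merged,
    )


def jsonify(obj, precision: int = 10):
    """Recursively convert to JSON-safe types with fixed float precision."""
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): jsonify(v, precision) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonify(v, precision) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return round(v, precision) if np.isfinite(v) else repr(v)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [jsonify(v, precision) for v in obj.tolist()]
    return obj


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(jsonify(config.raw), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_json(path: str | Path, payload: dict) -> None:
    """Deterministic JSON artifact (sorted keys, fixed float precision)."""
    Path(path).write_text(
        json.dumps(jsonify(payload), sort_keys=True, indent=1) + "\n",
        encoding="utf-8",
    )
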