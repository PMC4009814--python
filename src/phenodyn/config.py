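"""Configuration loading and validation.

A run configuration is a YAML mapping with up to six blocks — ``seasonal``,
``demography``, ``solver``, ``experiment``, ``output``, ``seed`` — each
optional.  Missing values fall back to the reference baseline, so an empty
file (or no file) describes the canonical parameterisation.  Unknown keys
are rejected rather than silently ignored, and configurations round-trip
losslessly through :func:`config_to_dict` / :func:`config_from_dict`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .population import DemographyParams, SolverOptions
from .seasonal import SeasonalParams

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "config_from_dict",
    "config_to_dict",
    "dump_config",
]


class ConfigError(ValueError):
    """A configuration file is malformed or violates a model invariant."""


@dataclass(frozen=True)
class RunConfig:
    seasonal: SeasonalParams = field(default_factory=SeasonalParams)
    demography: DemographyParams = field(default_factory=DemographyParams)
    solver: SolverOptions = field(default_factory=SolverOptions)
    experiment: dict = field(default_factory=lambda: {"kind": "ess"})
    output: dict = field(default_factory=dict)
    seed: int = 0


_EXPERIMENT_KINDS = {"ess", "equilibrium", "scenario", "sweep"}


def _build_block(cls, block: Any, name: str):
    if block is None:
        block = {}
    if not isinstance(block, dict):
        raise ConfigError(f"config block {name!r} must be a mapping")
    allowed = {f.name for f in fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in config block {name!r}; "
            f"allowed: {sorted(allowed)}"
        )
    clean = {}
    for key, val in block.items():
        if isinstance(val, (int, float)) and not np.isfinite(val):
            raise ConfigError(f"{name}.{key} must be finite, got {val!r}")
        if isinstance(val, list):
            val = tuple(val)
        clean[key] = val
    try:
        return cls(**clean)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid config block {name!r}: {exc}") from exc


def config_from_dict(data: Optional[dict]) -> RunConfig:
    """Validate a plain mapping into a :class:`RunConfig` with defaults filled."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("top-level config must be a mapping")
    allowed = {"seasonal", "demography", "solver", "experiment", "output", "seed"}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown top-level key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    experiment = data.get("experiment") or {"kind": "ess"}
    if not isinstance(experiment, dict):
        raise ConfigError("config block 'experiment' must be a mapping")
    kind = experiment.get("kind", "ess")
    if kind not in _EXPERIMENT_KINDS:
        raise ConfigError(
            f"experiment.kind must be one of {sorted(_EXPERIMENT_KINDS)}, got {kind!r}"
        )
    output = data.get("output") or {}
    if not isinstance(output, dict):
        raise ConfigError("config block 'output' must be a mapping")
    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    return RunConfig(
        seasonal=_build_block(SeasonalParams, data.get("seasonal"), "seasonal"),
        demography=_build_block(DemographyParams, data.get("demography"), "demography"),
        solver=_build_block(SolverOptions, data.get("solver"), "solver"),
        experiment={"kind": kind, **{k: v for k, v in experiment.items() if k != "kind"}},
        output=dict(output),
        seed=seed,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration from ``path``."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(data)


def config_to_dict(cfg: RunConfig) -> dict:
    """Plain-dict form of a configuration; inverse of :func:`config_from_dict`."""
    solver = asdict(cfg.solver)
    if solver.get("bracket") is not None:
        solver["bracket"] = list(solver["bracket"])
    return {
        "seasonal": asdict(cfg.seasonal),
        "demography": asdict(cfg.demography),
        "solver": solver,
        "experiment": dict(cfg.experiment),
        "output": dict(cfg.output),
        "seed": cfg.seed,
    }


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
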