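"""Flat key-value run configuration (YAML/JSON) and result serialization."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .baselines import ClassicSeirParams
from .engine import EnsembleResult, SimulationResult
from .heterogeneity import ModelParams, State

__all__ = [
    "ConfigError", "UnknownConfigKey", "ConfigValueError", "MalformedConfigFile",
    "RunConfig", "read_config", "write_results",
]


class ConfigError(Exception):
    """Base class for configuration problems."""


class UnknownConfigKey(ConfigError):
    pass


class ConfigValueError(ConfigError):
    pass


class MalformedConfigFile(ConfigError):
    pass


_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
_CLASSIC_KEYS = {"acceptance_coef", "dissemination_coef", "immune_coef"}
_EXTRA_KEYS = {"experiment", "out", "runs", "steps_per_day", "mu"}
KNOWN_KEYS = _MODEL_KEYS | _CLASSIC_KEYS | _EXTRA_KEYS


@dataclasses.dataclass
class RunConfig:
    """A validated, fully defaulted flat configuration document."""

    values: dict

    def model_params(self) -> ModelParams:
        kw = {k: v for k, v in self.values.items() if k in _MODEL_KEYS}
        try:
            return ModelParams(**kw)
        except (ValueError, TypeError) as exc:
            raise ConfigValueError(str(exc)) from exc

    def classic_seir_params(self) -> ClassicSeirParams:
        kw = {k: v for k, v in self.values.items()
              if k in _CLASSIC_KEYS or k in {"init_comm_frac", "N", "max_steps",
                                             "seed", "network", "ba_m_attach",
                                             "ws_k_ring", "ws_p_rewire", "er_p_edge"}}
        try:
            return ClassicSeirParams(**kw)
        except (ValueError, TypeError) as exc:
            raise ConfigValueError(str(exc)) from exc

    def get(self, key: str, default=None):
        return self.values.get(key, default)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=True)


def read_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a flat YAML/JSON config; unknown keys are rejected
    and every parameter-range violation raises a named error."""
    values: dict = {}
    if path is not None:
        try:
            with open(path) as fh:
                loaded = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise MalformedConfigFile(f"{path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise MalformedConfigFile(f"{path}: expected a flat mapping")
        values.update(loaded)
    if overrides:
        values.update(overrides)
    unknown = set(values) - KNOWN_KEYS
    if unknown:
        raise UnknownConfigKey(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(values=values)
    cfg.model_params()  # validate ranges eagerly
    return cfg


def write_results(result: SimulationResult | EnsembleResult, out_dir: str | Path,
                  seed: int | None = None) -> Path:
    """Write CSV series plus a JSON manifest of parameters and seeds."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(result, EnsembleResult):
        counts = {s.name: result.mean_counts(s) for s in State}
        polar = result.mean_polarizability()
        params = result.runs[0].params
        manifest = {"kind": "ensemble", "n_runs": len(result.runs),
                    "average_rsd_polarizability": result.average_rsd()}
    else:
        counts = {s.name: result.count_series(s) for s in State}
        polar = result.polarizability
        params = result.params
        manifest = {"kind": "single", "termination": result.termination}
    t = np.arange(len(polar))
    import pandas as pd
    df = pd.DataFrame({"t": t, **{k: np.asarray(v) for k, v in counts.items()},
                       "polarizability": polar})
    df.to_csv(out / "series.csv", index=False)
    manifest.update({"seed": seed, "params": dataclasses.asdict(params)})
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
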