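"""Run configuration and tabular IO.

One config dialect: flat-keyed YAML.  Unknown keys are rejected with the
offending name rather than ignored, and every run writes a metadata record
(the fully resolved config plus the tool version) next to its outputs so a
job can be re-run from its output directory alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .scenarios import Scenario, figure1_scenarios
from .simulate import DEFAULT_ATOL, DEFAULT_RTOL, DEFAULT_SS_TOL, DEFAULT_T_MAX

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "save_config",
    "resolve_scenario",
    "write_table",
    "read_table",
    "write_metadata",
]

#: Numeric formatting used by every table writer: locale-independent,
#: round-trips doubles exactly.
FLOAT_FORMAT = "%.17g"
TABLE_SEP = "\t"


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key."""


_RUNCONFIG_KEYS = {
    "scenario",
    "out_dir",
    "rtol",
    "atol",
    "ss_tol",
    "t_max",
    "seed",
    "verbosity",
}


@dataclass
class RunConfig:
    """Everything one run needs: the scenario, tolerances, seed, output dir."""

    scenario: str | Scenario = "fig1D_dynamics"
    out_dir: str = "out"
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    ss_tol: float = DEFAULT_SS_TOL
    t_max: float = DEFAULT_T_MAX
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("rtol", "atol", "ss_tol", "t_max"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or v <= 0:
                raise ConfigError(f"config key {name!r} must be a positive number, got {v!r}")
        if not isinstance(self.seed, int):
            raise ConfigError(f"config key 'seed' must be an integer, got {self.seed!r}")
        if self.verbosity not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"config key 'verbosity' has invalid value {self.verbosity!r}")

    def to_dict(self) -> dict:
        data = {
            "scenario": self.scenario.to_dict()
            if isinstance(self.scenario, Scenario)
            else self.scenario,
            "out_dir": self.out_dir,
            "rtol": float(self.rtol),
            "atol": float(self.atol),
            "ss_tol": float(self.ss_tol),
            "t_max": float(self.t_max),
            "seed": int(self.seed),
            "verbosity": self.verbosity,
        }
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict) or not data:
            raise ConfigError("config must be a non-empty key/value mapping")
        unknown = sorted(set(data) - _RUNCONFIG_KEYS)
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
        scenario = data.get("scenario", "fig1D_dynamics")
        if isinstance(scenario, dict):
            try:
                scenario = Scenario.from_dict(scenario)
            except (ValueError, KeyError) as err:
                raise ConfigError(f"invalid inline scenario: {err}") from err
        return cls(
            scenario=scenario,
            out_dir=str(data.get("out_dir", "out")),
            rtol=data.get("rtol", DEFAULT_RTOL),
            atol=data.get("atol", DEFAULT_ATOL),
            ss_tol=data.get("ss_tol", DEFAULT_SS_TOL),
            t_max=data.get("t_max", DEFAULT_T_MAX),
            seed=data.get("seed", 0),
            verbosity=str(data.get("verbosity", "INFO")),
        )


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run config; empty files are an error."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse config {path}: {err}") from err
    if data is None:
        raise ConfigError(f"config file {path} is empty")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False, default_flow_style=False)
    )


def resolve_scenario(config: RunConfig) -> Scenario:
    """Materialize the config's scenario, by bundled name or inline body."""
    if isinstance(config.scenario, Scenario):
        return config.scenario
    by_name = {s.name: s for s in figure1_scenarios()}
    if config.scenario not in by_name:
        raise ConfigError(
            f"unknown scenario {config.scenario!r}; bundled scenarios: "
            f"{', '.join(sorted(by_name))}"
        )
    return by_name[config.scenario]


def write_table(records, path: str | Path, columns: list[str] | None = None) -> None:
    """Write records as a delimited table with a fixed column order.

    Floats are rendered at 17 significant digits so a written value parses
    back to the identical double on any platform.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if columns is not None:
        df = df[columns]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=TABLE_SEP, index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=TABLE_SEP, float_precision="round_trip")


def write_metadata(config: RunConfig, out_dir: str | Path) -> Path:
    """Record the resolved config and tool version beside the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {"tool": "gahacr-sim", "version": __version__}
    record.update(config.to_dict())
    scenario = resolve_scenario(config)
    record["scenario"] = scenario.to_dict()
    path = out_dir / "run_metadata.yaml"
    path.write_text(yaml.safe_dump(record, sort_keys=False, default_flow_style=False))
    return path
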