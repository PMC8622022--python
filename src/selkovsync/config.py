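"""Run configuration: a nested, YAML-round-trippable description of a run.

A :class:`RunConfig` pins everything a run needs — kinetics, grid, time
stepping, initial conditions (named fixtures plus a seed), control gain
(a number or ``"auto"`` for the bound-estimation pipeline) and output
destination/format — so that two runs of the same file are bit-identical
in their diagnostics tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .grids import Grid, State, TimeSteppingConfig, build_grid, stable_dt
from .ics import ic_reference_drive, ic_reference_response, ic_perturbed_steady
from .model import KineticParams

__all__ = ["RunConfig", "reference_config", "ConfigError"]

_IC_FIXTURES = ("reference_drive", "reference_response", "perturbed_steady")


class ConfigError(ValueError):
    """Configuration validation error; the message names the bad field."""


@dataclass
class RunConfig:
    # kinetics
    a: float = 3.5
    b: float = 0.25
    d1: float = 0.01
    d2: float = 1.0
    # grid
    ndim: int = 1
    extent: float = 10.0
    n_points: int = 51
    # time stepping
    t_end: float = 100.0
    snapshot_interval: float = 4.0
    cfl_safety: float = 0.9
    dt: Union[float, str] = "auto"
    # initial conditions
    ic_drive: str = "reference_drive"
    ic_response: str = "reference_response"
    ic_variant: str = "x"
    ic_amplitude: float = 0.05
    seed: int = 0
    # control
    K: Union[float, str] = 15.0         # number or "auto"
    bound_margin: float = 1.2
    gain_overrides: Optional[dict] = None  # {"c11": .., "c12": .., "c22": ..}
    # output
    out_dir: str = "out"
    out_format: str = "hdf5"            # "hdf5" or "csv"

    def validate(self) -> None:
        for name in ("a", "b", "d1", "d2"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"field '{name}' must be > 0")
        if self.ndim not in (1, 2):
            raise ConfigError("field 'ndim' must be 1 or 2")
        if self.n_points < 3:
            raise ConfigError("field 'n_points' must be >= 3")
        if self.extent <= 0:
            raise ConfigError("field 'extent' must be > 0")
        if self.t_end < 0:
            raise ConfigError("field 't_end' must be >= 0")
        if not 0 < self.cfl_safety <= 1:
            raise ConfigError("field 'cfl_safety' must be in (0, 1]")
        for name in ("ic_drive", "ic_response"):
            if getattr(self, name) not in _IC_FIXTURES:
                raise ConfigError(
                    f"field '{name}' must be one of {_IC_FIXTURES}, "
                    f"got {getattr(self, name)!r}"
                )
        if self.K != "auto" and (not isinstance(self.K, (int, float)) or self.K <= 0):
            raise ConfigError("field 'K' must be a positive number or 'auto'")
        if self.dt != "auto" and (not isinstance(self.dt, (int, float)) or self.dt <= 0):
            raise ConfigError("field 'dt' must be a positive number or 'auto'")
        if self.out_format not in ("hdf5", "csv"):
            raise ConfigError("field 'out_format' must be 'hdf5' or 'csv'")

    # -- builders ---------------------------------------------------------
    def kinetic_params(self) -> KineticParams:
        return KineticParams(a=self.a, b=self.b, d1=self.d1, d2=self.d2)

    def grid(self) -> Grid:
        return build_grid(self.ndim, self.extent, self.n_points)

    def timestepping(self) -> TimeSteppingConfig:
        params, grid = self.kinetic_params(), self.grid()
        if self.dt == "auto":
            return TimeSteppingConfig.from_cfl(
                params, grid, t_end=self.t_end,
                snapshot_interval=self.snapshot_interval,
                cfl_safety=self.cfl_safety,
            )
        tcfg = TimeSteppingConfig(
            dt=float(self.dt), t_end=self.t_end,
            snapshot_interval=self.snapshot_interval, cfl_safety=self.cfl_safety,
        )
        tcfg.validate_against(params, grid)  # manual dt must be stable
        return tcfg

    def initial_state(self, which: str) -> State:
        name = {"drive": self.ic_drive, "response": self.ic_response}[which]
        grid = self.grid()
        if name == "reference_drive":
            return ic_reference_drive(grid, variant=self.ic_variant)
        if name == "reference_response":
            return ic_reference_response(grid, variant=self.ic_variant)
        # perturbed_steady: decorrelate drive/response with a seed offset
        offset = 0 if which == "drive" else 1
        return ic_perturbed_steady(
            self.kinetic_params(), grid, self.ic_amplitude, self.seed + offset
        )

    # -- serialisation ----------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=False, default_flow_style=False)
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def reference_config() -> RunConfig:
    """The 1D reference synchronization experiment.

    Domain [0, 10] at spacing 0.2, t in [0, 100] with snapshots every 4,
    kinetics (d1, d2, a, b) = (0.01, 1, 3.5, 0.25), sinusoidal drive and
    response fixtures, gain K = 15.
    """
    return RunConfig()
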