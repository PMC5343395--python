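"""Run configuration: a flat YAML mapping validated into simulation params.

All keys are optional; an empty file yields the reference defaults (capacity
10'000, 100'000 steps, 5% random kill, 0.1% mutation, noninformative regime,
one environment).  Precedence: built-in defaults < named profile < explicit
keys in the file < keyword overrides.  Unknown keys are rejected, ranges are
validated before anything runs, and ``load -> dump -> load`` round-trips to
identical effective parameters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .environment import EnvironmentParams
from .errors import (
    ConfigFileError,
    ConfigParseError,
    OutOfRangeError,
    ParameterError,
    UnknownKeyError,
)
from .evolution import SimulationParams
from .experiments import PROFILES

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    """Flat, file-friendly mirror of the simulation + experiment parameters."""

    # experiment
    profile: str | None = None
    n_replicates: int = 20
    outdir: str = "results"
    # population / evolution
    capacity: int = 10_000
    n_steps: int = 100_000
    random_kill_rate: float = 0.05
    mutation_rate: float = 0.001
    mutation_kernel: str = "step"
    split_mode: str = "fixed_half"
    migration_mode: str | None = None
    survival_form: str = "power15"
    cost_form: str = "production"
    seed: int = 0
    record_every: int = 100
    # environment
    regime: str = "noninformative"
    p_warning: float = 0.005
    p_stress: float = 0.004
    p_follow: float = 0.8
    switch_rate: float = 0.2
    n_envs: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    def to_environment_params(self) -> EnvironmentParams:
        try:
            return EnvironmentParams(
                regime=self.regime,
                p_warning=self.p_warning,
                p_stress=self.p_stress,
                p_follow=self.p_follow,
                switch_rate=self.switch_rate,
                n_steps=self.n_steps,
                n_envs=self.n_envs,
            )
        except ParameterError as exc:
            raise OutOfRangeError(str(exc)) from exc

    def to_simulation_params(self) -> SimulationParams:
        env = self.to_environment_params()
        try:
            return SimulationParams(
                capacity=self.capacity,
                n_steps=self.n_steps,
                random_kill_rate=self.random_kill_rate,
                mutation_rate=self.mutation_rate,
                mutation_kernel=self.mutation_kernel,
                split_mode=self.split_mode,
                migration_mode=self.migration_mode,
                env_params=env,
                survival_form=self.survival_form,
                cost_form=self.cost_form,
                seed=self.seed,
                record_every=self.record_every,
            )
        except ParameterError as exc:
            raise OutOfRangeError(str(exc)) from exc

    @classmethod
    def from_dict(cls, data: dict | None, **overrides) -> "RunConfig":
        data = dict(data or {})
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise UnknownKeyError(f"unknown configuration keys: {unknown}")
        profile = data.get("profile")
        if profile is not None:
            if profile not in PROFILES:
                raise UnknownKeyError(
                    f"unknown profile {profile!r}; known: {sorted(PROFILES)}"
                )
            merged = dict(PROFILES[profile])
            merged.update(data)  # explicit keys win over the profile
            data = merged
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise OutOfRangeError(f"n_replicates={self.n_replicates} must be >= 1")
        # range/consistency checks live in the params constructors
        self.to_simulation_params()


def load_config(path, **overrides) -> RunConfig:
    """Load, validate and default-fill a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigFileError(f"configuration file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigParseError(f"could not parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigParseError(f"{path} must contain a mapping at top level")
    return RunConfig.from_dict(data, **overrides)


def dump_config(cfg: RunConfig, path) -> None:
    """Write the effective configuration back out as YAML."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
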