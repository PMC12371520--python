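"""Configuration: schema, TOML parsing/serialisation, presets.

A configuration fully and reproducibly describes one run.  Unknown keys are
rejected with their full path; a resolved config (all defaults filled) can
be dumped back to TOML and reloaded to an identical object.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path

import numpy as np

from .core import Feedback, ForceField
from .regulation import KineticParams

__all__ = [
    "FibreConfig",
    "TFConfig",
    "IntegratorConfig",
    "SamplingConfig",
    "ObservablesConfig",
    "SimulationConfig",
    "load_config",
    "dump_config",
    "dumps_config",
    "preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class FibreConfig:
    n_beads: int = 200
    n_tu: int = 8
    tu_ids: tuple = ()  # explicit 1-based IDs; empty -> seeded random placement
    tu_seed: int = 2025  # seed for random TU placement when tu_ids is empty
    box_length: float = 35.0  # sigma


@dataclass(frozen=True)
class TFConfig:
    n_active: int = 8
    n_repressive: int = 8
    n_on_each: int = 4


@dataclass(frozen=True)
class IntegratorConfig:
    dt: float = 1e-2  # simulation time units (tau)
    gamma: float = 1.0
    kT: float = 1.0
    steps: int = 200_000
    neighbor_skin: float = 0.8  # sigma
    neighbor_method: str = "cells"  # "cells" | "allpairs"
    relax_iter: int = 200  # steepest-descent iterations before dynamics


@dataclass(frozen=True)
class SamplingConfig:
    stride: int = 100  # steps between recorded frames
    equilibration_fraction: float = 0.1
    trajectory_format: str = "none"  # "none" | "xyz" | "lammps"
    trajectory_stride: int = 1000


@dataclass(frozen=True)
class ObservablesConfig:
    r_clust: float = 2.0  # sigma, cluster linkage cutoff
    min_cluster_size: int = 2
    cluster_on_only: bool = True
    noise_metric: str = "sd"  # "sd" | "var"
    correlation_threshold: float = 0.25


@dataclass(frozen=True)
class SimulationConfig:
    """Complete, seedable description of one run."""

    fibre: FibreConfig = field(default_factory=FibreConfig)
    tfs: TFConfig = field(default_factory=TFConfig)
    forcefield: ForceField = field(default_factory=ForceField)
    kinetics: KineticParams = field(default_factory=KineticParams)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    observables: ObservablesConfig = field(default_factory=ObservablesConfig)
    feedback: Feedback = Feedback.POSITIVE
    seed: int = 0

    def with_updates(self, **top_level) -> "SimulationConfig":
        """Copy with replaced top-level fields (e.g. feedback=..., kinetics=...)."""
        if "feedback" in top_level:
            top_level["feedback"] = Feedback(top_level["feedback"])
        return dataclasses.replace(self, **top_level)

    def with_ps(self, p_s: float) -> "SimulationConfig":
        return dataclasses.replace(
            self, kinetics=dataclasses.replace(self.kinetics, p_s=float(p_s))
        )

    def resolve_tu_ids(self) -> np.ndarray:
        """1-based TU bead IDs, drawing random positions when not explicit."""
        if self.fibre.tu_ids:
            return np.asarray(sorted(self.fibre.tu_ids), dtype=np.int64)
        rng = np.random.default_rng(self.fibre.tu_seed)
        ids = rng.choice(self.fibre.n_beads, size=self.fibre.n_tu, replace=False) + 1
        return np.sort(ids)

    def validate(self) -> None:
        f = self.fibre
        if f.n_beads < 1:
            raise ValueError("fibre.n_beads must be >= 1")
        if f.tu_ids:
            ids = list(f.tu_ids)
            if len(set(ids)) != len(ids):
                raise ValueError("fibre.tu_ids contains duplicates")
            if min(ids) < 1 or max(ids) > f.n_beads:
                raise ValueError(
                    f"fibre.tu_ids must lie in [1, {f.n_beads}] (1-based)"
                )
        elif f.n_tu > f.n_beads:
            raise ValueError("fibre.n_tu exceeds fibre.n_beads")
        if self.tfs.n_on_each > 0 and (
            self.tfs.n_on_each > self.tfs.n_active
            or self.tfs.n_on_each > self.tfs.n_repressive
        ):
            raise ValueError("tfs.n_on_each exceeds a TF species count")
        if self.integrator.dt <= 0 or self.integrator.steps < 0:
            raise ValueError("integrator.dt must be > 0 and steps >= 0")
        if self.sampling.stride < 1:
            raise ValueError("sampling.stride must be >= 1")
        if not 0.0 <= self.sampling.equilibration_fraction < 1.0:
            raise ValueError("sampling.equilibration_fraction must be in [0, 1)")
        if self.sampling.trajectory_format not in ("none", "xyz", "lammps"):
            raise ValueError("sampling.trajectory_format must be none|xyz|lammps")
        if self.observables.noise_metric not in ("sd", "var"):
            raise ValueError("observables.noise_metric must be sd|var")
        if self.integrator.neighbor_method not in ("cells", "allpairs"):
            raise ValueError("integrator.neighbor_method must be cells|allpairs")
        # dataclass __post_init__ already validates forcefield and kinetics


_SECTIONS = {
    "fibre": FibreConfig,
    "tfs": TFConfig,
    "forcefield": ForceField,
    "kinetics": KineticParams,
    "integrator": IntegratorConfig,
    "sampling": SamplingConfig,
    "observables": ObservablesConfig,
}


def _build_section(cls, data: dict, path: str):
    valid = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"unknown config key: {path}.{key}")
        if key == "tu_ids":
            value = tuple(int(v) for v in value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid [{path}] section: {exc}") from exc


def config_from_dict(data: dict) -> SimulationConfig:
    """Build and validate a SimulationConfig from a nested dict."""
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"config section [{key}] must be a table")
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        elif key == "feedback":
            try:
                kwargs["feedback"] = Feedback(value)
            except ValueError:
                raise ValueError(
                    f"unknown feedback {value!r} (expected positive|negative|neutral)"
                ) from None
        elif key == "seed":
            kwargs["seed"] = int(value)
        else:
            raise ValueError(f"unknown config key: {key}")
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg


def config_to_dict(cfg: SimulationConfig) -> dict:
    out: dict = {"feedback": cfg.feedback.value, "seed": cfg.seed}
    for name, _ in _SECTIONS.items():
        section = getattr(cfg, name)
        d = {}
        for f in fields(section):
            v = getattr(section, f.name)
            if isinstance(v, tuple):
                v = list(v)
            d[f.name] = v
        out[name] = d
    return out


def load_config(path) -> SimulationConfig:
    """Load and validate a TOML configuration file (defaults resolved)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return config_from_dict(data)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)} to TOML")


def dumps_config(cfg: SimulationConfig) -> str:
    """Serialise a resolved configuration to TOML text."""
    data = config_to_dict(cfg)
    lines = [f"feedback = {_toml_value(data['feedback'])}",
             f"seed = {_toml_value(data['seed'])}", ""]
    for name in _SECTIONS:
        lines.append(f"[{name}]")
        for k, v in data[name].items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    return "\n".join(lines)


def dump_config(cfg: SimulationConfig, path) -> None:
    Path(path).write_text(dumps_config(cfg))


PRESET_NAMES = ("paper1000", "reduced200", "smoke_tiny")


def preset(name: str) -> SimulationConfig:
    """Load a shipped preset configuration by name."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    ref = resources.files("chromsilence").joinpath(f"presets/{name}.toml")
    with ref.open("rb") as fh:
        return config_from_dict(tomllib.load(fh))
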