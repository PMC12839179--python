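"""Pipeline configuration: one YAML file drives the whole sweep.

All physical quantities are SI (kg, m, s, N/m, radians internally;
degrees appear only at the .mot boundary). A single seed feeds named
per-stage substreams so an end-to-end run is fully deterministic.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exo import ExoGeometry
from .gait import DEFAULT_NOISE_SD, DEFAULT_SPEED, DEFAULT_STANCE_DURATION
from .redundancy import DEFAULT_RESERVE_WEIGHT
from .sweep import GRID_DEFAULTS

__all__ = ["SubjectConfig", "GaitConfig", "GridConfig", "SolverConfig",
           "PipelineConfig"]


@dataclass
class SubjectConfig:
    mass: float = 87.6      # kg
    height: float = 1.86    # m


@dataclass
class GaitConfig:
    speed: float = DEFAULT_SPEED
    stance_duration: float = DEFAULT_STANCE_DURATION
    noise_sd: float = DEFAULT_NOISE_SD
    n_contacts: int = 10
    n_samples: int = 100
    seed: int = 20260101


@dataclass
class GridConfig:
    k_min: float = GRID_DEFAULTS["k_min"]
    k_max: float = GRID_DEFAULTS["k_max"]
    k_step: float = GRID_DEFAULTS["k_step"]
    tau_min: float = GRID_DEFAULTS["tau_min"]
    tau_max: float = GRID_DEFAULTS["tau_max"]
    tau_step: float = GRID_DEFAULTS["tau_step"]


@dataclass
class SolverConfig:
    reserve_weight: float = DEFAULT_RESERVE_WEIGHT


@dataclass
class PipelineConfig:
    subject: SubjectConfig = field(default_factory=SubjectConfig)
    gait: GaitConfig = field(default_factory=GaitConfig)
    exo: ExoGeometry = field(default_factory=ExoGeometry)
    grid: GridConfig = field(default_factory=GridConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    outdir: str = "exosweep_out"

    def __post_init__(self) -> None:
        for name, value in (("mass", self.subject.mass),
                            ("height", self.subject.height),
                            ("speed", self.gait.speed),
                            ("stance_duration", self.gait.stance_duration)):
            if value <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            subject=SubjectConfig(**data.get("subject", {})),
            gait=GaitConfig(**data.get("gait", {})),
            exo=ExoGeometry(**data.get("exo", {})),
            grid=GridConfig(**data.get("grid", {})),
            solver=SolverConfig(**data.get("solver", {})),
            outdir=data.get("outdir", "exosweep_out"),
        )
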