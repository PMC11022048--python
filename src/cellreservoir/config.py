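"""Validated run configuration (YAML) with reference defaults.

Defaults are the reference study conditions: radii 10/9/2.5 μm, 0.5 μm
voxels, 20% cytoskeleton fill, log-normal conductance mean 0.1 / sd 0.5,
Debye length 1 μm, unit source charge, memory retention β = 0.9, the five
noise levels, and 20-trial ensembles.  Unknown keys are rejected so typos
fail loudly; every stochastic component has its own named seed.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Block):
    voxel_size: float = 0.5   # μm
    r_cm: float = 10.0        # μm
    r_pc: float = 9.0         # μm
    r_co: float = 2.5         # μm
    cs_fraction: float = 0.20

    @model_validator(mode="after")
    def _ordered(self):
        if not (0 < self.r_co < self.r_pc < self.r_cm):
            raise ValueError("radii must satisfy 0 < r_co < r_pc < r_cm")
        return self

    def build_kwargs(self) -> dict:
        return dict(
            voxel_size=self.voxel_size, r_cm=self.r_cm, r_pc=self.r_pc, r_co=self.r_co
        )


class ReservoirConfig(_Block):
    conductance_mean: float = 0.1
    conductance_sd: float = 0.5
    conduct_membrane: bool = False   # CM shell conduction switch


class DynamicsConfig(_Block):
    debye_length: float = 1.0   # μm
    beta: float = 0.5
    source_kind: str = "spherical"
    charge: float = 1.0
    charge_scale: float = 1.0 / 150.0  # δq (mM) → simulation units
    max_steps_factor: int = 4
    gate_downhill: bool = True


class ReadoutConfig(_Block):
    kind: str = "ann"
    l1: float = 1e-4
    l2: float = 1e-4
    hidden_width: int = 64
    epochs: int = 3000
    learning_rate: float = 0.01
    split: float = 0.25


class ExperimentConfig(_Block):
    fractions: list[float] = [f / 100 for f in range(1, 16)]
    n_trials: int = 100
    sigmas: list[float] = [0.05, 0.1, 0.25, 0.5, 1.0]
    n_ensemble: int = 20
    n_samples: int | None = None   # None: ten periods
    period: float | None = None   # None: 4x organelle arrival delay
    k_levels: list[float] = [0.0, 10.0, 20.0, 40.0]


class SeedsConfig(_Block):
    geometry: int = 11
    conductance: int = 12
    noise: int = 13
    readout_init: int = 14
    ensemble: int = 15


class RunConfig(_Block):
    geometry: GeometryConfig = GeometryConfig()
    reservoir: ReservoirConfig = ReservoirConfig()
    dynamics: DynamicsConfig = DynamicsConfig()
    readout: ReadoutConfig = ReadoutConfig()
    experiment: ExperimentConfig = ExperimentConfig()
    seeds: SeedsConfig = SeedsConfig()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; missing keys take the defaults.

    An empty (or absent) file yields the full default configuration.
    Schema violations raise with the offending keys listed.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
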