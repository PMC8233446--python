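"""Run configuration: YAML schema, loading, validation, round-tripping.

Unknown keys are hard errors (pydantic ``extra='forbid'``); all geometric
quantities carry explicit unit suffixes in their key names (SI units).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from tassaw.device import DeviceConfig, device_from_dict


class ConfigError(ValueError):
    pass


class CalibrationModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    voltage_v: float = Field(gt=0)
    pressure_pa: float = Field(gt=0)


class ParticleModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: Optional[str] = None
    material: str
    diameter_m: float = Field(gt=0)


class StageModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str
    length_m: float = Field(gt=0)
    width_m: float = Field(gt=0)
    tilt_deg: float = 0.0
    drive_voltage_v: float = 0.0
    drive_voltage_v_cells: Optional[float] = None
    calibration: Optional[CalibrationModel] = None
    axial_flow_m_s: float = 0.0
    side_flow_m_s: float = 0.0
    side_inlet_width_m: float = 0.0


class NumericsModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: str = "overdamped"
    rtol: float = Field(default=1e-6, gt=0)
    n_save: int = Field(default=120, ge=2)
    streaming_grid: tuple[int, int, int] = (32, 16, 8)
    streaming_enabled: bool = False


class RunConfigModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = "device"
    fluid: str
    frequency_hz: float = Field(gt=0)
    wavelength_m: float = Field(gt=0)
    channel_height_m: float = Field(gt=0)
    trace_height_m: float = 20e-6
    seed: int = 0
    default_particle_set: Optional[str] = None
    particle_sets: dict[str, list[ParticleModel]]
    release_offsets_m: list[float] = [0.0]
    stages: list[StageModel]
    numerics: NumericsModel = NumericsModel()
    output_dir: Optional[str] = None


class RunConfig:
    """A validated run configuration plus the assembled DeviceConfig."""

    def __init__(self, model: RunConfigModel,
                 particle_set: Optional[str] = None):
        self.model = model
        self.particle_set = particle_set
        self.device: DeviceConfig = device_from_dict(
            self.to_dict(), particle_set=particle_set)

    @property
    def seed(self) -> int:
        return self.model.seed

    @property
    def numerics(self) -> NumericsModel:
        return self.model.numerics

    def to_dict(self) -> dict:
        return self.model.model_dump(exclude_none=True)

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path, particle_set: Optional[str] = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys raise a :class:`ConfigError` naming them; missing required
    keys raise with the offending field path.
    """
    p = Path(path)
    if not p.is_file():
        raise ConfigError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping: {p}")
    try:
        model = RunConfigModel.model_validate(raw)
    except ValidationError as exc:
        msgs = []
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"]) or "<root>"
            msgs.append(f"{loc}: {err['msg']}")
        raise ConfigError(
            f"invalid config {p}:\n  " + "\n  ".join(msgs)) from exc
    return RunConfig(model, particle_set=particle_set)
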