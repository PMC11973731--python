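"""Validated run configuration (YAML-friendly, pydantic-backed).

Every packaged constant that shapes a run — group distribution targets,
device settings, noise levels, replicate counts — is surfaced here and can
be overridden from a YAML mapping.  ``RunConfig.load`` reads a YAML file;
``RunConfig()`` gives the packaged defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .cohort import GOLD1_DEFAULT, GOLD4_DEFAULT, GroupSpec
from .simulate import DeviceModel, NoiseSpec

__all__ = ["RunConfig", "GroupSpecConfig", "NoiseConfig", "DeviceConfig"]


class GroupSpecConfig(BaseModel):
    """Overridable GroupSpec fields; omitted fields keep group defaults."""

    n: int | None = None
    medians: dict[str, float] | None = None
    iqrs: dict[str, float] | None = None
    age_mean: float | None = None
    age_sd: float | None = None
    bmi_mean: float | None = None
    bmi_sd: float | None = None
    pack_years_mean: float | None = None
    pack_years_sd: float | None = None
    female_fraction: float | None = None
    copula_rho: float | None = None

    def resolve(self, base: GroupSpec) -> GroupSpec:
        updates = {k: v for k, v in self.model_dump().items() if v is not None}
        if "medians" in updates:
            updates["medians"] = {**base.medians, **updates["medians"]}
        if "iqrs" in updates:
            updates["iqrs"] = {**base.iqrs, **updates["iqrs"]}
        return dataclasses.replace(base, **updates)


class NoiseConfig(BaseModel):
    flow_cv: float = Field(default=NoiseSpec.flow_cv, ge=0)
    artifact_prob: float = Field(default=NoiseSpec.artifact_prob, ge=0, le=1)
    artifact_scale: float = Field(default=NoiseSpec.artifact_scale, ge=0)
    breath_rate: float = Field(default=NoiseSpec.breath_rate, gt=0)
    breath_flow_amp: float = Field(default=NoiseSpec.breath_flow_amp, ge=0)

    def resolve(self) -> NoiseSpec:
        return NoiseSpec(**self.model_dump())


class DeviceConfig(BaseModel):
    """Shared (non-calibrated) device settings; per-participant sensor_fc
    and p_overshoot come from calibration, not from here."""

    P_trigger: float = Field(default=DeviceModel.P_trigger, gt=0)
    fs_reom: float = Field(default=DeviceModel.fs_reom, gt=0)
    fs_fot: float = Field(default=DeviceModel.fs_fot, gt=0)
    tones: tuple[float, ...] = DeviceModel.tones
    rep_duration: float = Field(default=DeviceModel.rep_duration, gt=0)
    tone_amplitude: float = Field(default=DeviceModel.tone_amplitude, gt=0)

    def resolve(self) -> DeviceModel:
        return DeviceModel(**self.model_dump())


class RunConfig(BaseModel):
    """Full configuration of one pipeline run."""

    seed: int = 0
    gold1: GroupSpecConfig = GroupSpecConfig()
    gold4: GroupSpecConfig = GroupSpecConfig()
    noise: NoiseConfig = NoiseConfig()
    device: DeviceConfig = DeviceConfig()
    cheek_hold: bool = False
    replicates: int = Field(default=1, ge=1)
    bootstrap: int = Field(default=2000, ge=0)
    export_waveforms: bool = False
    out_dir: str | None = None

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not 0 <= v < 2**31:
            raise ValueError("seed must be in [0, 2^31)")
        return v

    @property
    def gold1_spec(self) -> GroupSpec:
        return self.gold1.resolve(GOLD1_DEFAULT)

    @property
    def gold4_spec(self) -> GroupSpec:
        return self.gold4.resolve(GOLD4_DEFAULT)

    @property
    def noise_spec(self) -> NoiseSpec:
        return self.noise.resolve()

    @property
    def device_model(self) -> DeviceModel:
        return self.device.resolve()

    @classmethod
    def load(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
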