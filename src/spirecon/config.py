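"""Validated YAML run configuration (schema-checked, unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .geometry import DetectorGeometry
from .orient import CMConfig
from .simulate import SimulationParams

__all__ = ["RunConfig", "GeometryBlock", "SimulationBlock", "CMBlock",
           "PhasingBlock", "MetricsBlock"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryBlock(_Strict):
    wavelength_A: float = 1.0
    n_pixels: int = 64
    pixel_um: float = 300.0
    distance_m: float = 0.1
    beam_center: tuple[float, float] | None = None

    def build(self) -> DetectorGeometry:
        return DetectorGeometry(self.wavelength_A, self.n_pixels, self.pixel_um,
                                self.distance_m, self.beam_center)


class SimulationBlock(_Strict):
    photons_per_pulse: float = 2e15
    beam_focus_um: float = 0.1
    poisson: bool = True
    beam_stop_px: int = 0
    n_patterns: int = 100

    def build(self, seed: int) -> SimulationParams:
        return SimulationParams(photons_per_pulse=self.photons_per_pulse,
                                beam_focus_um=self.beam_focus_um, seed=seed,
                                poisson=self.poisson, beam_stop_px=self.beam_stop_px)


class CMBlock(_Strict):
    delta_beta: float = 0.1
    refine_delta_beta: float | None = 0.02
    r_min: int | None = None
    r_max: int | None = None
    n_theta: int | None = None
    max_iters: int = 10
    tol: float = 1e-3

    def build(self) -> CMConfig:
        return CMConfig(delta_beta=self.delta_beta,
                        refine_delta_beta=self.refine_delta_beta,
                        r_min=self.r_min, r_max=self.r_max, n_theta=self.n_theta,
                        max_iters=self.max_iters, tol=self.tol)


class PhasingBlock(_Strict):
    mode: str = "prior"  # "prior" | "random"
    schedule_scale: float = 1.0
    support_extent_A: float | None = None
    support_margin: float = 1.2
    hio_feedback: float = 0.9
    n_random_starts: int = 1


class MetricsBlock(_Strict):
    fsc_threshold: float = 0.5
    half_fsc_threshold: float = 0.143
    prtf_threshold: float = 0.36787944117144233  # 1/e


class RunConfig(_Strict):
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    cm: CMBlock = Field(default_factory=CMBlock)
    phasing: PhasingBlock = Field(default_factory=PhasingBlock)
    metrics: MetricsBlock = Field(default_factory=MetricsBlock)
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
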