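"""Structured, schema-validated pipeline configuration.

Pydantic models mirror the domain dataclasses; unknown keys are rejected
and a config round-trips read -> write -> read identically.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .forward_model import IlluminationModel, OpticalModel
from .preprocessing import PreprocessConfig
from .simulator import AcquisitionSpec, PhantomSpec


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticalConfig(_Strict):
    pupil_diameter_mm: float = 6.7
    imaging_wavelength_nm: float = 850.0
    pixel_scale: float = 1.0 / 403.0
    oversampling_factor: int = 2
    defocus_infocus: float = 0.0
    defocus_background: float = 1.5
    retinal_scale: float = 300.0

    def build(self) -> OpticalModel:
        return OpticalModel(**self.model_dump())


class IlluminationConfig(_Strict):
    modulation_frequency_cpd: float = 34.0
    orientations: tuple[float, ...] = (45.0, -45.0)
    frames_per_block: int = 50
    phase_per_frame: float = 0.0
    contrast_infocus: float = 0.3
    contrast_background: float = 0.0
    mean_level: float = 1.0

    def build(self) -> IlluminationModel:
        return IlluminationModel(**self.model_dump())


class PhantomConfig(_Strict):
    cone_spacing_um: float = 5.0
    spacing_jitter: float = 0.1
    cone_sigma_um: float = 1.2
    reflectance_cv: float = 0.2
    background_correlation_um: float = 15.0
    background_to_signal_ratio: float = 2.0
    rng_seed: int = 0

    def build(self) -> PhantomSpec:
        return PhantomSpec(**self.model_dump())


class AcquisitionConfig(_Strict):
    n_frames: int = 200
    frame_rate_hz: float = 100.0
    switching_rate_hz: float = 2.0
    noise_sigma: float = 0.05
    drift_step_px: float = 0.5
    microsaccade_rate_hz: float = 0.5
    microsaccade_amplitude_px: float = 8.0
    blink_fraction: float = 0.05
    dark_offset: float = 100.0

    def build(self) -> AcquisitionSpec:
        return AcquisitionSpec(**self.model_dump())


class PreprocessSection(_Strict):
    crop_size: int | None = None
    taper_fraction: float = 0.2

    def build(self) -> PreprocessConfig:
        return PreprocessConfig(**self.model_dump())


class SelectionConfig(_Strict):
    quality_quantile: float = 0.5
    window_seconds: float = 2.0
    tolerance_bins: int = 3


class ShiftConfig(_Strict):
    notch_radius_bins: float = 3.0
    upsample_factor: int = 50


class ReconstructionConfig(_Strict):
    lam: float = 0.3
    max_iter: int = 300
    tol: float = 1.0e-6


class MetricsConfig(_Strict):
    low_cut_cpd: float = 20.0
    high_cut_cpd: float = 180.0
    min_separation_px: float = 3.0
    density_window_px: int = 64


class PathsConfig(_Strict):
    frames: str = "frames.tif"
    dark: str = "dark.tif"
    output_dir: str = "output"


class PipelineConfig(_Strict):
    camera_pixels: int = 256
    seed: int = 0
    paths: PathsConfig = PathsConfig()
    optical: OpticalConfig = OpticalConfig()
    illumination: IlluminationConfig = IlluminationConfig()
    phantom: PhantomConfig = PhantomConfig()
    acquisition: AcquisitionConfig = AcquisitionConfig()
    preprocess: PreprocessSection = PreprocessSection()
    selection: SelectionConfig = SelectionConfig()
    shifts: ShiftConfig = ShiftConfig()
    reconstruction: ReconstructionConfig = ReconstructionConfig()
    metrics: MetricsConfig = MetricsConfig()


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)
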