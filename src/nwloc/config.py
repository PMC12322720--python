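"""Run configuration: schema-validated YAML describing a reproducible run.

Every stochastic stage takes an explicit seed (no silent clock seeding);
unknown keys are rejected so that typos fail loudly.  The fully resolved
configuration is emitted alongside every run's outputs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LayoutConfig(_Strict):
    spacing_um: float = Field(0.99, gt=0)
    n_rows: int = Field(20, gt=0)
    n_cols: int = Field(20, gt=0)
    defect_fraction: float = Field(0.15, ge=0, le=1)
    jitter_sd_um: float = Field(0.02, ge=0)
    wire_length_um: float = Field(2.5, gt=0)
    missing_fraction_of_defects: float = Field(0.5, ge=0, le=1)
    max_kink_frac: float = Field(0.3, gt=0, le=1)


class MoleculesConfig(_Strict):
    surface_density_per_um2: float = Field(1.22, ge=0)
    capture_bias: float = Field(1.0, ge=0)
    kinked_binding: str = Field("background", pattern="^(background|substrate|exclude)$")


class OpticsConfig(_Strict):
    wavelength_em_nm: float = Field(670.0, gt=0)
    wavelength_ex_nm: float = Field(640.0, gt=0)
    na: float = Field(1.2, gt=0)
    rayleigh_range_um: float = Field(1.1, gt=0)
    background_photon_rate: float = Field(0.12, ge=0)
    enhancement_base: float = Field(2.0, gt=0)
    enhancement_tip: float = Field(18.0, gt=0)


class CameraConfig(_Strict):
    pixel_size_um: float = Field(0.1083, gt=0)
    dark_offset: float = Field(100.0, ge=0)
    read_noise: float = Field(2.0, ge=0)
    gain: float = Field(1.0, gt=0)
    exposure_ms: float = Field(100.0, gt=0)
    base_photon_rate: float = Field(4.5, gt=0)


class SimulatorConfig(_Strict):
    layout: LayoutConfig = LayoutConfig()
    molecules: MoleculesConfig = MoleculesConfig()
    optics: OpticsConfig = OpticsConfig()
    camera: CameraConfig = CameraConfig()
    seed: int = 0
    brightfield_contrast: float = Field(-0.3, ge=-1, le=1)


class PipelineStageConfig(_Strict):
    fusion: bool = True
    fusion_strength: float = Field(0.9, ge=0, le=1)
    postprocess: bool = True
    one_per_wire: bool = True
    r_max_um: float | None = Field(None, gt=0)
    n_levels: int = Field(3, ge=1)
    detection_plane: int = Field(2, ge=1)
    k_sigma: float = Field(3.0, ge=0)
    min_separation_px: float = Field(3.0, ge=0)
    gradient_threshold: float = Field(1.0, ge=0)
    fit_window_px: int = Field(7, ge=3)


class QuantifyConfig(_Strict):
    i_dc_policy: str = Field("blank_median", pattern="^(blank_median|frame_mode|camera)$")
    window_px: int = Field(3, ge=1)
    threshold_k: float = Field(3.0, ge=0)


class EvaluateConfig(_Strict):
    d_max_um: float | None = Field(None, gt=0)
    n_seeds: int = Field(20, ge=1)


class RunConfig(_Strict):
    simulator: SimulatorConfig = SimulatorConfig()
    pipeline: PipelineStageConfig = PipelineStageConfig()
    quantify: QuantifyConfig = QuantifyConfig()
    evaluate: EvaluateConfig = EvaluateConfig()
    output_dir: str = "nwloc_out"


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; ``None`` gives the defaults."""
    if path is None:
        return RunConfig()
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(payload)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Emit the fully resolved configuration."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
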