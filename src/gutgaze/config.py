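"""Run configuration: one YAML file driving every pipeline stage.

Every stochastic stage has an explicit seed; unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SeedsConfig(_Strict):
    global_seed: int = 0
    phantom: int | None = None
    recording: int | None = None
    augmentation: int | None = None
    training: int | None = None

    def for_stage(self, stage: str) -> int:
        value = getattr(self, stage)
        return self.global_seed if value is None else value


class PhantomConfig(_Strict):
    n_tubes: int = 3
    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 15.0
    diameter_range: tuple[float, float] = (10.0, 60.0)


class NoiseConfig(_Strict):
    jitter_sd: float = 1.0
    diameter_error_sd: float = 1.0
    knob_step: float = 1.0
    raw_rate: float = 60.0
    dwell: float = 0.75
    step_along_centerline: float = 7.0 / 45.0


class PreprocessingConfig(_Strict):
    window_hu: float = 400.0
    level_hu: float = 40.0
    target_2d: tuple[int, int] = (256, 256)
    target_3d: tuple[int, int, int] = (128, 128, 64)
    foreground_weight: float = 10.0
    n_augment: int = 0  # extra augmented copies per sample


class ModelConfig(_Strict):
    dims: int = 2
    input_shape: tuple[int, ...] | None = None
    base_channels: int | None = None
    n_levels: int | None = None
    dropout: float = 0.1
    epochs: int = 100
    lr: float = 1e-3
    val_fraction: float = 0.1
    lam: float | str = 0.01
    batch_size: int = 4


class ComparisonConfig(_Strict):
    parts: tuple[int, ...] = (1, 2, 3)
    exclusion_rule: str = "both_empty"
    search_radius: float = 5.0
    caliper_mode: str = "mean"


class RunConfig(_Strict):
    seeds: SeedsConfig = Field(default_factory=SeedsConfig)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    preprocessing: PreprocessingConfig = Field(default_factory=PreprocessingConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    comparison: ComparisonConfig = Field(default_factory=ComparisonConfig)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML; a missing path gives the defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)
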