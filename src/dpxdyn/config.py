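"""YAML-driven analysis configuration.

A minimal file needs only ``seed``; everything else defaults to the standard
study conditions (alpha 0.01, B = 2000 bootstrap resamples, 5 CV folds,
two blocks of 129 pairs at 90/13/13/13). Unknown keys are rejected and all
schema violations are reported together.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class ConfigError(ValueError):
    """Raised on schema violations; message lists every problem found."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BlockConfig(_Model):
    n_AX: int = 90
    n_AY: int = 13
    n_BX: int = 13
    n_BY: int = 13
    n_blocks: int = 2
    soa: float = 2.5
    iti_range: tuple[float, float] = (2.5, 3.5)


class ComponentConfig(_Model):
    name: str
    centers: list[str]
    sigma: float = 0.35
    window: tuple[float, float]
    kernel: str = "bump"
    amplitude_by_pair: dict[str, float]
    jitter_sd: float = 0.0


class NoiseConfig(_Model):
    background_sd: float = 5.0
    spectral_exponent: float = 1.5
    spatial_corr_length: float = 1.0
    sensor_white_sd: float = 1.5
    lowpass: float | None = 30.0


class BehaviourConfig(_Model):
    rt_mean_correct: dict[str, float] = Field(
        default_factory=lambda: {"AX": 0.351, "AY": 0.491, "BX": 0.273, "BY": 0.278}
    )
    rt_mean_incorrect: dict[str, float] = Field(
        default_factory=lambda: {"AX": 0.534, "AY": 0.385, "BX": 0.592, "BY": 0.608}
    )
    rt_sigma: float = 0.2
    error_prob_by_pair: dict[str, float] = Field(
        default_factory=lambda: {"AX": 0.02, "AY": 0.17, "BX": 0.04, "BY": 0.03}
    )
    subject_sd_rt: float = 0.025
    subject_sd_error: float = 0.35


class AnalysisConfig(_Model):
    seed: int
    alpha: float = 0.01
    B: int = 2000
    n_folds: int = 5
    n_subjects: int = 24
    sfreq: float = 128.0
    subject_amp_sd: float = 0.55
    rt_exclusion: tuple[float, float] = (0.1, 1.0)
    cue_window: tuple[float, float] = (-0.5, 2.5)
    probe_window: tuple[float, float] = (-0.5, 1.0)
    decode_window: tuple[float, float] = (-0.5, 3.5)
    decode_decim: int = 4
    contrasts: list[str] = Field(
        default_factory=lambda: ["cue: B vs A", "probe: AY vs AX"]
    )
    decode_contrasts: list[str] = Field(
        default_factory=lambda: ["AX vs BX", "AX vs AY"]
    )
    block: BlockConfig = Field(default_factory=BlockConfig)
    components: list[ComponentConfig] | None = None  # None -> built-in defaults
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    behaviour: BehaviourConfig = Field(default_factory=BehaviourConfig)
    out_dir: str = "dpxdyn_out"

    @field_validator("alpha")
    @classmethod
    def _alpha_open_unit(cls, v):
        if not 0.0 < v < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        return v

    @field_validator("B")
    @classmethod
    def _b_min(cls, v):
        if v < 100:
            raise ValueError("B must be >= 100")
        return v

    @field_validator("n_folds")
    @classmethod
    def _folds_min(cls, v):
        if v < 2:
            raise ValueError("n_folds must be >= 2")
        return v

    @field_validator("n_subjects")
    @classmethod
    def _subjects_min(cls, v):
        if v < 1:
            raise ValueError("n_subjects must be >= 1")
        return v

    @field_validator("decode_decim")
    @classmethod
    def _decim_min(cls, v):
        if v < 1:
            raise ValueError("decode_decim must be >= 1")
        return v


def validate_config(path) -> AnalysisConfig:
    """Load, default, and validate a YAML config file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    try:
        return AnalysisConfig(**raw)
    except Exception as e:  # pydantic collects all violations itself
        raise ConfigError(str(e)) from e


def dump_config(config: AnalysisConfig, path) -> None:
    """Write the fully defaulted effective config back to YAML."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
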