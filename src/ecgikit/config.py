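"""Pipeline configuration schema (validated; unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import InvalidParameterError

SCHEMA_VERSION = "1"


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rows: int = 8
    cols: int = 16
    spacing_mm: float = 25.0


class QCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    flat_sd_mv: float = 1e-3
    artifact_sd_mv: float = 3.0
    clip_fraction: float = 0.01
    amplitude_floor_mv: float = 0.05


class MarkerWindowConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    qrs_threshold: float = 0.15
    qrs_pad_ms: float = 8.0
    t_gap_ms: float = 30.0
    t_span_ms: float = 450.0


class PipelineConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    model_config = ConfigDict(extra="forbid")

    fs: float = 2400.0
    grid: GridConfig = Field(default_factory=GridConfig)
    kernel_kind: str = "monopole"
    lambda_rule: str = "creso"
    lambda_fixed: float | None = None
    reject_fraction: float = 0.1
    qc: QCConfig = Field(default_factory=QCConfig)
    marker_windows: MarkerWindowConfig = Field(default_factory=MarkerWindowConfig)
    seed: int = 0
    output_dir: str = "ecgikit_out"
    schema_version: str = SCHEMA_VERSION

    @field_validator("fs")
    @classmethod
    def _fs(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("fs must be positive")
        return v

    @field_validator("reject_fraction")
    @classmethod
    def _reject(cls, v: float) -> float:
        if not 0.0 <= v < 1.0:
            raise ValueError("reject_fraction must be in [0, 1)")
        return v

    @field_validator("kernel_kind")
    @classmethod
    def _kernel(cls, v: str) -> str:
        if v not in ("monopole", "bem", "custom"):
            raise ValueError(f"unknown kernel_kind {v!r}")
        return v

    @field_validator("lambda_rule")
    @classmethod
    def _rule(cls, v: str) -> str:
        if v not in ("creso", "lcurve", "fixed"):
            raise ValueError(f"unknown lambda_rule {v!r}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        from .io import read_yaml

        try:
            return cls(**read_yaml(path))
        except Exception as e:  # pydantic ValidationError or ParseError
            raise InvalidParameterError(f"invalid config {path}: {e}") from e
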