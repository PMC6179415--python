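"""Validated pipeline configuration.

A single schema covers the instrument (channel table, TCSPC binning),
the protocol timings, and the per-stage options. Unknown keys are
rejected so typos fail loudly; every field has a default matching the
instrument and protocol described in the package docs (20 MHz / 50 ns
period, 1024 bins, 180/450/900 s phases, 5 s sampling).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["PipelineConfig", "validate_config", "load_config", "default_config"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChannelEntry(_StrictModel):
    excitation_nm: float = Field(gt=0)
    emission_center_nm: float = Field(gt=0)
    emission_halfwidth_nm: float = Field(gt=0)


def _default_channels() -> dict[str, ChannelEntry]:
    return {
        "CH1": ChannelEntry(excitation_nm=372, emission_center_nm=410, emission_halfwidth_nm=10),
        "CH2": ChannelEntry(excitation_nm=372, emission_center_nm=455, emission_halfwidth_nm=25),
        "CH3": ChannelEntry(excitation_nm=372, emission_center_nm=525, emission_halfwidth_nm=25),
        "CH4": ChannelEntry(excitation_nm=438, emission_center_nm=525, emission_halfwidth_nm=25),
    }


class ProtocolTiming(_StrictModel):
    baseline_s: float = Field(default=180.0, gt=0)
    insult_s: float = Field(default=450.0, gt=0)
    reperfusion_s: float = Field(default=900.0, gt=0)
    interval_s: float = Field(default=5.0, gt=0)
    baseline_norm_window_s: float = Field(default=60.0, gt=0)

    @property
    def boundaries(self) -> tuple[float, float]:
        return (self.baseline_s, self.baseline_s + self.insult_s)

    @property
    def duration(self) -> float:
        return self.baseline_s + self.insult_s + self.reperfusion_s


class FitSettings(_StrictModel):
    n_bins: int = Field(default=1024, gt=0)
    period_ns: float = Field(default=50.0, gt=0)
    min_total_counts: int = Field(default=1000, ge=0)
    tau_min_ns: float = Field(default=0.01, gt=0)
    tau_max_ns: float = Field(default=20.0, gt=0)
    background: float = Field(default=0.0, ge=0)
    afterpulse: float = Field(default=0.0, ge=0)
    fit_background: bool = False
    fit_afterpulse: bool = False
    zero_policy: str = "clamp"

    @model_validator(mode="after")
    def _check(self) -> "FitSettings":
        if self.tau_min_ns >= self.tau_max_ns:
            raise ValueError("tau_min_ns must be below tau_max_ns")
        if self.zero_policy not in ("clamp", "exclude"):
            raise ValueError("zero_policy must be 'clamp' or 'exclude'")
        return self


class ReflectanceSettings(_StrictModel):
    sign_convention: str = "standard"
    smooth_window_nm: float | None = None
    oxygenation_wavelengths_nm: tuple[float, float] = (578.0, 600.0)
    cytochrome_wavelengths_nm: tuple[float, float] = (502.0, 550.0)

    @model_validator(mode="after")
    def _check(self) -> "ReflectanceSettings":
        if self.sign_convention not in ("standard", "as_printed"):
            raise ValueError("sign_convention must be 'standard' or 'as_printed'")
        return self


class PipelineConfig(_StrictModel):
    channels: dict[str, ChannelEntry] = Field(default_factory=_default_channels)
    protocol: ProtocolTiming = Field(default_factory=ProtocolTiming)
    fit: FitSettings = Field(default_factory=FitSettings)
    reflectance: ReflectanceSettings = Field(default_factory=ReflectanceSettings)
    seed: int = 0
    outdir: str = "results"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        for name in ("CH1", "CH2", "CH3", "CH4"):
            if name not in self.channels:
                raise ValueError(f"channel table must define {name}")
        return self


def validate_config(raw: dict | None) -> PipelineConfig:
    """Build a fully-defaulted, schema-valid configuration from a mapping.

    Raises pydantic's ``ValidationError`` carrying every violation found
    (unknown keys, out-of-range values) in one report.
    """
    return PipelineConfig.model_validate(raw or {})


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML configuration file (None -> all defaults)."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    return validate_config(raw)


def default_config() -> dict:
    """Full default configuration as a plain mapping (for `config --show-defaults`)."""
    return PipelineConfig().model_dump()
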