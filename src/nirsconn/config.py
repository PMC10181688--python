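"""Run configuration: a validated schema for the end-to-end pipeline.

A flat YAML file (or keyword overrides) is validated before any computation
starts, so a bad alpha or filter band fails fast with a schema error rather
than mid-pipeline.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .cdvar import DEFAULT_CONDITIONS

__all__ = ["FilterConfig", "MbllConfig", "SimulateConfig", "RunConfig", "load_config"]


class FilterConfig(BaseModel):
    order: int = Field(71, ge=1)
    band_hz: tuple[float, float] = (0.010, 0.400)
    zero_phase: bool = True

    @field_validator("band_hz")
    @classmethod
    def _band_ok(cls, v):
        low, high = v
        if not (0 < low < high):
            raise ValueError(f"need 0 < low < high, got {v}")
        return v


class MbllConfig(BaseModel):
    dpf: float = Field(6.0, gt=0)
    #: wavelength -> (eps_HbO, eps_HbR) in 1/(mM*cm); None = built-in table
    extinction_table: dict[float, tuple[float, float]] | None = None


class SimulateConfig(BaseModel):
    sparsity: float = Field(0.2, ge=0, le=1)
    effect_size: float = Field(0.4, gt=0)
    channels_per_cluster: int = Field(5, ge=1)
    channel_noise_sd: float = Field(0.1, ge=0)
    outlier_channels: int = Field(0, ge=0)
    outlier_offset: float = 0.0
    envelope: str = "boxcar"
    trials: int = Field(4, ge=1)
    task_s: float = Field(22.0, gt=0)
    inter_rest_s: float = Field(10.0, gt=0)
    initial_rest_s: float = Field(17.0, gt=0)
    fs: float = Field(10.2, gt=0)

    @field_validator("envelope")
    @classmethod
    def _env_ok(cls, v):
        if v not in ("boxcar", "hrf"):
            raise ValueError("envelope must be 'boxcar' or 'hrf'")
        return v


class RunConfig(BaseModel):
    """Everything the pipeline needs; every default is logged at run time."""

    out_dir: str = "nirsconn-out"
    seed: int = 0
    simulate: bool = True
    inputs: list[str] = Field(default_factory=list)
    conditions: list[str] = Field(default_factory=lambda: list(DEFAULT_CONDITIONS))
    clusters: int = Field(6, ge=1)
    order: int = Field(1, ge=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    correction: str = "none"
    per_trial: bool = False
    include_rest: bool = False
    filter_domain: str = "hb"  # filter hemoglobin ('hb') or optical density ('od')
    projection: str = "median"
    filter: FilterConfig = Field(default_factory=FilterConfig)
    mbll: MbllConfig = Field(default_factory=MbllConfig)
    sim: SimulateConfig = Field(default_factory=SimulateConfig)

    @field_validator("correction")
    @classmethod
    def _corr_ok(cls, v):
        if v not in ("none", "bh"):
            raise ValueError("correction must be 'none' or 'bh'")
        return v

    @field_validator("projection")
    @classmethod
    def _proj_ok(cls, v):
        if v not in ("median", "mean"):
            raise ValueError("projection must be 'median' or 'mean'")
        return v

    @field_validator("filter_domain")
    @classmethod
    def _dom_ok(cls, v):
        if v not in ("hb", "od"):
            raise ValueError("filter_domain must be 'hb' or 'od'")
        return v

    @field_validator("conditions")
    @classmethod
    def _conds_ok(cls, v):
        if len(v) < 1:
            raise ValueError("need at least one (baseline) condition")
        if len(set(v)) != len(v):
            raise ValueError("condition names must be unique")
        return v


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML config file (optional) and apply keyword overrides."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
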