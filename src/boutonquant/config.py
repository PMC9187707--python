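"""Validated run configuration (unknown keys rejected)."""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator


class DeconvConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    skip: bool = False
    iterations: int = Field(default=10, ge=0)
    psf_sigma_um: tuple[float, float] = (0.2, 0.5)


class PreprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sigma_small: float = Field(default=0.7, gt=0)
    sigma_large: float = Field(default=2.0, gt=0)
    dog_mode: str = "2d"
    deconv: DeconvConfig = Field(default_factory=DeconvConfig)

    @model_validator(mode="after")
    def _order(self):
        if not self.sigma_small < self.sigma_large:
            raise ValueError("sigma_small must be < sigma_large")
        return self


class SegmentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    step_adu: float = Field(default=50.0, gt=0)
    vmin_um3: float = Field(default=0.03, gt=0)
    vmax_um3: float = Field(default=2.0, gt=0)
    connectivity: int = 26
    bins: int = Field(default=256, ge=2)


class QuantifyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    depth_lo_um: float = Field(default=2.0, ge=0)
    depth_hi_um: float = Field(default=4.0, gt=0)
    edge_fraction: float = Field(default=0.02, gt=0, lt=0.5)
    lipofuscin_exclusion: bool = True


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    df_method: str = "residual"
    with_satterthwaite: bool = True


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reference_exposure_ms: float = Field(default=100.0, gt=0)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    segment: SegmentConfig = Field(default_factory=SegmentConfig)
    quantify: QuantifyConfig = Field(default_factory=QuantifyConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
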