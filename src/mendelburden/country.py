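"""Per-country demographic and policy inputs."""

from __future__ import annotations

import enum

from pydantic import BaseModel, Field, model_validator


class WHORegion(str, enum.Enum):
    AFR = "AFR"
    AMR = "AMR"
    EMR = "EMR"
    EUR = "EUR"
    SEAR = "SEAR"
    WPR = "WPR"


class CountryDemography(BaseModel):
    """One country's inputs to the estimation pipeline.

    ``mean_F`` is the population mean coefficient of consanguinity;
    ``u5mr_per_1000`` the national under-5 mortality rate per 1000
    livebirths (converted to a percentage where the mortality adjustment
    needs it); ``access_specialist`` and ``access_optimal_care`` are
    fractions of births with access to specialist genetic services and to
    optimal clinical care respectively.  ``top_legal`` records whether
    termination of pregnancy for fetal anomaly is legal or in documented
    widespread practice.
    """

    model_config = {"frozen": True}

    iso_code: str
    who_region: WHORegion
    total_births: float = Field(gt=0)
    mean_F: float = Field(ge=0.0, le=0.125)
    tfr: float = Field(gt=0)
    u5mr_per_1000: float = Field(ge=0, lt=1000)
    access_specialist: float = Field(ge=0.0, le=1.0)
    access_optimal_care: float = Field(ge=0.0, le=1.0)
    top_legal: bool
    prospective_screening: bool

    @property
    def u5mr_percent(self) -> float:
        """U5MR as percent of livebirths dying by age five (per-1000 / 10)."""
        return self.u5mr_per_1000 / 10.0

    @model_validator(mode="after")
    def _check(self) -> "CountryDemography":
        return self
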