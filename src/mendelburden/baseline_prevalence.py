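"""Baseline (pre-intervention) birth prevalence by inheritance group.

Rare single gene disorders are carried at population-genetic equilibrium —
a balance between new mutation and loss through natural selection — so
their collective baseline prevalence can be treated as constant across
populations, except for the component driven by parental consanguinity.
That component scales linearly with the population mean coefficient of
consanguinity F: observational studies place it between 5.6 and 7.7 extra
affected births per 1000 total births per unit of consanguinity (F = 0.01),
and the midpoint 6.5 is used as the default multiplier, i.e.

    consanguinity-associated births / 1000 total births = F x 100 x 6.5.

Non-consanguinity rates per 1000 total births: dominant 1.4, X-linked
0.053, recessive 1.84, genetic type unknown 1.16.  The recessive figure is
derived from 1.66 affected livebirths per 1000 by treating stillbirths as
10% of all affected births (1.66 / 0.9 = 1.84 to 2 dp); the same
stillbirth fraction applies to the consanguinity-associated group.
Dominant, X-linked and unknown groups are reported livebirth rates used
as-is, with no stillbirth uplift.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import TYPE_CHECKING

import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .country import CountryDemography

__all__ = [
    "InheritanceGroup",
    "BaselineParameters",
    "ConsanguinityProfile",
    "GroupRates",
    "PrevalenceEstimate",
    "Stage",
    "adjust_for_stillbirths",
    "consanguinity_associated_rate",
    "percent_couples_consanguineous",
    "baseline_estimate",
]


class InheritanceGroup(str, enum.Enum):
    """The five inheritance groups disorders are aggregated into.

    ``CONSANGUINITY_ASSOCIATED`` is the increment of recessive disorders
    attributable to parental consanguinity, over and above the
    non-consanguinity recessive rate.
    """

    DOMINANT = "dominant"
    X_LINKED = "x_linked"
    RECESSIVE = "recessive"
    UNKNOWN = "unknown"
    CONSANGUINITY_ASSOCIATED = "consanguinity_associated"


class Stage(str, enum.Enum):
    BASELINE = "baseline"
    ACTUAL = "actual"


def adjust_for_stillbirths(
    livebirth_rate: float, stillbirth_fraction: float
) -> float:
    """Total (live + still) birth rate from a livebirth rate.

    ``stillbirth_fraction`` is the share of all affected births that are
    stillborn, so total = livebirths / (1 - fraction).  With the default
    10% fraction, 1.66 affected livebirths per 1000 becomes 1.84 per 1000
    total births.
    """
    if not 0.0 <= stillbirth_fraction < 1.0:
        raise ValueError(
            f"stillbirth_fraction must be in [0, 1), got {stillbirth_fraction}"
        )
    if livebirth_rate < 0:
        raise ValueError("livebirth_rate must be non-negative")
    return livebirth_rate / (1.0 - stillbirth_fraction)


def consanguinity_associated_rate(
    mean_F: float, multiplier: float = 6.5
) -> float:
    """Consanguinity-associated affected births per 1000 total births.

    Linear in the population mean coefficient of consanguinity:
    rate = mean_F x 100 x multiplier.  One unit of parental consanguinity
    (F = 0.01) therefore contributes ``multiplier`` affected births per
    1000 at the default 6.5.
    """
    if mean_F < 0:
        raise ValueError(f"mean_F must be non-negative, got {mean_F}")
    return mean_F * 100.0 * multiplier


@dataclass(frozen=True)
class BaselineParameters:
    """Model parameters for baseline birth prevalence (per 1000 total births).

    ``consang_multiplier`` is the consanguinity-associated rate per unit of
    consanguinity (F = 0.01); the observational range is 5.6-7.7 with 6.5
    the midpoint default.  ``recessive_total`` must be consistent with the
    reported livebirth rate under the stillbirth adjustment.
    """

    dominant: float = 1.4
    x_linked: float = 0.053
    recessive_livebirth_reported: float = 1.66
    stillbirth_fraction_recessive: float = 0.10
    unknown: float = 1.16
    consang_multiplier: float = 6.5

    def __post_init__(self) -> None:
        for name in (
            "dominant",
            "x_linked",
            "recessive_livebirth_reported",
            "unknown",
            "consang_multiplier",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.stillbirth_fraction_recessive < 1.0:
            raise ValueError("stillbirth_fraction_recessive must be in [0, 1)")
        if not 5.6 <= self.consang_multiplier <= 7.7:
            warnings.warn(
                "consang_multiplier outside the observed range [5.6, 7.7]",
                stacklevel=2,
            )

    @property
    def recessive_total(self) -> float:
        """Recessive rate per 1000 total births after the stillbirth uplift."""
        return adjust_for_stillbirths(
            self.recessive_livebirth_reported, self.stillbirth_fraction_recessive
        )

    # -- config round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BaselineParameters":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "BaselineParameters":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls.from_dict(data)


@dataclass(frozen=True)
class ConsanguinityProfile:
    """Population consanguinity structure.

    ``mean_F`` is the population mean coefficient of consanguinity
    (reported national values range from 0.0001 in many developed countries
    to 0.0332).  The couple-class mix — two thirds of consanguineous
    couples first cousins (F = 0.0625), one third more distant relatives
    (default F = 0.03125, first cousins once removed) — converts mean_F
    into the fraction of all couples that are consanguineous.
    """

    mean_F: float
    fraction_first_cousins_among_consang: float = 2.0 / 3.0
    distant_relative_F: float = 0.03125

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_F <= 0.125:
            raise ValueError(f"mean_F must be in [0, 0.125], got {self.mean_F}")
        if not 0.0 <= self.fraction_first_cousins_among_consang <= 1.0:
            raise ValueError("fraction_first_cousins_among_consang not in [0,1]")
        if self.distant_relative_F < 0:
            raise ValueError("distant_relative_F must be non-negative")


def percent_couples_consanguineous(profile: ConsanguinityProfile) -> float:
    """Fraction of all parent couples that are consanguineous.

    mean_F divided by the mean per-couple F implied by the class mix;
    capped at 1 (with a warning) when mean_F exceeds the saturation bound.
    """
    f1c = profile.fraction_first_cousins_among_consang
    per_couple_F = f1c * 0.0625 + (1.0 - f1c) * profile.distant_relative_F
    if per_couple_F == 0:
        raise ValueError(
            "class mix implies zero per-couple F; cannot infer couple fraction"
        )
    frac = profile.mean_F / per_couple_F
    if frac > 1.0:
        warnings.warn(
            f"mean_F={profile.mean_F} exceeds the all-couples-consanguineous "
            f"bound {per_couple_F}; capping fraction at 1",
            stacklevel=2,
        )
        frac = 1.0
    return frac


@dataclass(frozen=True)
class GroupRates:
    """Rates for one inheritance group, per 1000 total births."""

    total_per_1000: float
    livebirth_per_1000: float
    stillbirth_per_1000: float

    def __post_init__(self) -> None:
        if min(
            self.total_per_1000, self.livebirth_per_1000, self.stillbirth_per_1000
        ) < 0:
            raise ValueError("rates must be non-negative")
        if abs(
            self.total_per_1000
            - (self.livebirth_per_1000 + self.stillbirth_per_1000)
        ) > 1e-9 * max(1.0, self.total_per_1000):
            raise ValueError("total must equal livebirth + stillbirth")


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Per-group birth prevalence, per 1000 total births."""

    rates: dict[InheritanceGroup, GroupRates] = field(default_factory=dict)
    stage: Stage = Stage.BASELINE

    def total(self, group: InheritanceGroup) -> float:
        return self.rates[group].total_per_1000

    def livebirth(self, group: InheritanceGroup) -> float:
        return self.rates[group].livebirth_per_1000

    def stillbirth(self, group: InheritanceGroup) -> float:
        return self.rates[group].stillbirth_per_1000

    @property
    def total_all_groups(self) -> float:
        return sum(r.total_per_1000 for r in self.rates.values())


def _split(total: float, stillbirth_fraction: float) -> GroupRates:
    still = total * stillbirth_fraction
    return GroupRates(
        total_per_1000=total,
        livebirth_per_1000=total - still,
        stillbirth_per_1000=still,
    )


def baseline_estimate(
    country: "CountryDemography",
    params: BaselineParameters | None = None,
) -> PrevalenceEstimate:
    """Baseline birth prevalence for one country, all five groups.

    Dominant, X-linked and unknown rates are livebirth rates taken as equal
    to total affected births (stillbirth component zero).  Recessive and
    consanguinity-associated groups carry the recessive stillbirth
    fraction.  The consanguinity-associated total is linear in the
    country's mean_F.
    """
    params = params or BaselineParameters()
    sbf = params.stillbirth_fraction_recessive
    consang_total = consanguinity_associated_rate(
        country.mean_F, params.consang_multiplier
    )
    rates = {
        InheritanceGroup.DOMINANT: _split(params.dominant, 0.0),
        InheritanceGroup.X_LINKED: _split(params.x_linked, 0.0),
        InheritanceGroup.RECESSIVE: _split(params.recessive_total, sbf),
        InheritanceGroup.UNKNOWN: _split(params.unknown, 0.0),
        InheritanceGroup.CONSANGUINITY_ASSOCIATED: _split(consang_total, sbf),
    }
    return PrevalenceEstimate(rates=rates, stage=Stage.BASELINE)
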