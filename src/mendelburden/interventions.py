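"""Maximum effect of genetic risk identification on birth prevalence.

Risk identification for recessive disorders can be *retrospective* (the
couple is recognised as at-risk only after the birth of an affected child)
or *prospective* (carriers detected before any affected birth, e.g. by
population carrier screening), in each case with or without access to
prenatal diagnosis (PND) and termination of pregnancy (TOP).

The ceiling on what retrospective identification can avert follows the
classical family-limitation argument: with a per-birth recurrence risk of
1/4 and the (maximal) assumption that every birth after the first affected
birth in a sibship is averted, the expected fraction of affected births
avoided is a closed-form function of sibship size — about 12.5% at sibship
size 2, rising to about 45% at size 6.  Sibship size is derived from the
national total fertility rate under the assumption that the average
at-risk couple aims for two unaffected children.

Dominant and X-linked early-onset disorders are assumed unaffected by risk
identification (minimal impact), as is the genetic-type-unknown group.
The maximum averted rate is scaled by the fraction of births with access
to specialist genetic services.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .baseline_prevalence import (
    GroupRates,
    InheritanceGroup,
    PrevalenceEstimate,
    Stage,
)

if TYPE_CHECKING:  # pragma: no cover
    from .country import CountryDemography

__all__ = [
    "PolicyGroup",
    "InterventionPolicy",
    "InterventionEffect",
    "ReductionConfig",
    "fraser_avoidable_fraction",
    "effective_sibship_size",
    "classify_policy",
    "max_averted",
    "actual_prevalence",
]

#: groups whose birth prevalence risk identification can reduce
REDUCIBLE_GROUPS = (
    InheritanceGroup.RECESSIVE,
    InheritanceGroup.CONSANGUINITY_ASSOCIATED,
)


class PolicyGroup(str, enum.Enum):
    RETROSPECTIVE_ONLY = "retrospective_only"
    RETROSPECTIVE_WITH_PND_TOP = "retrospective_with_pnd_top"
    PROSPECTIVE_ONLY = "prospective_only"
    PROSPECTIVE_WITH_PND_TOP = "prospective_with_pnd_top"


@dataclass(frozen=True)
class InterventionPolicy:
    """A country's risk-identification policy and service access."""

    policy_group: PolicyGroup
    top_legal_or_practised: bool
    access_specialist_services: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.access_specialist_services <= 1.0:
            raise ValueError("access_specialist_services must be in [0, 1]")
        needs_top = self.policy_group in (
            PolicyGroup.RETROSPECTIVE_WITH_PND_TOP,
            PolicyGroup.PROSPECTIVE_WITH_PND_TOP,
        )
        if needs_top and not self.top_legal_or_practised:
            raise ValueError(
                f"{self.policy_group.value} requires TOP to be legal or "
                "in documented practice"
            )


@dataclass(frozen=True)
class InterventionEffect:
    """Maximum averted births per 1000 total births, by group."""

    policy_group: PolicyGroup
    fraser_fraction: float
    max_averted_per_1000: dict[InheritanceGroup, float]


@dataclass(frozen=True)
class ReductionConfig:
    """Reduction factors applied per policy group.

    ``prospective_factor`` defaults to 0.90: surveillance of existing
    carrier-screening programmes shows prospective screening with PND can
    produce an over-90% fall in affected birth prevalence.
    ``retrospective_no_top_factor`` and ``prospective_no_top_factor``
    default to 0: without PND+TOP the model attributes no birth-prevalence
    reduction to counselling alone (most at-risk couples with fewer than
    two healthy children continue reproducing); both knobs are exposed
    because pure family limitation is a defensible nonzero alternative.
    """

    prospective_factor: float = 0.90
    retrospective_no_top_factor: float = 0.0
    prospective_no_top_factor: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "prospective_factor",
            "retrospective_no_top_factor",
            "prospective_no_top_factor",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def fraser_avoidable_fraction(sibship_size: int) -> float:
    """Maximum fraction of affected births averted by family limitation.

    Per-birth recurrence risk 1/4; every birth after the first affected
    birth in a sibship of size s is averted.  The expected number of
    affected births among births 2..s that follow an earlier affected
    birth, divided by the expected total affected births s/4:

        f(s) = [ sum_{i=2..s} (1 - (3/4)^(i-1)) * 1/4 ] / (s / 4)

    Strictly increasing for s >= 2 (f(1) = 0, f(2) = 0.125,
    f(6) = 0.452...) and -> 1 as s -> infinity.
    """
    if sibship_size < 1:
        raise ValueError(f"sibship_size must be >= 1, got {sibship_size}")
    s = int(sibship_size)
    averted = sum((1.0 - 0.75 ** (i - 1)) * 0.25 for i in range(2, s + 1))
    return averted / (s / 4.0)


def effective_sibship_size(tfr: float) -> int:
    """Sibship size used in the Fraser model, from the total fertility rate.

    The average at-risk couple is assumed to aim for two unaffected
    children, so the size is the TFR rounded to the nearest integer with a
    floor of 2.
    """
    if tfr <= 0:
        raise ValueError(f"tfr must be positive, got {tfr}")
    return max(2, round(tfr))


def classify_policy(country: "CountryDemography") -> InterventionPolicy:
    """Allocate a country to one of the four policy groups.

    For rare disorders the default mode of risk identification is
    retrospective in all settings; a country is placed in a prospective
    group only when it runs a carrier-screening programme.  PND+TOP
    variants require TOP for fetal anomaly to be legal or in documented
    widespread practice.
    """
    if country.prospective_screening:
        group = (
            PolicyGroup.PROSPECTIVE_WITH_PND_TOP
            if country.top_legal
            else PolicyGroup.PROSPECTIVE_ONLY
        )
    else:
        group = (
            PolicyGroup.RETROSPECTIVE_WITH_PND_TOP
            if country.top_legal
            else PolicyGroup.RETROSPECTIVE_ONLY
        )
    return InterventionPolicy(
        policy_group=group,
        top_legal_or_practised=country.top_legal,
        access_specialist_services=country.access_specialist,
    )


def _reduction_factor(
    policy_group: PolicyGroup, fraser: float, config: ReductionConfig
) -> float:
    if policy_group is PolicyGroup.RETROSPECTIVE_WITH_PND_TOP:
        return fraser
    if policy_group is PolicyGroup.PROSPECTIVE_WITH_PND_TOP:
        return config.prospective_factor
    if policy_group is PolicyGroup.RETROSPECTIVE_ONLY:
        return config.retrospective_no_top_factor
    return config.prospective_no_top_factor


def max_averted(
    baseline: PrevalenceEstimate,
    policy: InterventionPolicy,
    tfr: float,
    config: ReductionConfig | None = None,
) -> InterventionEffect:
    """Maximum births averted per 1000, given baseline prevalence and policy.

    For the recessive and consanguinity-associated groups:
    averted = baseline_total x reduction_factor(policy) x access, where the
    reduction factor is the Fraser fraction (at the TFR-derived sibship
    size) for retrospective identification with PND+TOP and the configured
    prospective factor for prospective screening with PND+TOP.  Dominant,
    X-linked and unknown groups are never reduced.
    """
    if baseline.stage is not Stage.BASELINE:
        raise ValueError("max_averted requires a baseline-stage estimate")
    config = config or ReductionConfig()
    fraser = fraser_avoidable_fraction(effective_sibship_size(tfr))
    factor = _reduction_factor(policy.policy_group, fraser, config)
    access = policy.access_specialist_services
    averted = {g: 0.0 for g in InheritanceGroup}
    for g in REDUCIBLE_GROUPS:
        averted[g] = baseline.total(g) * factor * access
    return InterventionEffect(
        policy_group=policy.policy_group,
        fraser_fraction=fraser,
        max_averted_per_1000=averted,
    )


def actual_prevalence(
    baseline: PrevalenceEstimate, effect: InterventionEffect
) -> PrevalenceEstimate:
    """Actual prevalence: baseline minus maximum averted, per group.

    The live/stillbirth split of each group is preserved proportionally.
    """
    rates: dict[InheritanceGroup, GroupRates] = {}
    for g, base in baseline.rates.items():
        averted = effect.max_averted_per_1000.get(g, 0.0)
        if averted > base.total_per_1000 * (1 + 1e-12):
            raise ValueError(
                f"averted rate {averted} exceeds baseline "
                f"{base.total_per_1000} for group {g.value}"
            )
        if base.total_per_1000 > 0:
            scale = (base.total_per_1000 - averted) / base.total_per_1000
        else:
            scale = 1.0
        rates[g] = GroupRates(
            total_per_1000=base.total_per_1000 * scale,
            livebirth_per_1000=base.livebirth_per_1000 * scale,
            stillbirth_per_1000=base.stillbirth_per_1000 * scale,
        )
    return PrevalenceEstimate(rates=rates, stage=Stage.ACTUAL)
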