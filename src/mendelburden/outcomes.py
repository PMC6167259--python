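"""Child mortality and disability outcomes from actual affected livebirths.

Case fatality rates (CFR, cumulative % of affected livebirths dying by the
neonatal period, infancy, and age five) are specified at two care levels,
"no care" and "optimal care"; a country's effective CFR is the linear
blend at its fraction of births with access to optimal care.  Robust
follow-up data exist only for consanguinity-associated recessive disorders
(early mortality 80-90% without care, 28% with optimal care) and these are
taken as representative of recessive disorders generally; dominant
disorders are assumed more severe and X-linked less severe, with the
genetic-type-unknown group conservatively given X-linked mortality.
Neonatal CFRs for the dominant, X-linked and unknown groups are estimated
at 60% of the corresponding infant CFR.

Deaths are adjusted for background mortality by subtracting the share that
would have died anyway:

    adjusted deaths = total deaths x (1 - U5MR/100)

where U5MR enters as a percentage of livebirths (national per-1000 figures
are divided by 10 on ingestion).  CFRs are cumulative, so neonatal deaths
are a subset of infant deaths and infant of under-5.  Because no rare
single gene disorder is currently curable, every affected survivor is
assumed to live with some degree of disability:
survivors = affected livebirths - adjusted under-5 deaths.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import yaml

from .baseline_prevalence import InheritanceGroup, PrevalenceEstimate, Stage

if TYPE_CHECKING:  # pragma: no cover
    from .country import CountryDemography

__all__ = [
    "CareLevel",
    "Timepoint",
    "CaseFatalityTable",
    "OutcomeEstimate",
    "GroupOutcome",
    "neonatal_from_infant",
    "blended_cfr",
    "deaths",
    "adjust_for_background_mortality",
    "outcome_estimate",
]


class CareLevel(str, enum.Enum):
    NO_CARE = "no_care"
    OPTIMAL_CARE = "optimal_care"


class Timepoint(str, enum.Enum):
    NEONATAL = "neonatal"
    INFANT = "infant"
    UNDER5 = "under5"


def neonatal_from_infant(infant_cfr: float) -> float:
    """Neonatal CFR estimated as 60% of the infant CFR (percent)."""
    if not 0.0 <= infant_cfr <= 100.0:
        raise ValueError(f"infant_cfr must be in [0, 100], got {infant_cfr}")
    return 0.6 * infant_cfr


# infant and under-5 CFRs (% of affected livebirths); neonatal rates for
# recessive and consanguinity-associated groups are observed, the rest are
# derived as 60% of infant.
_OBSERVED_NEONATAL = {
    (InheritanceGroup.RECESSIVE, CareLevel.NO_CARE): 19.0,
    (InheritanceGroup.RECESSIVE, CareLevel.OPTIMAL_CARE): 11.0,
    (InheritanceGroup.CONSANGUINITY_ASSOCIATED, CareLevel.NO_CARE): 19.0,
    (InheritanceGroup.CONSANGUINITY_ASSOCIATED, CareLevel.OPTIMAL_CARE): 11.0,
}

_INFANT = {
    (InheritanceGroup.DOMINANT, CareLevel.NO_CARE): 60.0,
    (InheritanceGroup.DOMINANT, CareLevel.OPTIMAL_CARE): 34.0,
    (InheritanceGroup.X_LINKED, CareLevel.NO_CARE): 35.0,
    (InheritanceGroup.X_LINKED, CareLevel.OPTIMAL_CARE): 20.0,
    (InheritanceGroup.RECESSIVE, CareLevel.NO_CARE): 39.0,
    (InheritanceGroup.RECESSIVE, CareLevel.OPTIMAL_CARE): 14.0,
    (InheritanceGroup.UNKNOWN, CareLevel.NO_CARE): 35.0,
    (InheritanceGroup.UNKNOWN, CareLevel.OPTIMAL_CARE): 20.0,
    (InheritanceGroup.CONSANGUINITY_ASSOCIATED, CareLevel.NO_CARE): 39.0,
    (InheritanceGroup.CONSANGUINITY_ASSOCIATED, CareLevel.OPTIMAL_CARE): 14.0,
}

_UNDER5 = {
    (InheritanceGroup.DOMINANT, CareLevel.NO_CARE): 100.0,
    (InheritanceGroup.DOMINANT, CareLevel.OPTIMAL_CARE): 50.0,
    (InheritanceGroup.X_LINKED, CareLevel.NO_CARE): 40.0,
    (InheritanceGroup.X_LINKED, CareLevel.OPTIMAL_CARE): 25.0,
    (InheritanceGroup.RECESSIVE, CareLevel.NO_CARE): 84.0,
    (InheritanceGroup.RECESSIVE, CareLevel.OPTIMAL_CARE): 28.0,
    (InheritanceGroup.UNKNOWN, CareLevel.NO_CARE): 40.0,
    (InheritanceGroup.UNKNOWN, CareLevel.OPTIMAL_CARE): 25.0,
    (InheritanceGroup.CONSANGUINITY_ASSOCIATED, CareLevel.NO_CARE): 84.0,
    (InheritanceGroup.CONSANGUINITY_ASSOCIATED, CareLevel.OPTIMAL_CARE): 28.0,
}


def _default_cells() -> dict[tuple[InheritanceGroup, CareLevel, Timepoint], float]:
    cells: dict[tuple[InheritanceGroup, CareLevel, Timepoint], float] = {}
    for (g, c), v in _INFANT.items():
        cells[(g, c, Timepoint.INFANT)] = v
        cells[(g, c, Timepoint.NEONATAL)] = _OBSERVED_NEONATAL.get(
            (g, c), neonatal_from_infant(v)
        )
    for (g, c), v in _UNDER5.items():
        cells[(g, c, Timepoint.UNDER5)] = v
    return cells


@dataclass(frozen=True)
class CaseFatalityTable:
    """CFR (% of affected livebirths) per group x care level x timepoint.

    Cells must be cumulative in the timepoint (neonatal <= infant <=
    under-5) and optimal care can never exceed no care.
    """

    cells: dict[tuple[InheritanceGroup, CareLevel, Timepoint], float] = field(
        default_factory=_default_cells
    )

    def __post_init__(self) -> None:
        for g in InheritanceGroup:
            for c in CareLevel:
                neo = self.cells[(g, c, Timepoint.NEONATAL)]
                inf = self.cells[(g, c, Timepoint.INFANT)]
                u5 = self.cells[(g, c, Timepoint.UNDER5)]
                if not (0.0 <= neo <= inf <= u5 <= 100.0):
                    raise ValueError(
                        f"CFRs for {g.value}/{c.value} must satisfy "
                        f"0 <= neonatal <= infant <= under5 <= 100; got "
                        f"{neo}, {inf}, {u5}"
                    )
            for t in Timepoint:
                if (
                    self.cells[(g, CareLevel.OPTIMAL_CARE, t)]
                    > self.cells[(g, CareLevel.NO_CARE, t)]
                ):
                    raise ValueError(
                        f"optimal-care CFR exceeds no-care for "
                        f"{g.value}/{t.value}"
                    )

    def cfr(self, group: InheritanceGroup, care: CareLevel, t: Timepoint) -> float:
        return self.cells[(group, care, t)]

    # -- config round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        out: dict = {}
        for g in InheritanceGroup:
            out[g.value] = {
                c.value: {
                    t.value: self.cells[(g, c, t)] for t in Timepoint
                }
                for c in CareLevel
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "CaseFatalityTable":
        cells = {
            (InheritanceGroup(g), CareLevel(c), Timepoint(t)): float(v)
            for g, by_care in d.items()
            for c, by_tp in by_care.items()
            for t, v in by_tp.items()
        }
        return cls(cells=cells)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "CaseFatalityTable":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls.from_dict(data)


def blended_cfr(
    group: InheritanceGroup,
    timepoint: Timepoint,
    access_optimal_care: float,
    table: CaseFatalityTable | None = None,
) -> float:
    """CFR interpolated linearly between the no-care and optimal-care levels."""
    if not 0.0 <= access_optimal_care <= 1.0:
        raise ValueError("access_optimal_care must be in [0, 1]")
    table = table or CaseFatalityTable()
    return access_optimal_care * table.cfr(
        group, CareLevel.OPTIMAL_CARE, timepoint
    ) + (1.0 - access_optimal_care) * table.cfr(
        group, CareLevel.NO_CARE, timepoint
    )


def deaths(affected_livebirths: float, cfr: float) -> float:
    """Deaths = affected livebirths x CFR/100 (real-valued; round at report)."""
    if affected_livebirths < 0 or cfr < 0:
        raise ValueError("inputs must be non-negative")
    return affected_livebirths * cfr / 100.0


def adjust_for_background_mortality(
    total_deaths: float, u5mr_percent: float
) -> float:
    """Remove the background-mortality share of condition-attributed deaths.

    adjusted = total - total/100 x U5MR, with U5MR as a percentage of
    livebirths, i.e. multiplicative shrinkage by (1 - U5MR/100).
    """
    if not 0.0 <= u5mr_percent < 100.0:
        raise ValueError(
            f"u5mr_percent must be in [0, 100), got {u5mr_percent}"
        )
    return total_deaths * (1.0 - u5mr_percent / 100.0)


@dataclass(frozen=True)
class GroupOutcome:
    """Annual outcome counts for one inheritance group."""

    affected_livebirths: float
    deaths_raw: dict[Timepoint, float]
    deaths_adjusted: dict[Timepoint, float]
    survivors_with_disability: float


@dataclass(frozen=True)
class OutcomeEstimate:
    """Per-group child mortality and disability outcome counts."""

    outcomes: dict[InheritanceGroup, GroupOutcome]

    def total_adjusted_deaths(self, t: Timepoint) -> float:
        return sum(o.deaths_adjusted[t] for o in self.outcomes.values())

    @property
    def total_survivors_with_disability(self) -> float:
        return sum(
            o.survivors_with_disability for o in self.outcomes.values()
        )


def outcome_estimate(
    actual: PrevalenceEstimate,
    country: "CountryDemography",
    table: CaseFatalityTable | None = None,
) -> OutcomeEstimate:
    """Convert actual per-1000 livebirth rates into annual outcome counts.

    Per group: affected livebirths = livebirth rate x births/1000; deaths
    at each timepoint from the care-blended CFR; each then adjusted for
    background mortality; disabled survivors are the affected livebirths
    surviving to age five.
    """
    if actual.stage is not Stage.ACTUAL:
        raise ValueError("outcome_estimate requires an actual-stage estimate")
    if country.total_births <= 0:
        raise ValueError("total_births must be positive")
    table = table or CaseFatalityTable()
    out: dict[InheritanceGroup, GroupOutcome] = {}
    for g in actual.rates:
        lb = actual.livebirth(g) * country.total_births / 1000.0
        raw = {
            t: deaths(lb, blended_cfr(g, t, country.access_optimal_care, table))
            for t in Timepoint
        }
        adj = {
            t: adjust_for_background_mortality(v, country.u5mr_percent)
            for t, v in raw.items()
        }
        out[g] = GroupOutcome(
            affected_livebirths=lb,
            deaths_raw=raw,
            deaths_adjusted=adj,
            survivors_with_disability=lb - adj[Timepoint.UNDER5],
        )
    return OutcomeEstimate(outcomes=out)
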