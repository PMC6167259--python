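"""End-to-end driver: country table in, per-country and regional results out.

Per country the three estimation steps run in sequence — baseline
prevalence, maximum intervention effect and actual prevalence, then child
outcomes — and results are aggregated to WHO regions.  Regional per-1000
rates are birth-weighted means of member-country rates (births being the
natural denominator of a per-1000-births rate); counts are plain sums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pydantic import ValidationError

from .baseline_prevalence import (
    BaselineParameters,
    InheritanceGroup,
    PrevalenceEstimate,
    baseline_estimate,
)
from .country import CountryDemography, WHORegion
from .interventions import (
    InterventionEffect,
    ReductionConfig,
    actual_prevalence,
    classify_policy,
    max_averted,
)
from .outcomes import (
    CaseFatalityTable,
    OutcomeEstimate,
    Timepoint,
    outcome_estimate,
)

__all__ = [
    "CountryResult",
    "RegionSummary",
    "PipelineResults",
    "read_country_table",
    "run_pipeline",
    "write_reports",
]

logger = logging.getLogger(__name__)

#: columns required in a country table
COUNTRY_COLUMNS = [
    "iso_code",
    "who_region",
    "total_births",
    "mean_F",
    "tfr",
    "u5mr_per_1000",
    "access_specialist",
    "access_optimal_care",
    "top_legal",
    "prospective_screening",
]


def read_country_table(path: str | Path) -> list[CountryDemography]:
    """Read and validate a delimited country table.

    The header must name every field of :class:`CountryDemography`; boolean
    flags accept 0/1.  Rows violating an invariant are rejected with a
    warning naming the row (1-based data line) and the failed constraint;
    valid rows are returned.  U5MR is carried per 1000 and converted to a
    percentage where the mortality adjustment consumes it.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COUNTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"country table {path} missing columns: {missing}")
    if df.empty:
        warnings.warn(f"country table {path} has no data rows", stacklevel=2)
        return []
    countries: list[CountryDemography] = []
    for idx, row in df.iterrows():
        record = row[COUNTRY_COLUMNS].to_dict()
        record["top_legal"] = bool(int(record["top_legal"]))
        record["prospective_screening"] = bool(
            int(record["prospective_screening"])
        )
        try:
            countries.append(CountryDemography(**record))
        except (ValidationError, ValueError) as exc:
            warnings.warn(
                f"{path} row {idx + 1} ({record.get('iso_code')}): "
                f"rejected — {exc}",
                stacklevel=2,
            )
    return countries


@dataclass(frozen=True)
class CountryResult:
    """All pipeline stages for one country."""

    country: CountryDemography
    baseline: PrevalenceEstimate
    effect: InterventionEffect
    actual: PrevalenceEstimate
    outcomes: OutcomeEstimate


@dataclass(frozen=True)
class RegionSummary:
    """Birth-weighted rates and summed counts for one WHO region."""

    region: WHORegion
    total_births: float
    baseline_rate_per_1000: dict[InheritanceGroup, float]
    actual_rate_per_1000: dict[InheritanceGroup, float]
    affected_births_baseline: dict[InheritanceGroup, float]
    affected_births_actual: dict[InheritanceGroup, float]
    under5_deaths_adjusted: dict[InheritanceGroup, float]
    survivors_with_disability: dict[InheritanceGroup, float]


@dataclass(frozen=True)
class PipelineResults:
    countries: list[CountryResult]
    regions: dict[WHORegion, RegionSummary]
    failures: list[tuple[str, str]]  # (iso_code, message)


def _run_country(
    country: CountryDemography,
    params: BaselineParameters,
    cft: CaseFatalityTable,
    reductions: ReductionConfig,
) -> CountryResult:
    baseline = baseline_estimate(country, params)
    policy = classify_policy(country)
    effect = max_averted(baseline, policy, country.tfr, reductions)
    actual = actual_prevalence(baseline, effect)
    outcomes = outcome_estimate(actual, country, cft)
    return CountryResult(
        country=country,
        baseline=baseline,
        effect=effect,
        actual=actual,
        outcomes=outcomes,
    )


def _summarise_region(
    region: WHORegion, members: list[CountryResult]
) -> RegionSummary:
    births = sum(r.country.total_births for r in members)
    base_rate, act_rate = {}, {}
    base_count, act_count, deaths, survivors = {}, {}, {}, {}
    for g in InheritanceGroup:
        bc = sum(
            r.baseline.total(g) * r.country.total_births / 1000.0
            for r in members
        )
        ac = sum(
            r.actual.total(g) * r.country.total_births / 1000.0
            for r in members
        )
        base_count[g], act_count[g] = bc, ac
        base_rate[g] = 1000.0 * bc / births
        act_rate[g] = 1000.0 * ac / births
        deaths[g] = sum(
            r.outcomes.outcomes[g].deaths_adjusted[Timepoint.UNDER5]
            for r in members
        )
        survivors[g] = sum(
            r.outcomes.outcomes[g].survivors_with_disability for r in members
        )
    return RegionSummary(
        region=region,
        total_births=births,
        baseline_rate_per_1000=base_rate,
        actual_rate_per_1000=act_rate,
        affected_births_baseline=base_count,
        affected_births_actual=act_count,
        under5_deaths_adjusted=deaths,
        survivors_with_disability=survivors,
    )


def run_pipeline(
    countries: list[CountryDemography],
    params: BaselineParameters | None = None,
    cft: CaseFatalityTable | None = None,
    reductions: ReductionConfig | None = None,
) -> PipelineResults:
    """Run baseline → interventions → outcomes for each country and aggregate.

    Deterministic given inputs and configuration.  A failure in one country
    is isolated and recorded in ``failures``; the run continues.
    """
    if not countries:
        raise ValueError("country list is empty")
    params = params or BaselineParameters()
    cft = cft or CaseFatalityTable()
    reductions = reductions or ReductionConfig()
    results: list[CountryResult] = []
    failures: list[tuple[str, str]] = []
    for c in countries:
        try:
            results.append(_run_country(c, params, cft, reductions))
        except Exception as exc:  # noqa: BLE001 - isolate per-country failures
            logger.error("country %s failed: %s", c.iso_code, exc)
            failures.append((c.iso_code, str(exc)))
    by_region: dict[WHORegion, list[CountryResult]] = {}
    for r in results:
        by_region.setdefault(r.country.who_region, []).append(r)
    regions = {
        reg: _summarise_region(reg, members)
        for reg, members in sorted(by_region.items(), key=lambda kv: kv[0].value)
    }
    return PipelineResults(countries=results, regions=regions, failures=failures)


# -- reporting ----------------------------------------------------------------

def country_frame(results: PipelineResults) -> pd.DataFrame:
    """Long-format per-country table: one row per country x group x stage."""
    rows = []
    for r in results.countries:
        for stage_name, est in (("baseline", r.baseline), ("actual", r.actual)):
            for g in InheritanceGroup:
                o = r.outcomes.outcomes[g]
                rows.append(
                    {
                        "iso_code": r.country.iso_code,
                        "who_region": r.country.who_region.value,
                        "stage": stage_name,
                        "group": g.value,
                        "total_per_1000": est.total(g),
                        "livebirth_per_1000": est.livebirth(g),
                        "stillbirth_per_1000": est.stillbirth(g),
                        "averted_per_1000": r.effect.max_averted_per_1000[g],
                        "affected_livebirths": (
                            o.affected_livebirths if stage_name == "actual" else ""
                        ),
                        "under5_deaths_adjusted": (
                            o.deaths_adjusted[Timepoint.UNDER5]
                            if stage_name == "actual"
                            else ""
                        ),
                        "survivors_with_disability": (
                            o.survivors_with_disability
                            if stage_name == "actual"
                            else ""
                        ),
                    }
                )
    return pd.DataFrame(rows)


def region_frame(results: PipelineResults) -> pd.DataFrame:
    """Per-region stacked composition: rate per 1000 by group and stage."""
    rows = []
    for reg, s in results.regions.items():
        for g in InheritanceGroup:
            rows.append(
                {
                    "who_region": reg.value,
                    "group": g.value,
                    "total_births": s.total_births,
                    "baseline_rate_per_1000": s.baseline_rate_per_1000[g],
                    "actual_rate_per_1000": s.actual_rate_per_1000[g],
                    "affected_births_baseline": s.affected_births_baseline[g],
                    "affected_births_actual": s.affected_births_actual[g],
                    "under5_deaths_adjusted": s.under5_deaths_adjusted[g],
                    "survivors_with_disability": s.survivors_with_disability[g],
                }
            )
    return pd.DataFrame(rows)


def _config_hash(
    params: BaselineParameters, cft: CaseFatalityTable, reductions: ReductionConfig
) -> str:
    blob = json.dumps(
        {
            "baseline": params.to_dict(),
            "case_fatality": cft.to_dict(),
            "reductions": {
                "prospective_factor": reductions.prospective_factor,
                "retrospective_no_top_factor": reductions.retrospective_no_top_factor,
                "prospective_no_top_factor": reductions.prospective_no_top_factor,
            },
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def write_reports(
    results: PipelineResults,
    out_dir: str | Path,
    params: BaselineParameters | None = None,
    cft: CaseFatalityTable | None = None,
    reductions: ReductionConfig | None = None,
    plot: bool = False,
) -> list[Path]:
    """Write per-country and regional CSVs, a run log, and an optional plot.

    CSVs carry full precision (machine-readable); the run log records the
    configuration hash so a run can be tied to its exact parameter set.
    Empty regions are simply absent from the region CSV.
    """
    if not results.countries:
        raise ValueError("no results to report")
    params = params or BaselineParameters()
    cft = cft or CaseFatalityTable()
    reductions = reductions or ReductionConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cpath = out / "countries.csv"
    country_frame(results).to_csv(cpath, index=False)
    written.append(cpath)

    rpath = out / "regions.csv"
    region_frame(results).to_csv(rpath, index=False)
    written.append(rpath)

    lpath = out / "run_log.json"
    lpath.write_text(
        json.dumps(
            {
                "n_countries": len(results.countries),
                "n_failures": len(results.failures),
                "failures": results.failures,
                "regions": sorted(r.value for r in results.regions),
                "config_sha256": _config_hash(params, cft, reductions),
                "baseline_parameters": params.to_dict(),
            },
            indent=2,
        )
    )
    written.append(lpath)

    if plot:
        written.append(_plot_regions(results, out / "regions.png"))
    return written


def _plot_regions(results: PipelineResults, path: Path) -> Path:
    """Stacked bar chart of baseline prevalence per 1000 by region and group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    regions = sorted(results.regions, key=lambda r: r.value)
    fig, ax = plt.subplots(figsize=(8, 5))
    bottom = [0.0] * len(regions)
    for g in InheritanceGroup:
        heights = [results.regions[r].baseline_rate_per_1000[g] for r in regions]
        ax.bar([r.value for r in regions], heights, bottom=bottom, label=g.value)
        bottom = [b + h for b, h in zip(bottom, heights)]
    ax.set_ylabel("baseline affected births per 1000 total births")
    ax.set_xlabel("WHO region")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
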