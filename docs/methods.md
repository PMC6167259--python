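# Methods

## Scope and model structure

The package estimates the collective burden of *rare, early-onset single
gene disorders* — those individually too rare for disorder-specific
surveillance — at country and WHO-region level. Disorders are handled as
five inheritance groups (autosomal dominant, X-linked, autosomal recessive,
genetic type unknown, and the consanguinity-associated recessive increment)
rather than as ICD-coded diagnoses. The estimation proceeds in three
deterministic steps per country: baseline birth prevalence, actual birth
prevalence after the maximum effect of risk identification, and child
mortality/disability outcomes. Nothing in the pipeline is stochastic; the
only randomness in the package lives in the gene-dropping kinship
cross-check and the synthetic fixture generator, both seeded.

## Baseline prevalence

Non-consanguinity group rates per 1000 total births (dominant 1.4, X-linked
0.053, recessive 1.84, unknown 1.16) are treated as universal equilibrium
values — a balance between new mutation and selection — so they do not vary
by country. They originate from population-based registry studies of
livebirth prevalence in Northern European / North American populations;
their transferability to other populations is an assumption of the model,
not a finding of this package.

**Stillbirth uplift.** The recessive livebirth rate of 1.66 per 1000 is
converted to total births by treating stillbirths as 10% *of affected
births*: total = livebirths / (1 − 0.10) = 1.844, reported as 1.84. The
alternative reading (add 10% of livebirths, ×1.10 = 1.826) fails to
reproduce the published 1.84 and is not used. Dominant, X-linked and
unknown rates deliberately receive no uplift: no usable fetal-death data
exist for those groups, so livebirth rates stand in for total births.

**Consanguinity increment.** The increment is linear in the population mean
coefficient of consanguinity: rate = F × 100 × multiplier, with the
multiplier defaulting to 6.5 per 1000 per unit of consanguinity (F = 0.01),
the midpoint of observational estimates spanning 5.6–7.7. `BaselineParameters`
constructed outside that range warns rather than fails, so sensitivity runs
at the endpoints are one config edit away (`BaselineParameters` and the
case-fatality table both round-trip through YAML/JSON).

**Couple-level interpretation.** `percent_couples_consanguineous` converts a
population mean F into the fraction of couples that are consanguineous by
assuming two thirds of consanguineous couples are first cousins (F = 0.0625)
and one third more distant relatives. The representative coefficient for
the distant-relative third is an open choice; 0.03125 (first cousins once
removed) is used and is configurable. Mean F beyond the implied
all-couples-consanguineous bound is capped at 1 with a warning rather than
rejected, since the inputs are survey estimates.

## Kinship engine

Kinship is computed by the standard recursion — φ(x,x) = (1 + F_x)/2,
φ(x,y) = mean of φ over the parents of whichever of x, y is further from
the founders, founders mutually unrelated and non-inbred — with memoisation
on unordered pairs; acyclicity is established once at pedigree construction
by topological ordering (Kahn's algorithm), which also supplies the
recursion order. Coefficients are therefore *above population background*:
the canonical union pedigrees assume unrelated founders, matching how the
published union-class coefficients are defined. Uncle–niece unions carry
the same F as double first cousins and are an alias, not a separate class.

The independent cross-check is gene dropping: founders carry unique allele
labels, each child inherits one label uniformly at random from each parent
(vectorised across replicates), and kinship is estimated as the probability
that random alleles from the two individuals match. Agreement is asserted
within 4 binomial standard errors on random pedigrees (and 10⁶ replicates
on the canonical first-cousin pedigree). Pedigree I/O accepts 3-column
(`individual father mother`) and standard 6-column LINKAGE/PED layouts,
ignoring sex and phenotype; `0` marks a missing parent, and an individual
with exactly one recorded parent is rejected.

X-linked kinship and inference of pedigrees from genotypes are out of scope.

## Interventions

Countries fall into four policy groups: retrospective or prospective risk
identification, each with or without prenatal diagnosis (PND) and
termination of pregnancy (TOP). For rare disorders risk identification is
currently retrospective essentially everywhere, so the prospective groups
are reached only via an explicit screening flag. PND+TOP groups require TOP
to be legal or in documented widespread practice.

**Family-limitation ceiling.** The retrospective maximum is derived from its
generative logic rather than hard-coded: per-birth recurrence risk 1/4 in an
at-risk sibship of size s, with every birth after the first affected birth
averted. The expected averted fraction has the closed form
f(s) = [Σ_{i=2..s} (1 − (3/4)^{i−1})/4] / (s/4), validated in the tests
against exhaustive enumeration (exact, s ≤ 8) and Monte Carlo sibship
simulation. The published anchors (~13% at family size 2, 45% at 6) are
reproduced as 12.5% and 45.2%, within the ±1-point tolerance appropriate to
"around". Sibship size maps from the TFR as round(max(TFR, 2)) — couples
are assumed to aim for at least two unaffected children; the exact published
mapping is not available, so this rounding rule is the package's choice and
is isolated in `effective_sibship_size`.

**Reduction factors.** Retrospective + PND+TOP uses the family-limitation
fraction, under the maximal assumption that every woman with access who is
diagnosed with an affected pregnancy terminates it. Prospective + PND+TOP
uses a configurable factor defaulting to 0.90, anchored to the observed
over-90% prevalence falls in established carrier-screening programmes.
Groups without PND+TOP default to 0: counselling alone is attributed no
prevalence reduction, because most at-risk couples with fewer than two
healthy children continue childbearing. A nonzero pure family-limitation
effect is defensible, so both no-TOP factors are exposed in
`ReductionConfig`. Averted rates apply only to the recessive and
consanguinity-associated groups (risk identification is assumed to have
minimal impact on early-onset dominant and X-linked prevalence), are scaled
by access to specialist services, and are subtracted from baseline with the
live/stillbirth split preserved proportionally. Everything here is a
*maximum potential* effect: actual prevalence is a lower bound scenario,
not an uptake model.

## Outcomes

Case fatality rates (CFRs) are cumulative percentages of affected
livebirths dying by the neonatal period, infancy and age five, tabulated at
two care levels. The empirical anchor is follow-up of
consanguinity-associated recessive disorders (under-5 mortality 84% without
care, 28% with optimal care), taken as representative of recessive
disorders generally; dominant disorders are assumed more severe (100/50),
X-linked less severe (40/25), and the unknown group conservatively receives
X-linked rates. Neonatal CFRs are observed only for the recessive groups;
for the others they are derived as 60% of the infant CFR (giving 36.0,
20.4, 21.0, 12.0 for the dominant and X-linked/unknown cells).

A country's effective CFR is the *linear* blend
access × optimal + (1 − access) × no-care; the data provide only the two
endpoints, so linearity is this package's interpolation choice. Deaths are
adjusted for background mortality by multiplicative shrinkage,
adjusted = raw × (1 − U5MR/100), applied at every timepoint. The adjustment
equation consumes U5MR as a *percent* of livebirths; because U5MR is
conventionally reported per 1000, country tables carry `u5mr_per_1000` and
the conversion (÷10) happens once, at the `CountryDemography` boundary — a
per-1000 reading of the equation would imply implausible shrinkage (e.g.
×(1−50) for U5MR 50). CFRs being cumulative, neonatal deaths are a subset
of infant and infant of under-5; no de-duplication across timepoints is
attempted or needed. Since no rare single gene disorder is currently
curable, all survivors to age five are counted as living with some degree
of disability: survivors = affected livebirths − adjusted under-5 deaths.
Lifetime survival and life expectancy are out of scope.

## Pipeline and aggregation

Country tables are delimited text with a named header; rows violating an
invariant (e.g. mean F outside [0, 0.125]) are rejected individually with a
warning naming the row and constraint, and per-country computation failures
are isolated so one bad record cannot abort a run. WHO-region membership is
an input column, not a hard-coded country list. Regional per-1000 rates are
birth-weighted means of member-country rates — births are the natural
weight for a per-1000-births quantity — and counts are sums; a conservation
test verifies regional counts equal summed country counts. Reports carry
full precision in CSV/JSON; rounding is a presentation concern. The run log
includes a SHA-256 hash of the full parameter set, so every output is
traceable to its configuration; there are no hidden constants outside
`BaselineParameters`, `CaseFatalityTable` and `ReductionConfig`.

## Synthetic data

The fixture generator produces country tables with realistic *structure*
and no real country's values. Mean F is bimodal — a log-uniform
low-consanguinity cluster around 10⁻⁴–10⁻².⁵ and a high cluster uniform on
0.02–0.033 — spanning the observed national range (0.0001–0.0332), with the
high cluster more probable in the regions where consanguineous marriage is
common (probability 0.85 in EMR down to 0.05 in EUR). U5MR is uniform on
2–120 per 1000; TFR rises with U5MR within 1.2–7.0; access to services
falls with U5MR; TOP legality and screening flags are correlated with
access. All draws come from one seeded generator, so tables are
reproducible bit-exactly (CSV round-trips use `%.17g` on write and
round-trip float parsing on read).

What the fixtures do **not** emulate: real national statistics, correlation
of births with region, subnational heterogeneity in consanguinity, or any
calibration to published regional figures. Tests passing on fixtures
therefore demonstrate the *internal* correctness of the pipeline
(conservation, monotonicity, regional weighting, the qualitative pattern
that high-consanguinity regions carry a larger consanguinity-associated
share of baseline prevalence) — not agreement with real-world regional
burden, which would require real demographic inputs.

## Problem sizes and numerical choices

Test and acceptance runs use sizes at which every check is exact or
statistically decisive while staying quick: exhaustive family-limitation
enumeration to sibship 8 (4^8 weighted sequences), 10⁶ Monte Carlo sibships
and 10⁶ gene drops for the headline cross-checks, 2×10⁴–5×10⁴ drops per
random pedigree in property tests, and 200–500 synthetic countries for
pipeline properties. Rates are carried at full double precision throughout;
conservation identities are asserted to 1e-12 (relative) and Monte Carlo
agreement at 3–4 standard errors. Dyadic-rational kinship values (0.0625,
0.03125, …) are exact in binary floating point, so canonical-coefficient
tests use equality; published 4-decimal values use half-up rounding
(0.03125 → 0.0313).

## Known limitations

- Baseline rates rest on pre-1990 registry studies from two high-income
  populations; the equilibrium argument, not data coverage, justifies their
  global use.
- Intervention effects are maxima under full-uptake assumptions, not
  forecasts; uptake heterogeneity, extended-family studies and
  preimplantation diagnosis are not modelled.
- Mortality data outside the consanguinity-associated group are sparse;
  the dominant/X-linked/unknown CFRs are structured assumptions.
- Paternal-age effects on mutation rates are deliberately excluded.
- The prospective-screening scenario factor (0.90) is a documented knob for
  exploration, not a validated projection.
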