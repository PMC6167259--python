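"""Family-limitation (Fraser) model, policy classification, actual prevalence."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from mendelburden import (
    InheritanceGroup,
    InterventionPolicy,
    PolicyGroup,
    ReductionConfig,
    Stage,
    actual_prevalence,
    baseline_estimate,
    classify_policy,
    effective_sibship_size,
    fraser_avoidable_fraction,
    max_averted,
    worked_example_country,
)
from mendelburden.baseline_prevalence import GroupRates, PrevalenceEstimate

from conftest import fraser_fraction_by_enumeration, fraser_fraction_by_simulation

G = InheritanceGroup


def _estimate(stage=Stage.BASELINE, **totals):
    """Build a PrevalenceEstimate with a 10% stillbirth split on recessive
    groups and pure-livebirth dominant/x-linked/unknown."""
    rates = {}
    for g in G:
        total = totals.get(g.value, 0.0)
        sbf = (
            0.10
            if g in (G.RECESSIVE, G.CONSANGUINITY_ASSOCIATED)
            else 0.0
        )
        rates[g] = GroupRates(total, total * (1 - sbf), total * sbf)
    return PrevalenceEstimate(rates=rates, stage=stage)


class TestFraserFraction:
    def test_single_birth_sibship_averts_nothing(self):
        assert fraser_avoidable_fraction(1) == 0.0

    def test_sibship_of_two(self):
        # reported as "around 13%"; exact value 1/8
        assert fraser_avoidable_fraction(2) == 0.125

    def test_sibship_of_six(self):
        # reported as 45%
        assert fraser_avoidable_fraction(6) == pytest.approx(0.4519856770833333)

    @pytest.mark.parametrize("s", range(1, 9))
    def test_closed_form_matches_exhaustive_enumeration(self, s):
        exact = fraser_fraction_by_enumeration(s)
        assert fraser_avoidable_fraction(s) == pytest.approx(
            float(exact), abs=1e-12
        )

    def test_enumeration_oracle_is_exact_rational(self):
        assert fraser_fraction_by_enumeration(2) == Fraction(1, 8)

    def test_monte_carlo_agrees_within_3se(self):
        est, se = fraser_fraction_by_simulation(6, 200_000, seed=11)
        assert abs(est - fraser_avoidable_fraction(6)) <= 3 * se

    def test_strictly_increasing_and_converges_to_one(self):
        values = [fraser_avoidable_fraction(s) for s in range(2, 30)]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert fraser_avoidable_fraction(1000) == pytest.approx(1.0, abs=1e-2)

    def test_invalid_sibship_rejected(self):
        with pytest.raises(ValueError):
            fraser_avoidable_fraction(0)


class TestEffectiveSibshipSize:
    @pytest.mark.parametrize(
        "tfr, expected", [(2.0, 2), (6.0, 6), (1.4, 2), (3.6, 4), (2.5, 2)]
    )
    def test_mapping(self, tfr, expected):
        assert effective_sibship_size(tfr) == expected

    def test_non_positive_tfr_rejected(self):
        with pytest.raises(ValueError):
            effective_sibship_size(0.0)


class TestClassifyPolicy:
    @pytest.mark.parametrize(
        "top, prospective, expected",
        [
            (False, False, PolicyGroup.RETROSPECTIVE_ONLY),
            (True, False, PolicyGroup.RETROSPECTIVE_WITH_PND_TOP),
            (False, True, PolicyGroup.PROSPECTIVE_ONLY),
            (True, True, PolicyGroup.PROSPECTIVE_WITH_PND_TOP),
        ],
    )
    def test_four_policy_groups(self, top, prospective, expected):
        country = worked_example_country().model_copy(
            update={"top_legal": top, "prospective_screening": prospective}
        )
        policy = classify_policy(country)
        assert policy.policy_group is expected
        assert policy.access_specialist_services == country.access_specialist

    def test_pnd_top_groups_require_top(self):
        with pytest.raises(ValueError):
            InterventionPolicy(
                policy_group=PolicyGroup.RETROSPECTIVE_WITH_PND_TOP,
                top_legal_or_practised=False,
                access_specialist_services=1.0,
            )


class TestMaxAverted:
    def test_no_access_averts_nothing(self):
        baseline = _estimate(recessive=1.84, consanguinity_associated=6.5)
        policy = InterventionPolicy(
            PolicyGroup.RETROSPECTIVE_WITH_PND_TOP, True, 0.0
        )
        effect = max_averted(baseline, policy, tfr=2.0)
        assert all(v == 0.0 for v in effect.max_averted_per_1000.values())

    def test_retrospective_pnd_top_at_tfr_two(self):
        baseline = _estimate(recessive=1.84)
        policy = InterventionPolicy(
            PolicyGroup.RETROSPECTIVE_WITH_PND_TOP, True, 1.0
        )
        effect = max_averted(baseline, policy, tfr=2.0)
        assert effect.fraser_fraction == 0.125
        assert effect.max_averted_per_1000[G.RECESSIVE] == pytest.approx(0.23)

    def test_prospective_pnd_top_default_factor(self):
        baseline = _estimate(consanguinity_associated=6.5)
        policy = InterventionPolicy(
            PolicyGroup.PROSPECTIVE_WITH_PND_TOP, True, 1.0
        )
        effect = max_averted(baseline, policy, tfr=2.0)
        assert effect.max_averted_per_1000[
            G.CONSANGUINITY_ASSOCIATED
        ] == pytest.approx(5.85)

    def test_dominant_and_xlinked_never_reduced(self):
        baseline = _estimate(dominant=1.4, x_linked=0.053, unknown=1.16,
                             recessive=1.84)
        policy = InterventionPolicy(
            PolicyGroup.PROSPECTIVE_WITH_PND_TOP, True, 1.0
        )
        effect = max_averted(baseline, policy, tfr=6.0)
        for g in (G.DOMINANT, G.X_LINKED, G.UNKNOWN):
            assert effect.max_averted_per_1000[g] == 0.0

    def test_without_pnd_top_default_factor_is_zero(self):
        baseline = _estimate(recessive=1.84)
        policy = InterventionPolicy(PolicyGroup.RETROSPECTIVE_ONLY, False, 1.0)
        effect = max_averted(baseline, policy, tfr=4.0)
        assert effect.max_averted_per_1000[G.RECESSIVE] == 0.0

    def test_family_limitation_knob_without_top(self):
        baseline = _estimate(recessive=2.0)
        policy = InterventionPolicy(PolicyGroup.RETROSPECTIVE_ONLY, False, 1.0)
        config = ReductionConfig(retrospective_no_top_factor=0.05)
        effect = max_averted(baseline, policy, tfr=4.0, config=config)
        assert effect.max_averted_per_1000[G.RECESSIVE] == pytest.approx(0.10)

    def test_requires_baseline_stage(self):
        actual = _estimate(stage=Stage.ACTUAL, recessive=1.84)
        policy = InterventionPolicy(PolicyGroup.RETROSPECTIVE_ONLY, False, 1.0)
        with pytest.raises(ValueError):
            max_averted(actual, policy, tfr=2.0)


class TestActualPrevalence:
    def test_zero_effect_leaves_baseline_unchanged(self):
        baseline = baseline_estimate(worked_example_country())
        policy = InterventionPolicy(PolicyGroup.RETROSPECTIVE_ONLY, False, 1.0)
        actual = actual_prevalence(
            baseline, max_averted(baseline, policy, tfr=2.0)
        )
        assert actual.stage is Stage.ACTUAL
        for g in G:
            assert actual.total(g) == baseline.total(g)

    def test_subtraction_example(self):
        baseline = _estimate(recessive=1.84)
        policy = InterventionPolicy(
            PolicyGroup.RETROSPECTIVE_WITH_PND_TOP, True, 1.0
        )
        actual = actual_prevalence(
            baseline, max_averted(baseline, policy, tfr=2.0)
        )
        assert actual.total(G.RECESSIVE) == pytest.approx(1.61)

    @settings(max_examples=50, deadline=None)
    @given(
        access=st.floats(0, 1),
        tfr=st.floats(0.5, 8),
        mean_F=st.floats(0, 0.0332),
        top=st.booleans(),
        prospective=st.booleans(),
    )
    def test_conservation_and_monotonicity(
        self, access, tfr, mean_F, top, prospective
    ):
        """baseline = actual + averted per group; actual never negative and
        non-increasing in access."""
        country = worked_example_country().model_copy(
            update={
                "access_specialist": access,
                "tfr": tfr,
                "mean_F": mean_F,
                "top_legal": top,
                "prospective_screening": prospective,
            }
        )
        baseline = baseline_estimate(country)
        effect = max_averted(baseline, classify_policy(country), tfr)
        actual = actual_prevalence(baseline, effect)
        for g in G:
            assert actual.total(g) + effect.max_averted_per_1000[
                g
            ] == pytest.approx(baseline.total(g), abs=1e-12)
            assert actual.total(g) >= 0
            # live/still split preserved proportionally (skip degenerate
            # subnormal rates where the ratio loses precision)
            if baseline.total(g) > 1e-12 and actual.total(g) > 1e-12:
                assert actual.livebirth(g) / actual.total(g) == pytest.approx(
                    baseline.livebirth(g) / baseline.total(g), abs=1e-9
                )
        # monotone in access: halving access cannot increase averted births
        policy_full = classify_policy(country)
        policy_half = InterventionPolicy(
            policy_full.policy_group,
            policy_full.top_legal_or_practised,
            access / 2,
        )
        averted_half = max_averted(baseline, policy_half, tfr)
        for g in G:
            assert (
                averted_half.max_averted_per_1000[g]
                <= effect.max_averted_per_1000[g] + 1e-12
            )

    def test_averted_exceeding_baseline_rejected(self):
        from mendelburden.interventions import InterventionEffect

        baseline = _estimate(recessive=1.0)
        effect = InterventionEffect(
            policy_group=PolicyGroup.RETROSPECTIVE_ONLY,
            fraser_fraction=0.0,
            max_averted_per_1000={g: (2.0 if g is G.RECESSIVE else 0.0) for g in G},
        )
        with pytest.raises(ValueError):
            actual_prevalence(baseline, effect)
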