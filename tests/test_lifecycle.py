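"""Lifetime-to-daily rate conversion and per-scenario vital-rate resolution."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitefear import (
    VitalRates,
    build_vital_rates,
    daily_from_lifetime_survival,
    lifetime_reproductive_output,
    make_scenario,
    preadult_duration_from_effect,
)
from mitefear.lifecycle import (
    PREADULT_SURVIVAL_EXPOSED,
    PREADULT_SURVIVAL_UNEXPOSED,
)


class TestDailyFromLifetime:
    @pytest.mark.parametrize(
        "lifetime, duration, expected",
        [(1.0, 12, 1.0), (0.25, 2, 0.5), (0.7076, 12, 0.9716)],
    )
    def test_examples(self, lifetime, duration, expected):
        assert daily_from_lifetime_survival(lifetime, duration) == pytest.approx(
            expected, abs=1e-4
        )

    def test_zero_lifetime_rejected(self):
        with pytest.raises(ValueError):
            daily_from_lifetime_survival(0.0, 10)

    @given(
        lifetime=st.floats(min_value=1e-6, max_value=1.0),
        duration=st.integers(min_value=1, max_value=120),
    )
    def test_round_trip(self, lifetime, duration):
        daily = daily_from_lifetime_survival(lifetime, duration)
        assert daily**duration == pytest.approx(lifetime, abs=1e-12)


def _scan_duration(s_un, s_ex, reduction, max_d=60):
    """Independent brute-force oracle for the implied stage duration."""
    ratio = s_ex / s_un
    errors = [(abs((1 - ratio**d) - reduction), d) for d in range(1, max_d + 1)]
    return min(errors)[1]


class TestPreadultDuration:
    @pytest.mark.parametrize(
        "reduction, expected", [(0.61, 12), (0.588, 11)]
    )
    def test_published_daily_rates(self, reduction, expected):
        got = preadult_duration_from_effect(
            PREADULT_SURVIVAL_UNEXPOSED, PREADULT_SURVIVAL_EXPOSED, reduction
        )
        assert got == expected
        assert got == _scan_duration(
            PREADULT_SURVIVAL_UNEXPOSED, PREADULT_SURVIVAL_EXPOSED, reduction
        )

    def test_single_day_half_survival(self):
        assert preadult_duration_from_effect(0.9, 0.45, 0.5) == 1

    def test_no_reduction_rejected(self):
        with pytest.raises(ValueError):
            preadult_duration_from_effect(0.9, 0.95, 0.5)

    @given(
        s_un=st.floats(min_value=0.5, max_value=0.99),
        ratio=st.floats(min_value=0.5, max_value=0.99),
        reduction=st.floats(min_value=0.05, max_value=0.95),
    )
    def test_matches_scan_oracle(self, s_un, ratio, reduction):
        s_ex = s_un * ratio
        assert preadult_duration_from_effect(
            s_un, s_ex, reduction
        ) == _scan_duration(s_un, s_ex, reduction)


@pytest.fixture
def round_baseline():
    """A baseline with round numbers (30-day lifespan, 1.2 eggs/day) for
    hand-checkable arithmetic."""
    s = 1.0 - 1.0 / 30.0
    return VitalRates(
        adult_daily_survival_uninfected=s,
        adult_daily_survival_infected=s,
        daily_fecundity_uninfected=1.2,
        daily_fecundity_infected=1.2,
    )


class TestBuildVitalRates:
    def test_scenario_a_is_identity(self, effects, baseline):
        assert build_vital_rates(effects, make_scenario("A"), baseline) == baseline

    def test_scenario_c_changes_only_preadult_survival(self, effects, baseline):
        rates = build_vital_rates(effects, make_scenario("C"), baseline)
        assert rates.preadult_daily_survival == PREADULT_SURVIVAL_EXPOSED
        unchanged = dataclasses.replace(
            rates, preadult_daily_survival=baseline.preadult_daily_survival
        )
        assert unchanged == baseline

    def test_adult_nce_arithmetic(self, effects, round_baseline):
        rates = build_vital_rates(effects, make_scenario("B"), round_baseline)
        # mortality 1/30 divided by 0.79; daily fecundity times 0.87/0.79
        assert rates.adult_daily_survival_uninfected == pytest.approx(
            1.0 - (1.0 / 30.0) / 0.79, abs=1e-12
        )
        assert rates.adult_daily_survival_uninfected == pytest.approx(0.9578, abs=1e-3)
        assert rates.daily_fecundity_uninfected == pytest.approx(
            1.2 * 0.87 / 0.79, abs=1e-12
        )

    def test_adult_nce_lifetime_output_is_87_percent(self, effects, baseline):
        # the compensatory mechanism: x1.101 daily rate over a x0.79 lifespan
        base_r0 = lifetime_reproductive_output(baseline)
        nce_r0 = lifetime_reproductive_output(
            build_vital_rates(effects, make_scenario("B"), baseline)
        )
        assert nce_r0 / base_r0 == pytest.approx(0.87, abs=1e-12)

    def test_infected_class_multipliers(self, effects, round_baseline):
        rates = build_vital_rates(
            effects, make_scenario("E"), round_baseline, infection_prob=0.05
        )
        mort_u = 1.0 - rates.adult_daily_survival_uninfected
        mort_i = 1.0 - rates.adult_daily_survival_infected
        assert mort_i == pytest.approx(mort_u * 1.670, abs=1e-12)
        assert rates.daily_fecundity_infected == pytest.approx(
            rates.daily_fecundity_uninfected / 2.019, abs=1e-12
        )
        assert rates.daily_infection_prob == 0.05

    def test_infection_prob_zero_without_ce(self, effects, baseline):
        for sid in "ABCD":
            rates = build_vital_rates(
                effects, make_scenario(sid), baseline, infection_prob=0.5
            )
            assert rates.daily_infection_prob == 0.0

    def test_scenario_monotonicity_of_lifetime_output(self, effects, baseline):
        r0 = {
            sid: lifetime_reproductive_output(
                build_vital_rates(effects, make_scenario(sid), baseline)
            )
            for sid in "ABCD"
        }
        assert r0["C"] < r0["A"]
        assert r0["D"] < r0["B"]

    def test_impossible_rates_rejected_with_field_name(self, effects):
        fragile = VitalRates(
            adult_daily_survival_uninfected=0.5,
            adult_daily_survival_infected=0.5,
        )
        with pytest.raises(ValueError, match="adult_daily_survival_infected"):
            build_vital_rates(effects, make_scenario("E"), fragile, infection_prob=0.1)

    def test_exposed_survival_derivable_from_effect(self, effects, baseline):
        # with the stated daily value switched off, the lifetime effect drives it
        derived = build_vital_rates(
            effects,
            make_scenario("C"),
            dataclasses.replace(baseline, preadult_daily_survival_exposed=None),
        )
        lifetime = baseline.preadult_daily_survival**12 * (1 - 0.61)
        assert derived.preadult_daily_survival == pytest.approx(
            lifetime ** (1 / 12), abs=1e-12
        )
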