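"""Daily stochastic update and replicate-ensemble behaviour."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitefear import (
    ExperimentDesign,
    VitalRates,
    init_population,
    make_scenario,
    run_replicates,
    step_day,
)


def _rates(**kw):
    defaults = dict(
        egg_duration=2,
        hatch_prob=0.95,
        preadult_duration=4,
        preadult_daily_survival=0.9,
        adult_daily_survival_uninfected=0.95,
        adult_daily_survival_infected=0.9,
        daily_fecundity_uninfected=1.0,
        daily_fecundity_infected=0.5,
        daily_infection_prob=0.0,
        recruitment_capacity=math.inf,
    )
    defaults.update(kw)
    return VitalRates(**defaults)


class TestInitPopulation:
    def test_founders_only(self):
        state = init_population(50, _rates())
        assert state.adults_uninfected == 50
        assert state.adults_infected == 0
        assert state.egg_counts.sum() == 0
        assert state.preadult_counts.sum() == 0
        assert state.day == 0
        assert state.ever_adults == 50

    def test_empty_population(self):
        assert init_population(0, _rates()).total == 0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            init_population(-1, _rates())


class TestStepDay:
    def test_empty_state_is_absorbing(self):
        rng = np.random.default_rng(0)
        state = init_population(0, _rates())
        nxt = step_day(state, _rates(), rng)
        assert nxt.total == 0
        assert nxt.day == 1

    def test_conservation_with_hazards_off(self):
        # survival 1 everywhere, no reproduction, no infection
        rates = _rates(
            preadult_daily_survival=1.0,
            adult_daily_survival_uninfected=1.0,
            adult_daily_survival_infected=1.0,
            daily_fecundity_uninfected=0.0,
            daily_fecundity_infected=0.0,
        )
        rng = np.random.default_rng(1)
        state = init_population(50, rates)
        for _ in range(50):
            state = step_day(state, rates, rng)
        assert state.total == 50
        assert state.adults_uninfected == 50

    def test_certain_infection_converts_all_adults(self):
        rates = _rates(
            adult_daily_survival_uninfected=1.0,
            adult_daily_survival_infected=1.0,
            daily_fecundity_uninfected=0.0,
            daily_fecundity_infected=0.0,
            daily_infection_prob=1.0,
        )
        rng = np.random.default_rng(2)
        state = step_day(init_population(10, rates), rates, rng)
        assert state.adults_uninfected == 0
        assert state.adults_infected == 10
        assert state.ever_infected == 10

    def test_input_state_not_mutated(self):
        rng = np.random.default_rng(3)
        state = init_population(50, _rates())
        before = (state.egg_counts.copy(), state.adults_uninfected, state.day)
        step_day(state, _rates(), rng)
        assert np.array_equal(state.egg_counts, before[0])
        assert (state.adults_uninfected, state.day) == before[1:]

    @given(
        seed=st.integers(min_value=0, max_value=1000),
        founders=st.integers(min_value=0, max_value=200),
        fec=st.floats(min_value=0.0, max_value=5.0),
        p=st.floats(min_value=0.0, max_value=1.0),
        capacity=st.sampled_from([math.inf, 10.0, 500.0]),
    )
    def test_counts_stay_nonnegative_integers(self, seed, founders, fec, p, capacity):
        rates = _rates(
            daily_fecundity_uninfected=fec,
            daily_infection_prob=p,
            recruitment_capacity=capacity,
        )
        rng = np.random.default_rng(seed)
        state = init_population(founders, rates)
        for _ in range(10):
            state = step_day(state, rates, rng)
            assert state.egg_counts.dtype.kind == "i"
            assert (state.egg_counts >= 0).all()
            assert (state.preadult_counts >= 0).all()
            assert state.adults_uninfected >= 0
            assert state.adults_infected >= 0
            assert state.ever_infected <= state.ever_adults


class TestRunReplicates:
    def test_seeded_determinism(self, effects, baseline, small_design):
        a = run_replicates(make_scenario("F"), effects, baseline, small_design, 0.02)
        b = run_replicates(make_scenario("F"), effects, baseline, small_design, 0.02)
        assert np.array_equal(a.uninfected_trajectories, b.uninfected_trajectories)
        assert np.array_equal(a.infected_trajectories, b.infected_trajectories)
        assert a.ever_infected_total == b.ever_infected_total

    def test_first_column_is_founders(self, effects, baseline, small_design):
        rs = run_replicates(make_scenario("A"), effects, baseline, small_design)
        assert (rs.adult_trajectories[:, 0] == small_design.n_founders).all()

    def test_zero_horizon(self, effects, baseline):
        design = ExperimentDesign(n_replicates=1, horizon=0, n_founders=50, master_seed=0)
        rs = run_replicates(make_scenario("A"), effects, baseline, design)
        assert rs.adult_trajectories.tolist() == [[50]]

    def test_replicate_streams_are_distinct(self, effects, baseline, small_design):
        rs = run_replicates(make_scenario("A"), effects, baseline, small_design)
        rows = {tuple(row) for row in rs.adult_trajectories}
        assert len(rows) == small_design.n_replicates

    def test_infection_tallies_bounded(self, effects, baseline, small_design):
        rs = run_replicates(make_scenario("E"), effects, baseline, small_design, 0.05)
        assert 0 < rs.ever_infected_total <= rs.adults_ever_total

    def test_different_master_seeds_differ(self, effects, baseline, small_design):
        other = dataclasses.replace(small_design, master_seed=12)
        a = run_replicates(make_scenario("A"), effects, baseline, small_design)
        b = run_replicates(make_scenario("A"), effects, baseline, other)
        assert not np.array_equal(a.adult_trajectories, b.adult_trajectories)

    def test_baseline_outgrows_wild_condition(self, effects, baseline):
        design = ExperimentDesign(n_replicates=100, horizon=60, master_seed=4)
        a = run_replicates(make_scenario("A"), effects, baseline, design)
        f = run_replicates(make_scenario("F"), effects, baseline, design, 0.02)
        assert a.mean_final_adults() > f.mean_final_adults()
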