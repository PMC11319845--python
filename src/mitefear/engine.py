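"""Daily stochastic update and replicate ensembles.

The population state is a vector of integer counts per daily age class:
``egg_duration`` egg classes, ``preadult_duration`` larva/pupa classes,
and two adult classes (uninfected, infected).  One day applies, in fixed
order:

1. **survival** — binomial thinning of every class (eggs survive within
   the egg stage; egg mortality enters through the hatch probability);
2. **infection** — each surviving uninfected adult becomes infected with
   the daily infection probability; infection is permanent;
3. **advancement** — classes age by one day; the last egg class hatches
   into the first pre-adult class with the hatch probability; the last
   pre-adult class matures into the uninfected adult class;
4. **reproduction** — eggs laid is a Poisson draw with mean
   ``fecundity_uninfected * adults_uninfected +
   fecundity_infected * adults_infected`` (newly matured adults lay on
   their maturation day);
5. **establishment** — with finite recruitment capacity ``K``, each egg
   laid establishes independently with probability ``K / (K + laid)``
   (Beverton–Holt-style saturation of the daily egg niche).

Replicate ensembles draw every replicate from its own
``SeedSequence(master_seed, scenario_index, replicate)`` stream, so any
single replicate of any scenario is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lifecycle import VitalRates, build_vital_rates
from .params import SCENARIO_IDS, EffectTable, ExperimentDesign, Scenario

__all__ = ["PopulationState", "ReplicateSet", "init_population", "step_day", "run_replicates"]


@dataclass
class PopulationState:
    """Integer counts per daily age class, plus run tallies.

    ``ever_adults`` counts every fly that ever entered adulthood
    (founders included) and ``ever_infected`` every adult that ever
    entered the infected class; the two feed the realized-prevalence
    summary.
    """

    egg_counts: np.ndarray
    preadult_counts: np.ndarray
    adults_uninfected: int
    adults_infected: int
    day: int = 0
    ever_adults: int = 0
    ever_infected: int = 0

    @property
    def total_adults(self) -> int:
        return self.adults_uninfected + self.adults_infected

    @property
    def total(self) -> int:
        return int(
            self.egg_counts.sum() + self.preadult_counts.sum() + self.total_adults
        )

    @property
    def is_extinct(self) -> bool:
        return self.total == 0


def init_population(n_founders: int, rates: VitalRates) -> PopulationState:
    """A founding dispersal: ``n_founders`` uninfected adults, nothing else."""
    if n_founders < 0:
        raise ValueError("n_founders must be >= 0")
    return PopulationState(
        egg_counts=np.zeros(rates.egg_duration, dtype=np.int64),
        preadult_counts=np.zeros(rates.preadult_duration, dtype=np.int64),
        adults_uninfected=int(n_founders),
        adults_infected=0,
        day=0,
        ever_adults=int(n_founders),
        ever_infected=0,
    )


def step_day(
    state: PopulationState, rates: VitalRates, rng: np.random.Generator
) -> PopulationState:
    """Advance one population by one day (see module docstring for the
    event order).  The input state is not modified."""
    # 1. survival
    pre = rng.binomial(state.preadult_counts, rates.preadult_daily_survival)
    a_u = int(rng.binomial(state.adults_uninfected, rates.adult_daily_survival_uninfected))
    a_i = int(rng.binomial(state.adults_infected, rates.adult_daily_survival_infected))
    eggs = state.egg_counts.copy()

    # 2. infection (permanent transition)
    newly_infected = int(rng.binomial(a_u, rates.daily_infection_prob))
    a_u -= newly_infected
    a_i += newly_infected

    # 3. advancement: age one class; hatch; mature
    matured = int(pre[-1])
    pre[1:] = pre[:-1]
    pre[0] = rng.binomial(eggs[-1], rates.hatch_prob)
    eggs[1:] = eggs[:-1]
    a_u += matured

    # 4. reproduction (new adults lay from their first adult day)
    mean_eggs = (
        a_u * rates.daily_fecundity_uninfected + a_i * rates.daily_fecundity_infected
    )
    laid = int(rng.poisson(mean_eggs)) if mean_eggs > 0 else 0

    # 5. establishment: saturating daily egg niche
    K = rates.recruitment_capacity
    if laid > 0 and math.isfinite(K):
        established = int(rng.binomial(laid, K / (K + laid)))
    else:
        established = laid
    eggs[0] = established

    return PopulationState(
        egg_counts=eggs,
        preadult_counts=pre,
        adults_uninfected=a_u,
        adults_infected=a_i,
        day=state.day + 1,
        ever_adults=state.ever_adults + matured,
        ever_infected=state.ever_infected + newly_infected,
    )


@dataclass
class ReplicateSet:
    """Adult-count trajectories and infection tallies for one scenario.

    ``uninfected_trajectories`` / ``infected_trajectories`` have shape
    ``(n_replicates, horizon + 1)``; column 0 is the founding state.
    """

    scenario: Scenario
    uninfected_trajectories: np.ndarray
    infected_trajectories: np.ndarray
    ever_infected_total: int
    adults_ever_total: int
    seed: int
    rates: VitalRates | None = field(default=None, repr=False)
    ever_infected_by_replicate: np.ndarray | None = field(default=None, repr=False)
    ever_adults_by_replicate: np.ndarray | None = field(default=None, repr=False)

    @property
    def adult_trajectories(self) -> np.ndarray:
        """Total adult count (uninfected + infected) per replicate per day."""
        return self.uninfected_trajectories + self.infected_trajectories

    @property
    def n_replicates(self) -> int:
        return self.uninfected_trajectories.shape[0]

    @property
    def horizon(self) -> int:
        return self.uninfected_trajectories.shape[1] - 1

    def mean_trajectory(self) -> np.ndarray:
        """Ensemble-mean adult count per day (extinct replicates count as 0)."""
        return self.adult_trajectories.mean(axis=0)

    def mean_final_adults(self) -> float:
        return float(self.adult_trajectories[:, -1].mean())


def _replicate_rng(master_seed: int, scenario: Scenario, replicate: int) -> np.random.Generator:
    scn_index = SCENARIO_IDS.index(scenario.id)
    return np.random.default_rng(
        np.random.SeedSequence((master_seed, scn_index, replicate))
    )


def run_replicates(
    scenario: Scenario,
    effects: EffectTable,
    baseline: VitalRates,
    design: ExperimentDesign,
    infection_prob: float | None = None,
) -> ReplicateSet:
    """Run the replicate ensemble for one scenario.

    Rates are resolved once via :func:`build_vital_rates`;
    ``infection_prob`` (the calibrated daily infection hazard) overrides
    the baseline's stored probability for scenarios with consumptive
    effects.  Each replicate runs on its own seeded stream derived from
    ``(master_seed, scenario index, replicate index)``.
    """
    rates = build_vital_rates(effects, scenario, baseline, infection_prob)
    n, h = design.n_replicates, design.horizon
    uninf = np.empty((n, h + 1), dtype=np.int64)
    inf = np.empty((n, h + 1), dtype=np.int64)
    ever_infected = np.zeros(n, dtype=np.int64)
    ever_adults = np.zeros(n, dtype=np.int64)
    for rep in range(n):
        rng = _replicate_rng(design.master_seed, scenario, rep)
        state = init_population(design.n_founders, rates)
        uninf[rep, 0] = state.adults_uninfected
        inf[rep, 0] = state.adults_infected
        for day in range(1, h + 1):
            state = step_day(state, rates, rng)
            uninf[rep, day] = state.adults_uninfected
            inf[rep, day] = state.adults_infected
        ever_infected[rep] = state.ever_infected
        ever_adults[rep] = state.ever_adults
    return ReplicateSet(
        scenario=scenario,
        uninfected_trajectories=uninf,
        infected_trajectories=inf,
        ever_infected_total=int(ever_infected.sum()),
        adults_ever_total=int(ever_adults.sum()),
        seed=design.master_seed,
        rates=rates,
        ever_infected_by_replicate=ever_infected,
        ever_adults_by_replicate=ever_adults,
    )
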