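"""Effect sizes, scenario definitions, and experiment design constants.

The empirical inputs to the simulation are a small table of lifetime
effect sizes of the mite *Macrocheles subbadius* on the cactophilic fly
*Drosophila nigrospiracula*, split by host life stage and by pathway:

* **NCE** (nonconsumptive effect) — the cost of merely being exposed to
  mites or mite cues, without infection (energetically costly grooming,
  displaced pupation sites, ...).
* **CE** (consumptive effect) — the direct cost of infection, which only
  adult flies experience.

Effects are stored as :class:`EffectEstimate` point estimates with their
published 95 % confidence intervals.  The headline pipeline uses point
estimates only; the intervals feed the optional sensitivity sampler
:func:`sample_effect_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "EffectEstimate",
    "EffectTable",
    "Scenario",
    "ExperimentDesign",
    "SCENARIO_IDS",
    "default_effect_table",
    "make_scenario",
    "sample_effect_table",
]


@dataclass(frozen=True)
class EffectEstimate:
    """One published effect size.

    Parameters
    ----------
    point:
        The effect expressed as a dimensionless fraction (e.g. ``0.61``
        for a 61 % reduction, ``1.019`` for a 101.9 % relative excess).
    ci_low, ci_high:
        95 % confidence bounds *as printed in the source*, which may be
        in units other than fractions (see ``ci_units``).
    ci_units:
        Label for the interval's units: ``"fraction"``, ``"percent"``,
        ``"days"`` or ``"eggs"``.
    direction:
        ``"reduction"``, ``"increase"`` or ``"none"``.
    """

    point: float
    ci_low: float = 0.0
    ci_high: float = 0.0
    ci_units: str = "fraction"
    direction: str = "none"

    def __post_init__(self) -> None:
        if self.point < 0:
            raise ValueError(f"effect point estimate must be >= 0, got {self.point}")
        if self.ci_low > self.ci_high:
            raise ValueError(
                f"ci_low ({self.ci_low}) must not exceed ci_high ({self.ci_high})"
            )

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low

    def ci_as_fraction(self, baseline_scale: float = 100.0) -> tuple[float, float]:
        """Convert the printed interval to fractions of the relevant baseline.

        ``percent`` intervals are divided by 100; ``days``/``eggs``
        intervals are divided by ``baseline_scale`` (e.g. the baseline
        mean adult lifespan in days).  If the converted interval fails to
        bracket the point estimate, the support is widened to include it
        so that a triangular draw is always well defined.
        """
        if self.ci_units == "fraction":
            lo, hi = self.ci_low, self.ci_high
        elif self.ci_units == "percent":
            lo, hi = self.ci_low / 100.0, self.ci_high / 100.0
        else:
            lo, hi = self.ci_low / baseline_scale, self.ci_high / baseline_scale
        return min(lo, self.point), max(hi, self.point)


@dataclass(frozen=True)
class EffectTable:
    """The encoded effect-size table plus the prevalence calibration target.

    Egg-stage effects are fixed at zero: no reduction in hatch rate was
    observed among eggs laid near mites, and egg consumption by mites is
    not modelled.
    """

    egg_nce: EffectEstimate = field(default_factory=lambda: EffectEstimate(0.0))
    egg_ce: EffectEstimate = field(default_factory=lambda: EffectEstimate(0.0))
    larva_nce_survival: EffectEstimate = field(
        default_factory=lambda: EffectEstimate(0.0)
    )
    adult_nce_lifespan: EffectEstimate = field(
        default_factory=lambda: EffectEstimate(0.0)
    )
    adult_nce_fecundity: EffectEstimate = field(
        default_factory=lambda: EffectEstimate(0.0)
    )
    adult_ce_fecundity: EffectEstimate = field(
        default_factory=lambda: EffectEstimate(0.0)
    )
    adult_ce_longevity: EffectEstimate = field(
        default_factory=lambda: EffectEstimate(0.0)
    )
    target_prevalence: float = 0.41

    def __post_init__(self) -> None:
        if self.egg_nce.point != 0 or self.egg_ce.point != 0:
            raise ValueError("egg-stage effects are treated as 0")
        if not 0.0 <= self.target_prevalence <= 1.0:
            raise ValueError(
                f"target_prevalence must be in [0, 1], got {self.target_prevalence}"
            )


def default_effect_table() -> EffectTable:
    """The published point estimates and 95 % confidence intervals.

    Larval (pre-adult) NCE: survival to adulthood reduced by 61 %.
    Adult NCE: mean lifespan reduced by 21 %, lifetime reproductive
    output by 13 %.  Adult CE: uninfected flies exceed infected flies by
    101.9 % in fecundity and 67.0 % in longevity (relative excess — the
    infected-class multipliers are 1/2.019 and 1/1.670).  The prevalence
    target for infection calibration is 41 % of adults parasitized.
    """
    return EffectTable(
        egg_nce=EffectEstimate(0.0, direction="none"),
        egg_ce=EffectEstimate(0.0, direction="none"),
        larva_nce_survival=EffectEstimate(
            0.61, 16.3, 28.3, ci_units="percent", direction="reduction"
        ),
        adult_nce_lifespan=EffectEstimate(
            0.21, 2.0, 12.2, ci_units="days", direction="reduction"
        ),
        adult_nce_fecundity=EffectEstimate(
            0.13, -0.4, 9.0, ci_units="eggs", direction="reduction"
        ),
        adult_ce_fecundity=EffectEstimate(
            1.019, 32.2, 175.0, ci_units="percent", direction="increase"
        ),
        adult_ce_longevity=EffectEstimate(
            0.670, 9.6, 19.8, ci_units="days", direction="increase"
        ),
        target_prevalence=0.41,
    )


@dataclass(frozen=True)
class Scenario:
    """A named combination of effect pathways.

    ======  =========  =========  ========
    id      nce_larva  nce_adult  ce_adult
    ======  =========  =========  ========
    A       –          –          –
    B       –          x          –
    C       x          –          –
    D       x          x          –
    E       –          x          x
    F       x          x          x
    ======  =========  =========  ========

    A is the mite-free baseline and F the "wild" condition.  A scenario
    with CEs but no adult NCEs is deliberately absent: infected flies in
    the source experiments were always simultaneously exposed to mite
    cues, so CE-only effect sizes do not exist.
    """

    id: str
    nce_larva: bool
    nce_adult: bool
    ce_adult: bool

    def __post_init__(self) -> None:
        if self.ce_adult and not self.nce_adult:
            raise ValueError(
                "consumptive effects without adult nonconsumptive effects are "
                "not modelled (no CE-only data exist)"
            )

    @property
    def flags(self) -> tuple[bool, bool, bool]:
        return (self.nce_larva, self.nce_adult, self.ce_adult)


_SCENARIO_FLAGS = {
    "A": (False, False, False),
    "B": (False, True, False),
    "C": (True, False, False),
    "D": (True, True, False),
    "E": (False, True, True),
    "F": (True, True, True),
}

SCENARIO_IDS: tuple[str, ...] = tuple(_SCENARIO_FLAGS)


def make_scenario(id: str) -> Scenario:
    """Return the scenario with the given letter id (``"A"``–``"F"``)."""
    key = str(id).upper()
    if key not in _SCENARIO_FLAGS:
        raise ValueError(
            f"unknown scenario id {id!r}; valid ids are {', '.join(SCENARIO_IDS)}"
        )
    return Scenario(key, *_SCENARIO_FLAGS[key])


@dataclass(frozen=True)
class ExperimentDesign:
    """Replicate ensemble design: how many populations, how long, how seeded."""

    n_replicates: int = 1000
    horizon: int = 100
    n_founders: int = 50
    master_seed: int = 20240813

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if self.n_founders < 0:
            raise ValueError("n_founders must be >= 0")


def sample_effect_table(
    base: EffectTable, seed: int, baseline_scales: dict[str, float] | None = None
) -> EffectTable:
    """Draw a perturbed effect table for sensitivity analysis.

    Each effect with a non-degenerate confidence interval is replaced by
    a draw from a triangular distribution whose support is the interval
    converted to fractions (see :meth:`EffectEstimate.ci_as_fraction`)
    and whose mode is the point estimate.  Effects with zero-width
    intervals (the egg-stage zeros) are returned unchanged.  The draw is
    deterministic given ``seed``.

    ``baseline_scales`` maps effect field names to the baseline quantity
    used to convert ``days``/``eggs`` intervals into fractions; fields
    not listed default to a scale of 100 (i.e. the printed numbers are
    read as percent).
    """
    rng = np.random.default_rng(seed)
    scales = baseline_scales or {}
    updates: dict[str, EffectEstimate] = {}
    for f in fields(base):
        if f.name == "target_prevalence":
            continue
        eff: EffectEstimate = getattr(base, f.name)
        if eff.ci_width == 0:
            continue
        lo, hi = eff.ci_as_fraction(scales.get(f.name, 100.0))
        if lo == hi:
            continue
        # a CI crossing zero means the effect may be absent; the point
        # estimate itself can never flip sign, so draws clamp at 0
        point = max(0.0, float(rng.triangular(lo, eff.point, hi)))
        updates[f.name] = replace(eff, point=point)
    return replace(base, **updates)
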