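"""Comparative statistics, projection-matrix analysis, and summaries.

The headline comparison is the percent change of each scenario's
ensemble-mean final adult count against the mite-free baseline.  Extinct
replicates contribute zeros to ensemble means; dropping them would bias
the comparison toward surviving populations.

The deterministic companion to the stochastic engine is the daily
projection matrix: the linear map giving the expected next-day class
vector at infinite recruitment capacity.  Its dominant eigenvalue is the
asymptotic daily growth rate λ, and the elasticity matrix
``e_ij = (a_ij / λ) v_i w_j / <v, w>`` (with leading left/right
eigenvectors ``v``, ``w``) gives the proportional sensitivity of λ to
each transition; elasticities sum to one.  The elasticity weight on
pre-adult survival versus adult survival is the quantitative form of the
"the earlier in life an effect acts, the larger its impact" rationale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import realized_prevalence
from .engine import ReplicateSet
from .lifecycle import VitalRates
from .params import Scenario

__all__ = [
    "ScenarioSummary",
    "ProjectionAnalysis",
    "percent_change",
    "projection_matrix",
    "summarize_experiment",
    "summary_frame",
]


@dataclass(frozen=True)
class ScenarioSummary:
    scenario: Scenario
    mean_final_adults: float
    pct_change_vs_baseline: float
    realized_prevalence: float | None
    mean_trajectory: np.ndarray


def percent_change(treated: ReplicateSet, baseline: ReplicateSet) -> float:
    """Percent change of the treated ensemble-mean final adult count
    relative to the baseline's (negative = reduction)."""
    if treated.horizon != baseline.horizon:
        raise ValueError("replicate sets must share the same horizon")
    base = baseline.mean_final_adults()
    if base == 0:
        raise ValueError("baseline mean final adult count is 0; percent change undefined")
    return 100.0 * (treated.mean_final_adults() - base) / base


@dataclass(frozen=True)
class ProjectionAnalysis:
    """Daily projection matrix with growth rate and elasticities.

    ``matrix[i, j]`` is the expected contribution of one individual in
    class ``j`` today to class ``i`` tomorrow (column = today's class).
    Class order: egg ages, pre-adult ages, adult uninfected, adult
    infected.
    """

    matrix: np.ndarray
    growth_rate: float
    elasticities: np.ndarray
    class_names: tuple[str, ...]
    elasticities_reliable: bool = True


def _class_names(rates: VitalRates) -> tuple[str, ...]:
    return (
        *(f"egg_{k + 1}" for k in range(rates.egg_duration)),
        *(f"preadult_{k + 1}" for k in range(rates.preadult_duration)),
        "adult_uninfected",
        "adult_infected",
    )


def projection_matrix(rates: VitalRates) -> ProjectionAnalysis:
    """Build the expected one-day transition matrix (infinite capacity).

    The matrix mirrors the stochastic daily update in expectation:
    survival, then infection, then advancement, then reproduction by the
    post-advancement adult classes.  Newly matured adults reproduce on
    their maturation day at the uninfected rate; adults infected today
    reproduce at the infected rate.
    """
    e, d = rates.egg_duration, rates.preadult_duration
    n = e + d + 2
    iu, ii = e + d, e + d + 1  # adult class indices
    s_pre = rates.preadult_daily_survival
    s_u = rates.adult_daily_survival_uninfected
    s_i = rates.adult_daily_survival_infected
    p = rates.daily_infection_prob
    fu = rates.daily_fecundity_uninfected
    fi = rates.daily_fecundity_infected

    A = np.zeros((n, n))
    # egg aging (no within-stage mortality)
    for k in range(e - 1):
        A[k + 1, k] = 1.0
    # hatching into the first pre-adult class
    A[e, e - 1] = rates.hatch_prob
    # pre-adult survival + aging
    for k in range(d - 1):
        A[e + k + 1, e + k] = s_pre
    # maturation into the uninfected adult class
    A[iu, e + d - 1] = s_pre
    # adult survival and infection
    A[iu, iu] = s_u * (1.0 - p)
    A[ii, iu] = s_u * p
    A[ii, ii] = s_i
    # reproduction by the post-update adult classes into the first egg class
    A[0, e + d - 1] = s_pre * fu
    A[0, iu] = s_u * (1.0 - p) * fu + s_u * p * fi
    A[0, ii] = s_i * fi

    eigvals, right = np.linalg.eig(A)
    lead = int(np.argmax(np.abs(eigvals)))
    lam = float(np.abs(eigvals[lead]))
    w = np.real(right[:, lead])
    eigvals_l, left = np.linalg.eig(A.T)
    lead_l = int(np.argmin(np.abs(eigvals_l - eigvals[lead])))
    v = np.real(left[:, lead_l])
    # orient eigenvectors non-negatively
    if w.sum() < 0:
        w = -w
    if v.sum() < 0:
        v = -v

    # elasticities are meaningful when the dominant eigenvalue comes from
    # the reproductive core: the communicating class of the first egg
    # class (in scenarios without infection the infected class is
    # unreachable, which is harmless; with zero fecundity there is no
    # reproductive cycle at all and the analysis degenerates)
    adjacency = (A > 0).astype(float)
    reach = np.linalg.matrix_power(np.eye(n) + adjacency, n - 1) > 0
    core = np.flatnonzero(reach[0, :] & reach[:, 0])
    lam_core = (
        float(np.max(np.abs(np.linalg.eigvals(A[np.ix_(core, core)]))))
        if core.size > 1
        else 0.0
    )
    reliable = (
        core.size > 1
        and abs(lam_core - lam) <= 1e-9 * max(1.0, lam)
        and lam > 0
        and np.all(w > -1e-12)
        and np.all(v > -1e-12)
    )
    denom = lam * float(v @ w)
    if reliable and abs(denom) > 1e-300:
        elas = A * np.outer(v, w) / denom
        elas = np.where(np.abs(elas) < 1e-300, 0.0, elas)
    else:
        elas = np.full_like(A, np.nan)
        reliable = False
    return ProjectionAnalysis(
        matrix=A,
        growth_rate=lam,
        elasticities=elas,
        class_names=_class_names(rates),
        elasticities_reliable=bool(reliable),
    )


def summarize_experiment(
    rep_sets: dict[str, ReplicateSet] | list[ReplicateSet],
    baseline_id: str = "A",
) -> list[ScenarioSummary]:
    """One :class:`ScenarioSummary` per scenario, compared with the baseline."""
    if not isinstance(rep_sets, dict):
        rep_sets = {rs.scenario.id: rs for rs in rep_sets}
    if baseline_id not in rep_sets:
        raise ValueError(
            f"baseline scenario {baseline_id!r} missing from the replicate sets"
        )
    base = rep_sets[baseline_id]
    out = []
    for sid in sorted(rep_sets):
        rs = rep_sets[sid]
        prev = realized_prevalence(rs) if rs.scenario.ce_adult else None
        out.append(
            ScenarioSummary(
                scenario=rs.scenario,
                mean_final_adults=rs.mean_final_adults(),
                pct_change_vs_baseline=percent_change(rs, base),
                realized_prevalence=prev,
                mean_trajectory=rs.mean_trajectory(),
            )
        )
    return out


def summary_frame(summaries: list[ScenarioSummary]) -> pd.DataFrame:
    """Tabular view of the scenario summaries (one row per scenario)."""
    return pd.DataFrame(
        {
            "scenario": [s.scenario.id for s in summaries],
            "mean_final_adults": [s.mean_final_adults for s in summaries],
            "pct_change_vs_baseline": [s.pct_change_vs_baseline for s in summaries],
            "realized_prevalence": [s.realized_prevalence for s in summaries],
        }
    )
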