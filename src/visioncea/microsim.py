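"""Individual-level Monte Carlo simulator.

A brute-force cross-check of the cohort engine: individuals start in a
state drawn from the starting distribution and transition through exactly
the same per-cycle matrices (same schedule, same mortality embedding code
path), accruing discounted cost and QALYs.  By the law of large numbers the
sample means converge to the cohort engine's expectations, so agreement
within Monte Carlo error validates the trace arithmetic — accumulation,
discounting and absorption — independently of the matrix construction,
which is validated separately against the published tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import Schedule, annual_prob_to_cycle_prob, discount_factor, embed_mortality
from .parameters import (
    ArmParameters,
    LifeTable,
    ModelConfig,
    UtilityTable,
    N_VA_STATES,
    DEATH_STATE,
)

__all__ = ["MicrosimResult", "simulate_individuals"]


@dataclass
class MicrosimResult:
    """Sample means and standard errors over simulated individuals."""

    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    n: int

    def within(self, cost: float, qaly: float, n_se: float = 3.0) -> bool:
        """Do the given cohort-engine values lie within ``n_se`` standard
        errors of the simulated means?  (Degenerate SE=0 requires equality
        to float precision.)"""
        ok_c = abs(cost - self.mean_cost) <= max(n_se * self.se_cost, 1e-9 * max(abs(cost), 1))
        ok_q = abs(qaly - self.mean_qaly) <= max(n_se * self.se_qaly, 1e-12 * max(abs(qaly), 1))
        return ok_c and ok_q


def simulate_individuals(n: int, config: ModelConfig, arm: ArmParameters,
                         life: LifeTable, utilities: UtilityTable,
                         rng: np.random.Generator | int | None = None,
                         schedule: Schedule | None = None,
                         collect_occupancy: bool = False,
                         ):
    """Simulate ``n`` individual trajectories under one arm.

    Uses the same ``schedule``/``embed_mortality`` path as the cohort
    engine.  Returns a :class:`MicrosimResult`; with
    ``collect_occupancy=True`` returns ``(result, counts)`` where
    ``counts[k]`` holds per-state individual counts at the start of cycle
    ``k`` (for occupancy spot-checks).

    Half-cycle correction is not implemented here; compare against cohort
    runs with ``half_cycle_correction=False``.
    """
    if n < 1:
        raise ValueError("need at least one individual")
    if config.half_cycle_correction:
        raise ValueError("microsimulation does not support half-cycle correction")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t = config.cycle_length_years
    d = config.discount_rate_per_year
    u = utilities.utilities(config.utility_method)
    if schedule is None:
        annual_cost = arm.annual_treatment_cost() + arm.annual_background_cost(
            config.include_indirect_costs, config.indirect_annual_cost)
        entries = arm.transition.entries
        schedule = lambda k, s: (entries, annual_cost)  # noqa: E731

    if config.horizon_years is not None:
        max_cycles = int(round(config.horizon_years / t))
    else:
        max_cycles = int(np.ceil((life.max_age + 2 - config.starting_age_years) / t))

    states = rng.choice(N_VA_STATES, size=n, p=config.starting_distribution)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    occupancy_counts = []

    age = config.starting_age_years
    # cohort occupancy proxy for schedule callbacks that inspect it
    s_cohort = np.zeros(6)
    s_cohort[:N_VA_STATES] = config.starting_distribution

    for k in range(max_cycles):
        alive = states != DEATH_STATE
        if not alive.any():
            break
        if collect_occupancy:
            occupancy_counts.append(np.bincount(states, minlength=6).copy())
        q_annual = life.annual_q(age)
        q_cycle = annual_prob_to_cycle_prob(q_annual, t)
        entries, annual_cost = schedule(k, s_cohort)
        M = embed_mortality(entries, q_cycle)

        df = discount_factor(k * t, d)
        cost[alive] += df * annual_cost * t
        qaly += df * u[states] * t

        cum = M.cumsum(axis=1)
        draws = rng.random(n)
        states = np.where(alive,
                          (draws[:, None] > cum[states]).sum(axis=1),
                          DEATH_STATE)
        s_cohort = s_cohort @ M
        age += t

    result = MicrosimResult(
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        n=n,
    )
    if collect_occupancy:
        return result, np.array(occupancy_counts)
    return result
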