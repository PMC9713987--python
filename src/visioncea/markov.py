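"""Deterministic cohort engine: probability conversions, mortality embedding,
cohort trace, discounted accumulation and ICERs.

Conventions (documented, exercised in tests):

* Background mortality is embedded first each cycle: the VA row is scaled by
  the cycle survival probability and the death probability goes to the death
  column, preserving row-stochasticity.
* The life-table lookup uses floor(current age); age advances by one cycle
  length per cycle.
* Discounting applies at cycle start times ``k*t`` with annual-equivalent
  compounding ``(1+d)^(-k*t)``.
* Costs accrue as (annual figure x cycle length) while alive; the death state
  accrues zero cost and zero utility.  Half-cycle correction (off by
  default) averages adjacent-cycle occupancies for accrual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .parameters import (
    ArmParameters,
    ConfigurationError,
    LifeTable,
    MatrixValidationError,
    ModelConfig,
    TransitionMatrix,
    UtilityTable,
    N_VA_STATES,
    DEATH_STATE,
    STATE_LABELS,
    validate_matrix,
)

__all__ = [
    "annual_prob_to_cycle_prob",
    "discount_factor",
    "embed_mortality",
    "CohortTrace",
    "run_cohort",
    "accumulate",
    "CEResult",
    "compute_icer",
    "Schedule",
]

# A schedule yields, for cycle index k and current occupancy (6-vector), the
# pre-mortality 5x5 VA matrix and the annual per-alive-patient cost applying
# during that cycle.  Scenario extrapolations are expressed as schedules.
Schedule = Callable[[int, np.ndarray], tuple[np.ndarray, float]]

_ABSORPTION_TOL = 1e-9


def annual_prob_to_cycle_prob(p_annual: float, t: float) -> float:
    """Convert an annual probability to a per-cycle probability.

    Uses the constant-rate identity ``p_cycle = 1 - e^(-r t)`` with
    ``r = -ln(1 - p_annual)``, i.e. ``1 - (1 - p_annual)^t``.  Composing the
    result over ``1/t`` cycles reproduces the annual probability exactly.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"p_annual must be in [0, 1], got {p_annual}")
    if t <= 0:
        raise ValueError(f"cycle length must be positive, got {t}")
    if p_annual == 1.0:
        return 1.0
    return 1.0 - (1.0 - p_annual) ** t


def discount_factor(t_years: float, d: float) -> float:
    """Present-value factor ``(1+d)^(-t)`` at time ``t_years``."""
    if t_years < 0:
        raise ValueError("time must be nonnegative")
    if d < 0:
        raise ValueError("discount rate must be nonnegative")
    return (1.0 + d) ** (-t_years)


def embed_mortality(m: TransitionMatrix | np.ndarray, q_cycle: float) -> np.ndarray:
    """Combine a 5x5 VA matrix with a per-cycle death probability.

    Each VA row is scaled by ``1 - q_cycle`` and ``q_cycle`` placed in the
    death column; the death row is absorbing.  Output is 6x6 row-stochastic.
    """
    entries = m.entries if isinstance(m, TransitionMatrix) else np.asarray(m, float)
    violations = validate_matrix(entries)
    if violations:
        raise MatrixValidationError("embed_mortality", "; ".join(violations))
    if not 0.0 <= q_cycle <= 1.0:
        raise ValueError(f"q_cycle must be in [0, 1], got {q_cycle}")
    M = np.zeros((6, 6))
    M[:N_VA_STATES, :N_VA_STATES] = entries * (1.0 - q_cycle)
    M[:N_VA_STATES, DEATH_STATE] = q_cycle
    M[DEATH_STATE, DEATH_STATE] = 1.0
    return M


@dataclass
class CohortTrace:
    """Cycle-by-cycle record of a cohort run.

    ``occupancy[k]`` is the state distribution at the start of cycle ``k``
    (six entries summing to 1); ``occupancy_end`` is the distribution after
    the final transition.  Cost and QALY arrays hold per-cycle accruals.
    """

    ages: np.ndarray
    occupancy: np.ndarray
    occupancy_end: np.ndarray
    cost: np.ndarray
    cost_discounted: np.ndarray
    qaly: np.ndarray
    qaly_discounted: np.ndarray
    cycle_length: float
    arm_name: str = ""

    @property
    def n_cycles(self) -> int:
        return len(self.ages)

    @property
    def total_cost(self) -> float:
        return float(self.cost_discounted.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_discounted.sum())

    def alive_va_distribution(self, k: int) -> np.ndarray:
        """VA distribution at cycle k conditional on being alive."""
        s = self.occupancy[min(k, self.n_cycles - 1), :N_VA_STATES]
        total = s.sum()
        return s / total if total > 0 else s

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.occupancy,
                          columns=[f"occ[{lbl}]" for lbl in STATE_LABELS])
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(self.n_cycles))
        df["cost"] = self.cost
        df["disc_cost"] = self.cost_discounted
        df["qaly"] = self.qaly
        df["disc_qaly"] = self.qaly_discounted
        return df


def _default_schedule(arm: ArmParameters, config: ModelConfig) -> Schedule:
    annual_cost = arm.annual_treatment_cost() + arm.annual_background_cost(
        config.include_indirect_costs, config.indirect_annual_cost)
    entries = arm.transition.entries

    def schedule(k: int, occupancy: np.ndarray) -> tuple[np.ndarray, float]:
        return entries, annual_cost

    return schedule


def run_cohort(config: ModelConfig, arm: ArmParameters, life: LifeTable,
               utilities: UtilityTable, schedule: Schedule | None = None,
               ) -> CohortTrace:
    """Run the cohort model for one arm and return its full trace.

    With a lifetime horizon the run stops once death occupancy reaches
    ``1 - 1e-9`` or the cohort ages past the life-table terminal age (where
    q = 1 guarantees absorption).  ``schedule`` overrides the constant
    year-1 matrix and cost (used by scenario extrapolations).
    """
    t = config.cycle_length_years
    d = config.discount_rate_per_year
    if config.starting_age_years < life.min_age:
        raise ConfigurationError(
            f"starting age {config.starting_age_years} below life-table range")
    if schedule is None:
        schedule = _default_schedule(arm, config)
    u = utilities.utilities(config.utility_method)

    if config.horizon_years is not None:
        max_cycles = int(round(config.horizon_years / t))
        lifetime = False
    else:
        max_cycles = int(np.ceil((life.max_age + 2 - config.starting_age_years) / t))
        lifetime = True

    s = np.zeros(6)
    s[:N_VA_STATES] = config.starting_distribution
    age = config.starting_age_years

    ages, occ, costs, dcosts, qalys, dqalys = [], [], [], [], [], []
    k = 0
    while k < max_cycles:
        if lifetime and s[DEATH_STATE] >= 1.0 - _ABSORPTION_TOL:
            break
        q_annual = life.annual_q(age)
        q_cycle = annual_prob_to_cycle_prob(q_annual, t)
        entries, annual_cost = schedule(k, s)
        M = embed_mortality(entries, q_cycle)
        s_next = s @ M

        s_eff = 0.5 * (s + s_next) if config.half_cycle_correction else s
        alive = s_eff[:N_VA_STATES].sum()
        df = discount_factor(k * t, d)
        cycle_cost = alive * annual_cost * t
        cycle_qaly = float(s_eff @ u) * t

        ages.append(age)
        occ.append(s.copy())
        costs.append(cycle_cost)
        dcosts.append(df * cycle_cost)
        qalys.append(cycle_qaly)
        dqalys.append(df * cycle_qaly)

        s = s_next
        age += t
        k += 1

    return CohortTrace(
        ages=np.array(ages),
        occupancy=np.array(occ) if occ else np.zeros((0, 6)),
        occupancy_end=s,
        cost=np.array(costs),
        cost_discounted=np.array(dcosts),
        qaly=np.array(qalys),
        qaly_discounted=np.array(dqalys),
        cycle_length=t,
        arm_name=arm.name,
    )


def accumulate(trace: CohortTrace) -> tuple[float, float]:
    """Total discounted (cost, QALY) over a trace."""
    return trace.total_cost, trace.total_qaly


@dataclass
class CEResult:
    """Cost-utility comparison of a comparator against a reference arm.

    ``icer`` (euros per QALY) is populated only when the incremental cost
    and incremental QALYs share a sign; otherwise ``label`` records
    dominance ("dominant": cheaper and more effective; "dominated": costlier
    and less effective) or "undefined" when incremental QALYs are zero.
    """

    reference_arm: str
    comparator_arm: str
    cost_reference: float
    qaly_reference: float
    cost_comparator: float
    qaly_comparator: float
    delta_cost: float = field(init=False)
    delta_qaly: float = field(init=False)
    icer: float | None = field(init=False)
    label: str = field(init=False)

    def __post_init__(self):
        self.delta_cost = self.cost_comparator - self.cost_reference
        self.delta_qaly = self.qaly_comparator - self.qaly_reference
        dc, dq = self.delta_cost, self.delta_qaly
        if dq == 0:
            self.icer = None
            self.label = "undefined" if dc != 0 else "equivalent"
        elif dc < 0 and dq > 0:
            self.icer = None
            self.label = "dominant"
        elif dc > 0 and dq < 0:
            self.icer = None
            self.label = "dominated"
        else:
            self.icer = dc / dq
            self.label = "icer"

    @property
    def icer_rounded(self) -> int | None:
        return None if self.icer is None else int(round(self.icer))

    def to_dict(self) -> dict:
        return {
            "reference_arm": self.reference_arm,
            "comparator_arm": self.comparator_arm,
            "cost_reference_eur": self.cost_reference,
            "qaly_reference": self.qaly_reference,
            "cost_comparator_eur": self.cost_comparator,
            "qaly_comparator": self.qaly_comparator,
            "incremental_cost_eur": self.delta_cost,
            "incremental_qaly": self.delta_qaly,
            "icer_eur_per_qaly": self.icer,
            "label": self.label,
        }


def compute_icer(cost_ref: float, qaly_ref: float,
                 cost_new: float, qaly_new: float,
                 reference_arm: str = "reference",
                 comparator_arm: str = "comparator") -> CEResult:
    """Incremental cost-effectiveness ratio of ``new`` versus ``ref``."""
    for v in (cost_ref, qaly_ref, cost_new, qaly_new):
        if not np.isfinite(v):
            raise ValueError("cost/QALY inputs must be finite")
    return CEResult(reference_arm, comparator_arm,
                    cost_ref, qaly_ref, cost_new, qaly_new)
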