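"""Synthetic generators for inputs the published tables do not provide.

Two real-world inputs of the model are not published: the national life
table and the cohort's starting VA distribution.  This module generates
clearly-labelled synthetic stand-ins — a Gompertz–Makeham mortality
schedule and Dirichlet/preset occupancy vectors — plus fully random model
parameter sets with the same structural constraints as the published ones,
for property-based testing and sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    AdverseEvent,
    ArmParameters,
    CostItem,
    LifeTable,
    ModelConfig,
    ParameterSet,
    ParameterValidationError,
    TransitionMatrix,
    UtilityTable,
    N_VA_STATES,
    _DIST_PRESETS,
)

__all__ = [
    "GompertzSpec",
    "DEFAULT_GOMPERTZ",
    "make_life_table",
    "make_starting_distribution",
    "make_synthetic_model",
]


@dataclass(frozen=True)
class GompertzSpec:
    """Gompertz–Makeham hazard ``mu(x) = a * exp(b x) + c`` by age ``x``.

    ``a`` is the baseline hazard (per year), ``b`` the log-hazard slope per
    year of age, ``c`` an age-independent (Makeham) hazard.  Annual death
    probabilities follow from integrating the hazard over each year of age.
    """

    a: float = 2.4e-5
    b: float = 0.095
    c: float = 0.0
    start_age: int = 40
    max_age: int = 100

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0 or self.c < 0:
            raise ParameterValidationError("gompertz", "need a > 0, b > 0, c >= 0")
        if self.max_age <= self.start_age:
            raise ParameterValidationError("gompertz", "max_age must exceed start_age")


# Defaults give life expectancy ~17 years at age 68 — the right order of
# magnitude for a Western European population of that age.  Synthetic:
# never to be presented as national statistics.
DEFAULT_GOMPERTZ = GompertzSpec()


def make_life_table(spec: GompertzSpec = DEFAULT_GOMPERTZ) -> LifeTable:
    """Annual death probabilities from a Gompertz–Makeham hazard.

    ``q_x = 1 - exp(-[c + (a/b)(e^{b(x+1)} - e^{bx})])`` for integer ages;
    the final age is forced to q = 1 so cohorts always absorb.
    """
    ages = np.arange(spec.start_age, spec.max_age + 1)
    H = spec.c + (spec.a / spec.b) * (np.exp(spec.b * (ages + 1.0))
                                      - np.exp(spec.b * ages))
    qx = 1.0 - np.exp(-H)
    if np.any(qx[:-1] >= 1.0):
        bad = int(ages[:-1][qx[:-1] >= 1.0][0])
        raise ParameterValidationError(
            "gompertz", f"hazard saturates (q >= 1) already at age {bad}")
    qx[-1] = 1.0
    return LifeTable(ages, qx, source=f"synthetic Gompertz-Makeham {spec}")


def make_starting_distribution(concentration="synthetic_moderate",
                               rng: np.random.Generator | None = None,
                               ) -> np.ndarray:
    """Starting occupancy over the 5 VA states.

    ``concentration`` is a preset name ("uniform", "synthetic_moderate") or
    a positive 5-vector of Dirichlet concentrations sampled with ``rng``.
    """
    if isinstance(concentration, str):
        try:
            return np.array(_DIST_PRESETS[concentration], dtype=float)
        except KeyError:
            raise ParameterValidationError(
                "starting_distribution", f"unknown preset {concentration!r}"
            ) from None
    conc = np.asarray(concentration, dtype=float)
    if conc.shape != (N_VA_STATES,) or np.any(conc <= 0):
        raise ParameterValidationError("starting_distribution",
                                       "need 5 positive concentrations")
    if rng is None:
        rng = np.random.default_rng()
    draw = rng.dirichlet(conc)
    return draw / draw.sum()


def _random_banded_matrix(rng: np.random.Generator, decline_scale: float,
                          improve_scale: float, label: str) -> TransitionMatrix:
    """Random row-stochastic matrix with the empirical band structure:
    one-step improvement plus one- and two-step worsening, heavy diagonal."""
    m = np.zeros((N_VA_STATES, N_VA_STATES))
    for i in range(N_VA_STATES):
        improve = rng.uniform(0.0, improve_scale) if i >= 1 else 0.0
        w1 = rng.uniform(0.0, decline_scale) if i + 1 < N_VA_STATES else 0.0
        w2 = rng.uniform(0.0, decline_scale / 3) if i + 2 < N_VA_STATES else 0.0
        if i + 1 == N_VA_STATES - 1:  # worst band reachable one step down only
            w2 = 0.0
        total_off = improve + w1 + w2
        if total_off >= 0.95:  # keep diagonal dominant
            shrink = 0.95 / total_off
            improve, w1, w2 = improve * shrink, w1 * shrink, w2 * shrink
        if i >= 1:
            m[i, i - 1] = improve
        if i + 1 < N_VA_STATES:
            m[i, i + 1] = w1
        if i + 2 < N_VA_STATES:
            m[i, i + 2] = w2
        m[i, i] = 1.0 - m[i].sum()
    return TransitionMatrix(m, arm_label=label).require_valid()


def _slow_decline(base: TransitionMatrix, gap: float, label: str) -> TransitionMatrix:
    """Copy of ``base`` with every worsening probability reduced by ``gap``
    (floored at 0), the freed mass returned to the diagonal."""
    m = base.entries.copy()
    for i in range(N_VA_STATES):
        for j in (i + 1, i + 2):
            if j < N_VA_STATES and m[i, j] > 0:
                delta = min(gap, m[i, j])
                m[i, j] -= delta
                m[i, i] += delta
    return TransitionMatrix(m, arm_label=label).require_valid()


def _monotone_utilities(rng: np.random.Generator) -> UtilityTable:
    means = np.sort(rng.uniform(0.4, 0.95, N_VA_STATES))[::-1]
    spread = rng.uniform(0.03, 0.15, N_VA_STATES)
    tbl = {"mean": means, "low": np.clip(means - spread, 0, 1),
           "high": np.clip(means + spread, 0, 1.2)}
    return UtilityTable({"TTO": {k: v.copy() for k, v in tbl.items()},
                         "SG": {k: v.copy() for k, v in tbl.items()}})


def make_synthetic_model(rng: np.random.Generator | int | None = None,
                         decline_gap: float = 0.03,
                         decline_scale: float = 0.15,
                         improve_scale: float = 0.10,
                         annual_cost_scale: float = 5000.0,
                         gompertz: GompertzSpec = DEFAULT_GOMPERTZ,
                         ) -> ParameterSet:
    """Random but structurally valid two-arm model for property tests.

    The "treated" arm's worsening probabilities are those of the "reference"
    arm reduced by ``decline_gap`` per cycle (mass returned to the
    diagonal), so the treated cohort stochastically dominates the reference
    one and deterministic incremental QALYs are positive, increasing in the
    gap.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ref_tm = _random_banded_matrix(rng, decline_scale, improve_scale, "reference")
    trt_tm = _slow_decline(ref_tm, decline_gap, "treated")
    utilities = _monotone_utilities(rng)
    life = make_life_table(gompertz)

    def make_arm(name, tm, drug_cost, injections):
        item_cost = float(rng.uniform(20, 200))
        use = float(rng.uniform(2, 12))
        return ArmParameters(
            name=name, transition=tm,
            drug_unit_cost=drug_cost, drug_unit_cost_sd=0.2 * drug_cost,
            injections_per_year=injections,
            cost_items=[CostItem("monitoring_visit", item_cost, 0.2 * item_cost,
                                 use, max(use - 2, 0.5), use + 2)],
            adverse_events=[AdverseEvent("complication",
                                         float(rng.uniform(0.001, 0.02)),
                                         float(rng.uniform(1000, 4000)), 500.0)],
            other_annual_cost=float(rng.uniform(500, 2500)),
        )

    arms = {
        "reference": make_arm("reference", ref_tm,
                              float(rng.uniform(0.3, 1.0) * annual_cost_scale / 8),
                              float(rng.uniform(6, 12))),
        "treated": make_arm("treated", trt_tm,
                            float(rng.uniform(0.3, 1.0) * annual_cost_scale / 4),
                            float(rng.uniform(2, 5))),
    }
    config = ModelConfig(
        starting_distribution=make_starting_distribution(np.full(N_VA_STATES, 2.0),
                                                         rng),
        starting_distribution_source="synthetic_dirichlet",
        starting_age_years=float(rng.uniform(55, 80)),
    )
    return ParameterSet(arms=arms, utilities=utilities, life=life, config=config,
                        reference_arm="reference", comparator_arm="treated",
                        other_costs={"comorbidity_eur_2020_per_year":
                                     arms["reference"].other_annual_cost,
                                     "non_medical_eur_2020_per_year": 0.0})
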