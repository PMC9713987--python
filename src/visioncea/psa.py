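"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by Monte Carlo: each draw samples a
complete parameter set — beta-distributed transition probabilities and
utilities, gamma-distributed unit costs (20% variation coefficient), and
uniformly distributed annual resource use — runs both arms through the
deterministic cohort engine, and records the incremental cost and QALY
pair.  Summaries are the cost-effectiveness plane quadrant fractions, the
cost-effectiveness acceptability curve (CEAC) over a willingness-to-pay
grid, and per-arm absolute scatters.

Reproducibility: one master seed spawns one child seed per draw
(``numpy.random.SeedSequence``), so results are bit-identical for a given
(seed, N) independent of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import scenarios
from .parameters import ParameterSet, ParameterValidationError, TransitionMatrix, N_VA_STATES

__all__ = [
    "beta_from_moments",
    "gamma_from_cv",
    "gamma_from_moments",
    "sample_transition_row",
    "sample_parameters",
    "PSAResult",
    "run_psa",
    "ceac",
    "quadrant_fractions",
    "DEFAULT_LAMBDA_GRID",
]

logger = logging.getLogger(__name__)

# Willingness-to-pay grid: 0 to 100,000 euros/QALY in 500-euro steps,
# bracketing the 30,000 euros/QALY threshold commonly cited in Spain.
DEFAULT_LAMBDA_GRID = np.arange(0.0, 100_000.0 + 1, 500.0)

DEFAULT_COST_CV = 0.2
DEFAULT_TRANSITION_CV = 0.2


def beta_from_moments(mean: float, sd: float, name: str = "parameter",
                      ) -> tuple[float, float]:
    """Method-of-moments beta parameters for a given mean and SD.

    ``nu = mean(1-mean)/sd^2 - 1; alpha = mean*nu; beta = (1-mean)*nu``.
    Raises when the variance is infeasible for a beta on (0, 1).
    """
    if not 0.0 < mean < 1.0:
        raise ParameterValidationError(name, f"beta mean must be in (0,1), got {mean}")
    if sd <= 0:
        raise ParameterValidationError(name, "beta sd must be positive")
    if sd * sd >= mean * (1.0 - mean):
        raise ParameterValidationError(
            name, f"sd {sd} infeasible for a beta with mean {mean} "
                  f"(requires sd^2 < mean(1-mean) = {mean * (1 - mean):.4g})")
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_cv(mean: float, cv: float = DEFAULT_COST_CV) -> tuple[float, float]:
    """Gamma (shape, scale) with the given mean and variation coefficient:
    ``k = 1/cv^2``, ``theta = mean * cv^2``."""
    if mean <= 0 or cv <= 0:
        raise ValueError("mean and cv must be positive")
    return 1.0 / (cv * cv), mean * cv * cv


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) from a mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    return (mean / sd) ** 2, sd * sd / mean


def sample_transition_row(means: np.ndarray, sds: np.ndarray,
                          rng: np.random.Generator,
                          diagonal_index: int,
                          renorm_counter: list | None = None) -> np.ndarray:
    """Sample one transition row: independent betas on the nonzero
    off-diagonal entries, diagonal set to the complement.

    If the sampled off-diagonal mass exceeds 1 (negative complement), the
    whole row is renormalised; the event is counted and logged.
    """
    row = np.zeros(N_VA_STATES)
    for j in range(N_VA_STATES):
        if j == diagonal_index or means[j] == 0:
            continue
        if sds[j] == 0:
            row[j] = means[j]
        else:
            a, b = beta_from_moments(means[j], sds[j], name=f"transition[{j}]")
            row[j] = rng.beta(a, b)
    off = row.sum()
    if off <= 1.0:
        row[diagonal_index] = 1.0 - off
    else:
        row[diagonal_index] = means[diagonal_index]
        row /= row.sum()
        if renorm_counter is not None:
            renorm_counter.append(1)
    return row


def _sample_matrix(tm: TransitionMatrix, cv: float, rng: np.random.Generator,
                   renorm_counter: list) -> TransitionMatrix:
    m = np.zeros_like(tm.entries)
    for i in range(N_VA_STATES):
        means = tm.entries[i]
        sds = np.where(np.arange(N_VA_STATES) == i, 0.0, cv * means)
        m[i] = sample_transition_row(means, sds, rng, i, renorm_counter)
    return TransitionMatrix(m, arm_label=tm.arm_label)


def sample_parameters(base: ParameterSet, rng: np.random.Generator,
                      transition_cv: float = DEFAULT_TRANSITION_CV,
                      renorm_counter: list | None = None) -> ParameterSet:
    """One complete PSA draw of the uncertain parameters.

    Sampled: transition probabilities (beta, CV on off-diagonals),
    utilities of the configured method (beta from range-derived SDs, clipped
    to [0, 1]), unit costs including drug vials and comorbidity/non-medical
    annual costs (gamma, 20% CV), and annual resource use (uniform over the
    published ranges).  Adverse-event rates and injection counts stay fixed.
    """
    ps = base.copy()
    if renorm_counter is None:
        renorm_counter = []
    method = ps.config.utility_method

    # utilities: per state, independent betas; draws clipped at 1
    tbl = ps.utilities.methods[method]
    sds = ps.utilities.sampling_sd(method)
    new_means = np.empty(N_VA_STATES)
    for i in range(N_VA_STATES):
        mean = tbl["mean"][i]
        if sds[i] == 0:
            new_means[i] = mean
            continue
        a, b = beta_from_moments(mean, min(sds[i], 0.99 * np.sqrt(mean * (1 - mean))),
                                 name=f"utility[{i}]")
        new_means[i] = min(rng.beta(a, b), 1.0)
    tbl["mean"] = new_means
    tbl["low"] = np.minimum(tbl["low"], new_means)
    tbl["high"] = np.maximum(tbl["high"], new_means)

    for arm in ps.arms.values():
        arm.transition = _sample_matrix(arm.transition, transition_cv, rng,
                                        renorm_counter)
        if arm.drug_unit_cost_sd > 0:
            k, theta = gamma_from_moments(arm.drug_unit_cost,
                                          arm.drug_unit_cost_sd)
            arm.drug_unit_cost = float(rng.gamma(k, theta))
        for ci in arm.cost_items:
            if ci.unit_cost_sd > 0:
                k, theta = gamma_from_moments(ci.unit_cost, ci.unit_cost_sd)
                ci.unit_cost = float(rng.gamma(k, theta))
            ci.annual_use_mean = float(rng.uniform(ci.annual_use_low,
                                                   ci.annual_use_high))
        for ev in arm.adverse_events:
            if ev.unit_cost_sd > 0:
                k, theta = gamma_from_moments(ev.unit_cost, ev.unit_cost_sd)
                ev.unit_cost = float(rng.gamma(k, theta))
        if arm.other_annual_cost > 0:
            k, theta = gamma_from_cv(arm.other_annual_cost, DEFAULT_COST_CV)
            arm.other_annual_cost = float(rng.gamma(k, theta))
    return ps


@dataclass
class PSAResult:
    """Monte Carlo PSA output.

    Scatter arrays are aligned by draw.  ``quadrants`` maps plane quadrants
    (ΔQALY on x, ΔCost on y; the comparator relative to the reference) to
    fractions: I more costly/more effective, II more costly/less effective,
    III less costly/less effective, IV less costly/more effective.
    """

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    cost_reference: np.ndarray
    qaly_reference: np.ndarray
    cost_comparator: np.ndarray
    qaly_comparator: np.ndarray
    lambda_grid: np.ndarray
    ceac: np.ndarray
    quadrants: dict[str, float]
    seed: int
    n_draws: int
    renormalisation_fraction: float = 0.0

    def ceac_at(self, lam: float) -> float:
        """CEAC value at a willingness-to-pay (interpolating the grid)."""
        return float(np.interp(lam, self.lambda_grid, self.ceac))

    def scatter_frame(self):
        import pandas as pd

        quad = np.where(self.delta_qaly > 0,
                        np.where(self.delta_cost > 0, "I", "IV"),
                        np.where(self.delta_cost > 0, "II", "III"))
        return pd.DataFrame({
            "draw": np.arange(self.n_draws),
            "delta_cost_eur": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "quadrant": quad,
            "cost_reference_eur": self.cost_reference,
            "qaly_reference": self.qaly_reference,
            "cost_comparator_eur": self.cost_comparator,
            "qaly_comparator": self.qaly_comparator,
        })

    def ceac_frame(self):
        import pandas as pd

        return pd.DataFrame({"lambda_eur_per_qaly": self.lambda_grid,
                             "probability_comparator_optimal": self.ceac})


def ceac(delta_cost: np.ndarray, delta_qaly: np.ndarray,
         lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID) -> np.ndarray:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay λ, the fraction of draws with positive net
    monetary benefit ``λ·ΔQ − ΔC > 0``; ties count for the reference arm.
    """
    dc = np.asarray(delta_cost, float)
    dq = np.asarray(delta_qaly, float)
    if dc.size == 0:
        raise ValueError("need at least one draw")
    lam = np.asarray(lambda_grid, float)
    nmb = lam[:, None] * dq[None, :] - dc[None, :]
    return (nmb > 0).mean(axis=1)


def quadrant_fractions(delta_cost: np.ndarray, delta_qaly: np.ndarray,
                       ) -> dict[str, float]:
    """Cost-effectiveness plane quadrant fractions (sum to 1).

    Boundary convention: ΔQ > 0 counts as "more effective", ΔC > 0 as
    "more costly"; exact zeros fall to the less-favourable side for the
    comparator.
    """
    dc = np.asarray(delta_cost, float)
    dq = np.asarray(delta_qaly, float)
    n = dc.size
    more_eff = dq > 0
    more_cost = dc > 0
    return {
        "I": float((more_eff & more_cost).sum()) / n,
        "II": float((~more_eff & more_cost).sum()) / n,
        "III": float((~more_eff & ~more_cost).sum()) / n,
        "IV": float((more_eff & ~more_cost).sum()) / n,
    }


def run_psa(n_draws: int, base: ParameterSet, seed: int | None = None,
            lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
            transition_cv: float = DEFAULT_TRANSITION_CV) -> PSAResult:
    """Monte Carlo PSA: ``n_draws`` sampled parameter sets, each run
    deterministically through both arms.

    Fully reproducible from ``seed`` (defaults to the configured seed): a
    per-draw child seed sequence drives every sampled quantity.
    """
    if n_draws < 1:
        raise ValueError("need at least one draw")
    if seed is None:
        seed = base.config.seed
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_draws)

    dc = np.empty(n_draws)
    dq = np.empty(n_draws)
    c_ref = np.empty(n_draws)
    q_ref = np.empty(n_draws)
    c_cmp = np.empty(n_draws)
    q_cmp = np.empty(n_draws)
    renorm: list = []

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        ps = sample_parameters(base, rng, transition_cv, renorm)
        res = scenarios.evaluate(ps)
        dc[i] = res.delta_cost
        dq[i] = res.delta_qaly
        c_ref[i] = res.cost_reference
        q_ref[i] = res.qaly_reference
        c_cmp[i] = res.cost_comparator
        q_cmp[i] = res.qaly_comparator

    n_rows_sampled = n_draws * 2 * N_VA_STATES
    renorm_frac = len(renorm) / n_rows_sampled
    if renorm:
        logger.info("PSA: %d of %d sampled transition rows renormalised "
                    "(%.3f%%)", len(renorm), n_rows_sampled, 100 * renorm_frac)

    return PSAResult(
        delta_cost=dc, delta_qaly=dq,
        cost_reference=c_ref, qaly_reference=q_ref,
        cost_comparator=c_cmp, qaly_comparator=q_cmp,
        lambda_grid=np.asarray(lambda_grid, float),
        ceac=ceac(dc, dq, lambda_grid),
        quadrants=quadrant_fractions(dc, dq),
        seed=seed, n_draws=n_draws,
        renormalisation_fraction=renorm_frac,
    )
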