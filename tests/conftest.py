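import numpy as np
import pytest
from hypothesis import settings

import visioncea as v

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference_ps():
    """Bundled published inputs with the synthetic life table."""
    return v.load_reference_parameters()


@pytest.fixture(scope="session")
def reconciled_ps(reference_ps):
    """Published inputs with the injection counts exchanged between arms,
    the configuration in which the comparator is the dearer arm and
    positive ICERs exist."""
    return v.cost_ordering_reconciliation(reference_ps)


@pytest.fixture()
def synthetic_ps():
    return v.make_synthetic_model(np.random.default_rng(42))


def make_degenerate_ps(utility: float = 0.85, horizon_years: float = 1.0,
                       discount: float = 0.0, annual_q: float = 0.0,
                       annual_cost: float = 0.0, start_age: float = 68.0,
                       max_age: int = 120):
    """Single-state degenerate model: identity transitions, all mass in the
    best VA state, constant mortality, flat utility — closed-form outcomes."""
    tm = v.TransitionMatrix(np.eye(5), arm_label="degenerate")
    arm = v.ArmParameters(
        name="degenerate", transition=tm,
        drug_unit_cost=max(annual_cost, 1e-9), drug_unit_cost_sd=0.0,
        injections_per_year=1.0, cost_items=[], adverse_events=[],
        other_annual_cost=0.0, rehab_annual_cost=0.0, equipment_annual_cost=0.0)
    means = np.full(5, utility)
    util = v.UtilityTable({m: {"mean": means.copy(), "low": means - 0.0,
                               "high": means + 0.0} for m in ("TTO", "SG")})
    ages = np.arange(int(start_age), max_age + 1)
    qx = np.full(ages.shape, annual_q, dtype=float)
    qx[-1] = 1.0
    life = v.LifeTable(ages, qx, source="constant-hazard test table")
    dist = np.zeros(5)
    dist[0] = 1.0
    config = v.ModelConfig(horizon_years=horizon_years,
                           discount_rate_per_year=discount,
                           starting_age_years=start_age,
                           starting_distribution=dist,
                           starting_distribution_source="degenerate")
    return config, arm, life, util
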