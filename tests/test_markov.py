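"""Cohort engine: probability conversions, mortality embedding, traces,
discounting, accumulation and ICER labelling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import visioncea as v
from visioncea.markov import run_cohort
from tests.conftest import make_degenerate_ps


class TestProbabilityConversion:
    @pytest.mark.parametrize("p_annual, t, expected", [
        (0.0, 0.25, 0.0),
        (0.3, 1.0, 0.3),
        (0.7, 1.0, 0.7),
        # 1 - exp(-(-ln 0.7) * 0.25) evaluated independently
        (0.3, 0.25, 0.0853088),
        (1.0, 0.25, 1.0),
    ])
    def test_values(self, p_annual, t, expected):
        assert v.annual_prob_to_cycle_prob(p_annual, t) == pytest.approx(
            expected, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            v.annual_prob_to_cycle_prob(1.2, 0.25)
        with pytest.raises(ValueError):
            v.annual_prob_to_cycle_prob(-0.1, 0.25)
        with pytest.raises(ValueError):
            v.annual_prob_to_cycle_prob(0.5, 0.0)

    @given(st.floats(min_value=0.0, max_value=0.999999))
    @settings(max_examples=50, deadline=None)
    def test_four_quarter_cycles_recompose_annual(self, p):
        """Survival over four 3-month cycles equals annual survival to 1e-12."""
        q = v.annual_prob_to_cycle_prob(p, 0.25)
        recomposed = 1.0 - (1.0 - q) ** 4
        assert recomposed == pytest.approx(p, abs=1e-12)


class TestDiscountFactor:
    def test_values(self):
        assert v.discount_factor(5.0, 0.0) == 1.0
        assert v.discount_factor(0.0, 0.035) == 1.0
        assert v.discount_factor(1.0, 0.035) == pytest.approx(1 / 1.035)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            v.discount_factor(-1.0, 0.035)


class TestEmbedMortality:
    def test_zero_mortality_preserves_matrix(self, reference_ps):
        m = reference_ps.arms["aflibercept"].transition
        M = v.embed_mortality(m, 0.0)
        np.testing.assert_array_equal(M[:5, :5], m.entries)
        np.testing.assert_array_equal(M[:, 5], [0, 0, 0, 0, 0, 1])

    def test_certain_death(self, reference_ps):
        M = v.embed_mortality(reference_ps.arms["dexamethasone"].transition, 1.0)
        np.testing.assert_array_equal(M[:, 5], np.ones(6))
        np.testing.assert_array_equal(M[:5, :5], np.zeros((5, 5)))

    def test_scales_row_by_survival(self, reference_ps):
        """First comparator row at 1% cycle mortality: printed row x 0.99."""
        M = v.embed_mortality(reference_ps.arms["dexamethasone"].transition, 0.01)
        np.testing.assert_allclose(
            M[0], [0.976437, 0.010593, 0.002970, 0.0, 0.0, 0.01], atol=1e-12)

    def test_row_stochastic_output(self, reference_ps):
        for q in (0.0, 0.013, 0.5, 1.0):
            M = v.embed_mortality(reference_ps.arms["aflibercept"].transition, q)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_matrix_rejected(self):
        bad = np.full((5, 5), 0.2)  # stochastic but off-band
        with pytest.raises(v.MatrixValidationError):
            v.embed_mortality(bad, 0.01)


class TestRunCohort:
    def test_degenerate_qaly_is_utility_times_horizon(self):
        """No death, no movement, no discounting: Q = u * T exactly."""
        config, arm, life, util = make_degenerate_ps(
            utility=0.85, horizon_years=1.0, discount=0.0)
        trace = run_cohort(config, arm, life, util)
        assert trace.total_qaly == pytest.approx(0.85, abs=1e-12)

    def test_forty_year_degenerate(self):
        config, arm, life, util = make_degenerate_ps(
            utility=0.85, horizon_years=40.0, discount=0.0, start_age=50)
        trace = run_cohort(config, arm, life, util)
        assert trace.total_qaly == pytest.approx(34.0, abs=1e-9)

    def test_immediate_absorption_under_certain_death(self):
        config, arm, life, util = make_degenerate_ps(
            utility=0.85, horizon_years=2.0, discount=0.0, annual_q=1.0)
        trace = run_cohort(config, arm, life, util)
        # utility accrues during the first cycle only
        assert trace.total_qaly == pytest.approx(0.85 * 0.25, abs=1e-12)
        assert trace.occupancy[1, 5] == pytest.approx(1.0)

    def test_zero_cost_schedule_gives_zero_cost(self):
        config, arm, life, util = make_degenerate_ps(annual_cost=0.0)
        trace = run_cohort(config, arm, life, util,
                           schedule=lambda k, s: (np.eye(5), 0.0))
        assert trace.total_cost == 0.0

    def test_conservation_and_death_monotone(self, reference_ps):
        for arm in reference_ps.arms.values():
            trace = run_cohort(reference_ps.config, arm, reference_ps.life,
                               reference_ps.utilities)
            occ_sums = trace.occupancy.sum(axis=1)
            np.testing.assert_allclose(occ_sums, 1.0, atol=1e-9)
            death = trace.occupancy[:, 5]
            assert np.all(np.diff(death) >= -1e-12)
            assert trace.occupancy_end[5] >= 1.0 - 1e-9

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_conservation_on_random_models(self, seed):
        ps = v.make_synthetic_model(np.random.default_rng(seed))
        trace = run_cohort(ps.config, ps.arms["treated"], ps.life, ps.utilities)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(trace.occupancy[:, 5]) >= -1e-12)
        assert trace.total_cost >= 0 and trace.total_qaly >= 0

    def test_qaly_bounded_by_horizon_times_max_utility(self, reference_ps):
        config = reference_ps.config.replace(horizon_years=10.0)
        trace = run_cohort(config, reference_ps.arms["dexamethasone"],
                           reference_ps.life, reference_ps.utilities)
        assert trace.total_qaly <= 10.0 * 0.85 + 1e-9

    def test_annuity_closed_form_limit(self):
        """Constant annual mortality q, no VA dynamics: discounted life-years
        agree with the continuous annuity integral_0^T e^{-(mu+delta)s} ds
        (mu = -ln(1-q), delta = ln(1+d)) within 1% at 3-month cycles."""
        q, d, T = 0.02, 0.035, 40.0
        config, arm, life, util = make_degenerate_ps(
            utility=1.0, horizon_years=T, discount=d, annual_q=q,
            start_age=50, max_age=120)
        trace = run_cohort(config, arm, life, util)
        rho = -np.log(1 - q) + np.log(1 + d)
        analytic = (1 - np.exp(-rho * T)) / rho
        assert trace.total_qaly == pytest.approx(analytic, rel=0.01)

    def test_half_cycle_correction_shrinks_outcomes(self, reference_ps):
        """Averaging adjacent occupancies counts deaths half a cycle earlier,
        so QALYs (and costs) decrease slightly."""
        arm = reference_ps.arms["aflibercept"]
        base = run_cohort(reference_ps.config, arm, reference_ps.life,
                          reference_ps.utilities)
        hcc = run_cohort(reference_ps.config.replace(half_cycle_correction=True),
                         arm, reference_ps.life, reference_ps.utilities)
        assert hcc.total_qaly < base.total_qaly
        assert abs(hcc.total_qaly - base.total_qaly) / base.total_qaly < 0.05

    def test_starting_age_below_table_raises(self, reference_ps):
        config = reference_ps.config.replace(starting_age_years=30.0)
        with pytest.raises(v.ConfigurationError):
            run_cohort(config, reference_ps.arms["aflibercept"],
                       reference_ps.life, reference_ps.utilities)

    def test_discount_identity_at_zero_rate(self, reference_ps):
        config = reference_ps.config.replace(discount_rate_per_year=0.0)
        trace = run_cohort(config, reference_ps.arms["dexamethasone"],
                           reference_ps.life, reference_ps.utilities)
        assert trace.total_qaly == pytest.approx(float(trace.qaly.sum()), abs=1e-9)
        assert trace.total_cost == pytest.approx(float(trace.cost.sum()), abs=1e-6)


class TestComputeIcer:
    def test_printed_increments_reproduce_printed_icer(self):
        res = v.compute_icer(0.0, 0.0, 77_349.0, 2.667)
        assert res.icer_rounded == 29_002

    def test_printed_totals_agree_within_rounding(self):
        res = v.compute_icer(92_340.0, 4.134, 169_689.0, 6.80)
        assert res.delta_cost == pytest.approx(77_349.0)
        # per-arm QALYs are printed at coarser precision; the ratio must fall
        # inside the band implied by that rounding
        assert 28_950 < res.icer < 29_075

    def test_dominant_label(self):
        res = v.compute_icer(100.0, 1.0, 90.0, 2.0)
        assert res.label == "dominant" and res.icer is None

    def test_dominated_label(self):
        res = v.compute_icer(90.0, 2.0, 100.0, 1.0)
        assert res.label == "dominated" and res.icer is None

    def test_undefined_when_no_qaly_difference(self):
        res = v.compute_icer(100.0, 1.0, 150.0, 1.0)
        assert res.label == "undefined" and res.icer is None
        assert res.delta_cost == 50.0

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            v.compute_icer(np.nan, 1.0, 2.0, 3.0)


def test_trace_export_columns(reference_ps):
    trace = run_cohort(reference_ps.config, reference_ps.arms["aflibercept"],
                       reference_ps.life, reference_ps.utilities)
    df = trace.to_dataframe()
    assert {"cycle", "age", "disc_cost", "disc_qaly"} <= set(df.columns)
    assert len(df) == trace.n_cycles
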