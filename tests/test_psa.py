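"""Distribution fitting, parameter sampling, Monte Carlo propagation,
CEAC and quadrant summaries."""

import numpy as np
import pytest

import visioncea as v
from visioncea.psa import (
    DEFAULT_LAMBDA_GRID,
    beta_from_moments,
    ceac,
    gamma_from_cv,
    gamma_from_moments,
    quadrant_fractions,
    run_psa,
    sample_parameters,
    sample_transition_row,
)


class TestBetaFromMoments:
    def test_uniform_special_case(self):
        a, b = beta_from_moments(0.5, np.sqrt(1 / 12))
        assert a == pytest.approx(1.0, abs=1e-12)
        assert b == pytest.approx(1.0, abs=1e-12)

    def test_utility_like_parameters(self):
        a, b = beta_from_moments(0.85, 0.05)
        assert (a, b) == (pytest.approx(42.5), pytest.approx(7.5))

    def test_infeasible_variance_names_parameter(self):
        with pytest.raises(v.ParameterValidationError, match="my_param"):
            beta_from_moments(0.5, 0.6, name="my_param")

    def test_moment_recovery(self):
        rng = np.random.default_rng(11)
        a, b = beta_from_moments(0.78, 0.03)
        draws = rng.beta(a, b, 100_000)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.78) < 3 * se
        assert draws.std(ddof=1) == pytest.approx(0.03, rel=0.05)


class TestGamma:
    def test_cv_parameterisation(self):
        k, theta = gamma_from_cv(112.0, 0.2)
        assert (k, theta) == (pytest.approx(25.0), pytest.approx(4.48))
        # shape depends only on the variation coefficient
        assert gamma_from_cv(3702.0, 0.2)[0] == pytest.approx(25.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gamma_from_cv(-10.0, 0.2)
        with pytest.raises(ValueError):
            gamma_from_moments(112.0, 0.0)

    def test_moment_recovery(self):
        rng = np.random.default_rng(12)
        k, theta = gamma_from_cv(112.0, 0.2)
        draws = rng.gamma(k, theta, 100_000)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 112.0) < 3 * se
        assert draws.std(ddof=1) / draws.mean() == pytest.approx(0.2, rel=0.05)


class TestSampleTransitionRow:
    def test_zero_sd_returns_printed_row(self, reference_ps):
        means = reference_ps.arms["dexamethasone"].transition.entries[0]
        row = sample_transition_row(means, np.zeros(5),
                                    np.random.default_rng(0), 0)
        np.testing.assert_allclose(row, means, atol=1e-15)

    def test_rows_always_stochastic(self, reference_ps):
        rng = np.random.default_rng(5)
        means = reference_ps.arms["aflibercept"].transition.entries[1]
        sds = 0.2 * means
        sds[1] = 0.0
        for _ in range(200):
            row = sample_transition_row(means, sds, rng, 1)
            assert row.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(row >= 0)

    def test_sample_means_match_printed_row(self, reference_ps):
        """10^5 draws of the comparator's first row recover the printed
        off-diagonal means within 3 standard errors."""
        rng = np.random.default_rng(99)
        means = reference_ps.arms["dexamethasone"].transition.entries[0]
        sds = 0.2 * means
        sds[0] = 0.0
        n = 100_000
        draws = np.array([sample_transition_row(means, sds, rng, 0)
                          for _ in range(n)])
        for j in (1, 2):
            se = draws[:, j].std(ddof=1) / np.sqrt(n)
            assert abs(draws[:, j].mean() - means[j]) < 3 * se


class TestSampleParameters:
    def test_sampled_matrices_valid_and_utilities_clipped(self, reference_ps):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ps = sample_parameters(reference_ps, rng)
            for arm in ps.arms.values():
                assert v.validate_matrix(arm.transition) == []
            u = ps.utilities.utilities(ps.config.utility_method)
            assert np.all(u <= 1.0) and np.all(u >= 0.0)

    def test_sg_draws_clipped_at_one(self, reference_ps):
        ps0 = reference_ps.copy()
        ps0.config = ps0.config.replace(utility_method="SG")
        rng = np.random.default_rng(8)
        maxima = [sample_parameters(ps0, rng).utilities.utilities("SG").max()
                  for _ in range(50)]
        assert max(maxima) <= 1.0

    def test_base_untouched(self, reference_ps):
        before = reference_ps.arms["aflibercept"].transition.entries.copy()
        sample_parameters(reference_ps, np.random.default_rng(1))
        np.testing.assert_array_equal(
            reference_ps.arms["aflibercept"].transition.entries, before)

    def test_resource_use_within_published_ranges(self, reference_ps):
        rng = np.random.default_rng(21)
        for _ in range(20):
            ps = sample_parameters(reference_ps, rng)
            for arm in ps.arms.values():
                for ci in arm.cost_items:
                    assert ci.annual_use_low <= ci.annual_use_mean <= ci.annual_use_high


class TestCeac:
    def test_zero_lambda_is_cost_saving_probability(self):
        dc = np.array([-10.0, 5.0, -3.0, 8.0])
        dq = np.array([1.0, 1.0, -1.0, -1.0])
        assert ceac(dc, dq, np.array([0.0]))[0] == 0.5

    def test_infinite_lambda_is_effect_probability(self):
        dc = np.array([-10.0, 5.0, -3.0, 8.0])
        dq = np.array([1.0, 1.0, -1.0, -0.5])
        assert ceac(dc, dq, np.array([1e12]))[0] == 0.5

    def test_step_at_deterministic_icer(self):
        dc = np.full(100, 1000.0)
        dq = np.full(100, 1.0)
        grid = np.array([0.0, 999.0, 1000.0, 1001.0])
        np.testing.assert_array_equal(ceac(dc, dq, grid), [0, 0, 0, 1])

    def test_requires_points(self):
        with pytest.raises(ValueError):
            ceac(np.array([]), np.array([]))


def test_quadrant_fractions_sum_to_one():
    rng = np.random.default_rng(4)
    dc, dq = rng.normal(size=500), rng.normal(size=500)
    q = quadrant_fractions(dc, dq)
    assert sum(q.values()) == pytest.approx(1.0, abs=1e-12)
    assert all(0 <= f <= 1 for f in q.values())


class TestRunPsa:
    def test_single_zero_variance_draw_equals_deterministic(self, reference_ps):
        """With every SD and range collapsed, the PSA scatter point is the
        deterministic result."""
        ps = reference_ps.copy()
        for arm in ps.arms.values():
            arm.drug_unit_cost_sd = 0.0
            for ci in arm.cost_items:
                ci.unit_cost_sd = 0.0
                ci.annual_use_low = ci.annual_use_high = ci.annual_use_mean
            for ev in arm.adverse_events:
                ev.unit_cost_sd = 0.0
            arm.other_annual_cost = 0.0
        for meth in ps.utilities.methods.values():
            meth["low"] = meth["mean"].copy()
            meth["high"] = meth["mean"].copy()
        det = v.evaluate(ps)
        res = run_psa(1, ps, seed=123, transition_cv=0.0)
        assert res.delta_cost[0] == pytest.approx(det.delta_cost, abs=1e-9)
        assert res.delta_qaly[0] == pytest.approx(det.delta_qaly, abs=1e-12)

    def test_seeded_bit_reproducibility(self, reference_ps):
        a = run_psa(40, reference_ps, seed=777)
        b = run_psa(40, reference_ps, seed=777)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)
        np.testing.assert_array_equal(a.ceac, b.ceac)
        assert a.quadrants == b.quadrants

    def test_quadrants_and_ceac_consistent(self, reconciled_ps):
        """CEAC(lambda) equals the fraction of draws that are dominant
        (quadrant IV), plus quadrant-I draws with ICER below lambda, plus
        quadrant-III draws with ICER above lambda."""
        res = run_psa(150, reconciled_ps, seed=5)
        lam = 30_000.0
        dc, dq = res.delta_cost, res.delta_qaly
        expected = float(np.mean(
            ((dq > 0) & (dc <= 0))
            | ((dq > 0) & (dc > 0) & (dc / dq < lam))
            | ((dq <= 0) & (dc <= 0) & (dc < lam * dq))))
        assert res.ceac_at(lam) == pytest.approx(expected, abs=1e-9)
        assert sum(res.quadrants.values()) == pytest.approx(1.0)

    def test_mean_parameter_link_to_deterministic(self, reference_ps):
        """Running the deterministic model at the base (mean) parameters is
        exactly the deterministic reference result — the PSA never alters
        the base set."""
        before = v.evaluate(reference_ps).to_dict()
        run_psa(25, reference_ps, seed=9)
        after = v.evaluate(reference_ps).to_dict()
        assert before == after

    def test_scatter_and_ceac_frames(self, reference_ps):
        res = run_psa(10, reference_ps, seed=2)
        sf = res.scatter_frame()
        assert len(sf) == 10
        assert set(sf["quadrant"]) <= {"I", "II", "III", "IV"}
        cf = res.ceac_frame()
        assert len(cf) == len(DEFAULT_LAMBDA_GRID)
        assert cf["probability_comparator_optimal"].between(0, 1).all()
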