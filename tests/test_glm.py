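import numpy as np
import pytest
from scipy import special

from gammapac import (
    design_matrix, fit, fit_alpha, fit_weights,
    negative_log_likelihood, pnnll, select_order,
)
from conftest import draw_glm_data


def eq8_objective(w, y, theta):
    K = (len(w) - 1) // 2
    L = design_matrix(theta, K).matrix @ np.asarray(w)
    return float(np.sum(y * np.exp(-L) + L))


def eq9_objective(alpha, y, L):
    return float(np.sum(special.gammaln(alpha) - (alpha - 1) * np.log(y)
                        + alpha * y * np.exp(-L) + alpha * L
                        - alpha * np.log(alpha)))


class TestDesignMatrix:
    def test_intercept_only(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 17)
        d = design_matrix(theta, 0)
        assert d.matrix.shape == (17, 1)
        assert np.all(d.matrix == 1.0)

    def test_k1_at_zero_phase(self):
        assert np.allclose(design_matrix([0.0], 1).matrix, [[1.0, 1.0, 0.0]])

    def test_orthogonality_on_uniform_grid(self):
        theta = -np.pi + 2 * np.pi * np.arange(1024) / 1024
        R = design_matrix(theta, 2).matrix
        R = R / np.linalg.norm(R, axis=0)
        gram = R.T @ R
        assert np.max(np.abs(gram - np.eye(5))) < 1e-10

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            design_matrix([0.0], -1)


class TestNegativeLogLikelihood:
    def test_exponential_unit_case(self):
        # y=1, K=0, w=[0], alpha=1: logGamma(1)=0, L=0, term = y = 1
        assert np.isclose(
            negative_log_likelihood([1.0], [0.3], [0.0], 1.0), 1.0)

    def test_matches_termwise_density(self, rng):
        y, theta = draw_glm_data(rng, [0.2, 0.4, -0.1], 2.0, 200)
        w, alpha = np.array([0.1, 0.3, 0.2]), 2.7
        L = design_matrix(theta, 1).matrix @ w
        rate = alpha * np.exp(-L)
        logpdf = (alpha * np.log(rate) - special.gammaln(alpha)
                  + (alpha - 1) * np.log(y) - rate * y)
        assert np.isclose(negative_log_likelihood(y, theta, w, alpha),
                          -np.sum(logpdf), atol=1e-10)

    def test_partial_objective_identity(self, rng):
        # NLL(a,w1) - NLL(a,w2) = a * (obj(w1) - obj(w2))
        y, theta = draw_glm_data(rng, [0.0, 0.5, 0.0], 3.0, 500)
        alpha = 1.8
        w1, w2 = np.array([0.2, 0.1, -0.3]), np.array([-0.1, 0.4, 0.2])
        lhs = (negative_log_likelihood(y, theta, w1, alpha)
               - negative_log_likelihood(y, theta, w2, alpha))
        rhs = alpha * (eq8_objective(w1, y, theta) - eq8_objective(w2, y, theta))
        assert np.isclose(lhs, rhs, rtol=1e-10)

    def test_rejects_nonpositive_amplitude(self):
        with pytest.raises(ValueError):
            negative_log_likelihood([0.0, 1.0], [0.1, 0.2], [0.0], 1.0)


class TestFitWeights:
    def test_constant_amplitude_closed_form(self):
        c = 3.7
        w = fit_weights(np.full(200, c), np.linspace(-3, 3, 200), 0)
        assert np.isclose(w[0], np.log(c), atol=1e-8)

    def test_parameter_recovery(self, rng):
        w_true = np.array([0.5, 0.3, -0.2])
        y, theta = draw_glm_data(rng, w_true, 3.0, 20_000)
        w = fit_weights(y, theta, 1)
        assert np.all(np.abs(w - w_true) < 0.05)

    def test_beats_random_search(self, rng):
        y, theta = draw_glm_data(rng, [0.2, 0.4, 0.1], 2.0, 2_000)
        w = fit_weights(y, theta, 1)
        f_star = eq8_objective(w, y, theta)
        box = rng.uniform(-0.5, 0.5, size=(10_000, 3)) + w
        f_rand = min(eq8_objective(b, y, theta) for b in box)
        assert f_star <= f_rand + 1e-9

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_weights(np.ones(3), np.zeros(3), 1)


class TestFitAlpha:
    @pytest.mark.parametrize("shape,lo,hi", [(1.0, 0.97, 1.03),
                                             (5.0, 4.8, 5.2)])
    def test_shape_recovery(self, rng, shape, lo, hi):
        y = rng.gamma(shape, 1.0 / shape, size=50_000)
        w = fit_weights(y, rng.uniform(-np.pi, np.pi, y.size), 0)
        alpha = fit_alpha(y, np.zeros(y.size), w)
        assert lo < alpha < hi

    def test_agrees_with_grid_search(self, rng):
        y, theta = draw_glm_data(rng, [0.1, 0.3, 0.0], 2.5, 5_000)
        w = fit_weights(y, theta, 1)
        L = design_matrix(theta, 1).matrix @ w
        alpha = fit_alpha(y, theta, w)
        grid = np.linspace(1e-3, 100.0, 100_000)
        vals = [eq9_objective(a, y, L) for a in
                grid[np.abs(grid - alpha) < 0.5]]
        a_grid = grid[np.abs(grid - alpha) < 0.5][int(np.argmin(vals))]
        assert np.isclose(alpha, a_grid, rtol=5e-4)

    def test_stationarity_condition(self, rng):
        y, theta = draw_glm_data(rng, [0.0, 0.2, 0.1], 3.0, 5_000)
        w = fit_weights(y, theta, 1)
        L = design_matrix(theta, 1).matrix @ w
        alpha = fit_alpha(y, theta, w)
        lhs = special.digamma(alpha) - np.log(alpha)
        rhs = np.mean(np.log(y) - L - y * np.exp(-L)) + 1.0
        assert np.isclose(lhs, rhs, atol=1e-9)

    def test_degenerate_constant_amplitude_warns(self):
        with pytest.warns(UserWarning):
            fit_alpha(np.full(100, 2.0), np.zeros(100), [np.log(2.0)])


class TestFit:
    def test_intercept_reproduces_sample_mean(self, rng):
        y = rng.gamma(4.0, 0.5, size=5_000)
        m = fit(y, rng.uniform(-np.pi, np.pi, y.size), 0)
        assert np.isclose(np.exp(m.w[0]), y.mean(), rtol=0.01)

    def test_deterministic_refit(self, rng):
        y, theta = draw_glm_data(rng, [0.1, 0.2, -0.1], 2.0, 1_000)
        m1, m2 = fit(y, theta, 1), fit(y, theta, 1)
        assert np.array_equal(m1.w, m2.w) and m1.alpha == m2.alpha

    def test_scale_equivariance(self, rng):
        y, theta = draw_glm_data(rng, [0.3, 0.4, 0.1], 3.0, 5_000)
        m1, m2 = fit(y, theta, 1), fit(10.0 * y, theta, 1)
        assert np.isclose(m2.w[0] - m1.w[0], np.log(10.0), atol=1e-5)
        assert np.allclose(m2.w[1:], m1.w[1:], atol=1e-5)
        assert np.isclose(m2.alpha, m1.alpha, rtol=1e-4)

    def test_phase_shift_equivariance(self, rng):
        from gammapac import wrap_phase
        y, theta = draw_glm_data(rng, [0.2, 0.5, 0.0], 3.0, 10_000)
        delta = 1.1
        m1 = fit(y, theta, 2)
        m2 = fit(y, wrap_phase(theta + delta), 2)
        grid = np.linspace(-np.pi, np.pi, 64, endpoint=False)
        assert np.allclose(m1.mean(grid), m2.mean(wrap_phase(grid + delta)),
                           rtol=1e-3)

    def test_convexity_along_random_segments(self, rng):
        y, theta = draw_glm_data(rng, [0.1, 0.3, -0.2], 2.0, 500)
        for _ in range(10):
            w1 = rng.normal(scale=0.5, size=3)
            w2 = rng.normal(scale=0.5, size=3)
            mid = eq8_objective((w1 + w2) / 2, y, theta)
            assert mid <= (eq8_objective(w1, y, theta)
                           + eq8_objective(w2, y, theta)) / 2 + 1e-9
        L = design_matrix(theta, 1).matrix @ np.array([0.1, 0.3, -0.2])
        for _ in range(10):
            a1, a2 = rng.uniform(0.1, 20.0, size=2)
            mid = eq9_objective((a1 + a2) / 2, y, L)
            assert mid <= (eq9_objective(a1, y, L)
                           + eq9_objective(a2, y, L)) / 2 + 1e-9


class TestSelectOrder:
    def test_singleton_candidate_forced(self, rng):
        y, theta = draw_glm_data(rng, [0.1, 0.2, 0.1], 2.0, 500)
        assert select_order(y, theta, [3]).chosen_K == 3

    def test_empty_candidates_rejected(self, rng):
        y, theta = draw_glm_data(rng, [0.1], 2.0, 100, K=0)
        with pytest.raises(ValueError):
            select_order(y, theta, [])

    def test_nll_nonincreasing_in_k(self, rng):
        y, theta = draw_glm_data(rng, [0.2, 0.4, 0.2], 3.0, 2_000)
        report = select_order(y, theta, range(4))
        nlls = [report.models[k].nll for k in report.candidates]
        assert np.all(np.diff(nlls) <= 1e-6 * np.abs(nlls[0]))

    def test_recovers_true_order_and_null(self, rng):
        # reduced version of the selection-consistency experiment
        hits = 0
        for _ in range(10):
            y, theta = draw_glm_data(rng, [0.3, 0.6, 0.3, 0.4, -0.3], 3.0,
                                     10_000)
            hits += select_order(y, theta, range(6)).chosen_K == 2
        assert hits >= 9
        nulls = 0
        for _ in range(10):
            theta = rng.uniform(-np.pi, np.pi, 10_000)
            y = rng.gamma(3.0, 1.0 / 3.0, size=10_000)
            nulls += select_order(y, theta, range(6)).chosen_K == 0
        assert nulls >= 9

    def test_pnnll_formula(self):
        assert np.isclose(pnnll(100.0, 2, 1000),
                          0.1 + 5 / 2000 * np.log(1000))
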