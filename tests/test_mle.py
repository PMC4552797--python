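"""Newton-Raphson maximum likelihood: score, Hessian, fit, surfaces, SEs."""

import math

import numpy as np
import pytest

from cohortkin import (
    CohortData,
    WeibullParams,
    hessian,
    initialize_params,
    log_likelihood,
    negative_log_likelihood,
    newton_raphson_fit,
    nll_surface,
    pdf,
    profile_nll,
    sample,
    score,
    standard_errors,
)


def fd_score(p, x, rel=1e-6):
    """Central finite differences of the log-likelihood."""
    a, b = p.alpha, p.beta
    ha, hb = rel * a, rel * b

    def f(aa, bb):
        return log_likelihood(WeibullParams(aa, bb), x)

    return np.array(
        [
            (f(a + ha, b) - f(a - ha, b)) / (2 * ha),
            (f(a, b + hb) - f(a, b - hb)) / (2 * hb),
        ]
    )


def fd_hessian(p, x, rel=1e-6):
    """Central finite differences of the analytic score."""
    a, b = p.alpha, p.beta
    ha, hb = rel * a, rel * b
    da = (score(WeibullParams(a + ha, b), x) - score(WeibullParams(a - ha, b), x)) / (2 * ha)
    db = (score(WeibullParams(a, b + hb), x) - score(WeibullParams(a, b - hb), x)) / (2 * hb)
    return np.column_stack([da, db])


class TestLogLikelihood:
    def test_single_point_closed_form(self):
        # x = alpha, beta = 1: log f = log(1/alpha) - 1
        a = 0.7
        ll = log_likelihood(WeibullParams(a, 1.0), np.array([a]))
        assert ll == pytest.approx(math.log(1 / a) - 1, abs=1e-12)

    def test_expansion_equals_summed_log_densities(self, random_param_data):
        p, x = random_param_data(4, n=20)
        direct = float(np.sum(np.log(pdf(p, x))))
        assert log_likelihood(p, x) == pytest.approx(direct, abs=1e-12 * abs(direct) + 1e-12)

    def test_negative_log_likelihood_is_negation(self, random_param_data):
        p, x = random_param_data(5, n=30)
        assert negative_log_likelihood(p, x) == -log_likelihood(p, x)

    def test_permutation_invariance(self, random_param_data):
        p, x = random_param_data(6, n=50)
        shuffled = np.random.default_rng(0).permutation(x)
        assert log_likelihood(p, shuffled) == pytest.approx(log_likelihood(p, x), rel=1e-15)

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(WeibullParams(1, 1), np.array([1.0, 0.0]))


class TestDerivatives:
    @pytest.mark.parametrize("seed", range(10))
    def test_score_matches_finite_differences(self, random_param_data, seed):
        p, x = random_param_data(seed)
        g, g_fd = score(p, x), fd_score(p, x)
        np.testing.assert_allclose(g, g_fd, rtol=1e-4, atol=1e-6 * np.abs(g_fd).max())

    @pytest.mark.parametrize("seed", range(10))
    def test_hessian_matches_finite_differences(self, random_param_data, seed):
        p, x = random_param_data(seed + 100)
        h, h_fd = hessian(p, x), fd_hessian(p, x)
        np.testing.assert_allclose(h, h_fd, rtol=1e-3, atol=1e-5 * np.abs(h_fd).max())

    def test_hessian_symmetric(self, random_param_data):
        p, x = random_param_data(7)
        h = hessian(p, x)
        assert h[0, 1] == h[1, 0]

    def test_single_point_score_alpha_component_zero(self):
        # one observation at x = alpha with beta = 1: d logL/d alpha =
        # -1/alpha + x/alpha^2 = 0 exactly
        g = score(WeibullParams(0.9, 1.0), np.array([0.9]))
        assert g[0] == pytest.approx(0.0, abs=1e-12)

    def test_score_vanishes_at_mle(self, cohort_25c):
        fit = newton_raphson_fit(cohort_25c)
        # score on the log-parameter scale drives convergence; back on the
        # raw scale the components are score_log / parameter
        assert np.max(np.abs(fit.score_at_opt)) < 1e-4


class TestNewtonRaphson:
    def test_parameter_recovery_large_sample(self, cohort_25c, params_25c):
        fit = newton_raphson_fit(cohort_25c)
        assert fit.converged
        assert fit.params.alpha == pytest.approx(params_25c.alpha, rel=0.02)
        assert fit.params.beta == pytest.approx(params_25c.beta, rel=0.05)
        neg_def = np.all(np.linalg.eigvalsh(fit.hessian_at_opt) < 0)
        assert neg_def

    def test_warm_start_converges_fast(self, cohort_25c, params_25c):
        fit = newton_raphson_fit(cohort_25c, init=params_25c)
        assert fit.converged and fit.n_iter <= 5

    def test_loglik_not_below_init(self, cohort_25c):
        init = WeibullParams(0.3, 0.8)
        fit = newton_raphson_fit(cohort_25c, init=init)
        assert fit.loglik >= log_likelihood(init, cohort_25c)

    def test_matches_grid_argmin(self, cohort_25c):
        fit = newton_raphson_fit(cohort_25c)
        a, b = fit.params.alpha, fit.params.beta
        ag = np.linspace(0.9 * a, 1.1 * a, 200)
        bg = np.linspace(0.9 * b, 1.1 * b, 200)
        grid = nll_surface(cohort_25c, ag, bg)
        gm = grid.argmin_params
        assert abs(gm.alpha - a) <= ag[1] - ag[0]
        assert abs(gm.beta - b) <= bg[1] - bg[0]

    def test_matches_lifelines_fit(self, cohort_25c):
        lifelines = pytest.importorskip("lifelines")
        wf = lifelines.WeibullFitter().fit(cohort_25c.ages_at_death)
        fit = newton_raphson_fit(cohort_25c)
        assert fit.params.alpha == pytest.approx(wf.lambda_, rel=1e-4)
        assert fit.params.beta == pytest.approx(wf.rho_, rel=1e-4)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            newton_raphson_fit(CohortData([2.0, 2.0, 2.0], "tied"))

    def test_max_iter_exhaustion_returns_unconverged(self, cohort_25c):
        fit = newton_raphson_fit(
            cohort_25c, init=WeibullParams(5.0, 0.2), max_iter=2
        )
        assert not fit.converged
        assert fit.n_iter == 2

    def test_trace_gradient_norm_reaches_tolerance(self, cohort_25c):
        fit = newton_raphson_fit(cohort_25c, tol=1e-8)
        assert fit.trace[-1][1] < 1e-8


class TestInitialization:
    def test_quantile_cohort_recovers_parameters(self):
        # ages at the exact model quantiles make the life-table survivorship
        # noiseless, so the log-log regression seed lands near the truth
        p = WeibullParams(0.7, 2.5)
        q = (np.arange(1, 2001) - 0.5) / 2000
        ages = p.alpha * (-np.log(1 - q)) ** (1 / p.beta)
        init, method = initialize_params(CohortData(ages, "q"))
        assert method == "loglog-regression"
        assert init.alpha == pytest.approx(p.alpha, rel=0.05)
        assert init.beta == pytest.approx(p.beta, rel=0.10)

    def test_exponential_sample_shape_near_one(self):
        x = sample(WeibullParams(1.0, 1.0), 10_000, seed=2)
        init, _ = initialize_params(CohortData(x, "e"))
        assert 0.8 <= init.beta <= 1.2

    def test_two_distinct_ages_give_finite_positive_seed(self):
        init, _ = initialize_params(CohortData([1.0, 3.0], "tiny"))
        assert init.alpha > 0 and init.beta > 0


class TestSurfacesAndProfiles:
    def test_surface_cells_equal_direct_nll(self, random_param_data):
        p, x = random_param_data(8, n=40)
        ag = np.linspace(0.5 * p.alpha, 1.5 * p.alpha, 7)
        bg = np.linspace(0.5 * p.beta, 1.5 * p.beta, 5)
        grid = nll_surface(x, ag, bg)
        for i in (0, 3, 6):
            for j in (0, 2, 4):
                direct = negative_log_likelihood(WeibullParams(ag[i], bg[j]), x)
                assert grid.nll[i, j] == pytest.approx(direct, rel=1e-12)

    def test_coarser_grid_never_lower_minimum(self, random_param_data):
        p, x = random_param_data(9, n=60)
        ag = np.linspace(0.5, 2.0, 41)
        bg = np.linspace(0.5, 5.0, 41)
        fine = nll_surface(x, ag, bg)
        coarse = nll_surface(x, ag[::4], bg[::4])
        assert coarse.nll.min() >= fine.nll.min() - 1e-12

    def test_profile_unimodal_and_consistent_with_joint_fit(self, cohort_25c):
        fit = newton_raphson_fit(cohort_25c)
        bg = np.linspace(0.5, 8.0, 400)
        prof = profile_nll(cohort_25c, fit.params.alpha, bg)
        signs = np.sign(np.diff(prof))
        changes = np.sum(np.diff(signs[signs != 0]) != 0)
        assert changes == 1  # single minimum along the shape axis
        at_mle = profile_nll(cohort_25c, fit.params.alpha, np.array([fit.params.beta]))
        assert at_mle[0] == pytest.approx(-fit.loglik, abs=1e-8)

    def test_profile_single_point(self, random_param_data):
        p, x = random_param_data(10, n=25)
        val = profile_nll(x, p.alpha, np.array([p.beta]))
        assert val[0] == pytest.approx(negative_log_likelihood(p, x), rel=1e-12)

    def test_grid_validation(self, random_param_data):
        _, x = random_param_data(11, n=10)
        with pytest.raises(ValueError):
            nll_surface(x, np.array([1.0, 0.5]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            profile_nll(x, -1.0, np.array([1.0]))


class TestStandardErrors:
    def test_exponential_closed_form(self):
        # beta = 1: SE(alpha_hat) ~ alpha_hat / sqrt(n)
        x = sample(WeibullParams(0.8, 1.0), 10_000, seed=3)
        fit = newton_raphson_fit(CohortData(x, "e"))
        se_a, _ = standard_errors(fit)
        assert se_a == pytest.approx(fit.params.alpha / math.sqrt(x.size), rel=0.10)

    def test_one_over_sqrt_n_scaling(self):
        p = WeibullParams(0.7118, 3.4663)
        ses = []
        for n in (250, 1000, 4000):
            x = sample(p, n, seed=60)
            fit = newton_raphson_fit(CohortData(x, "s"))
            ses.append(standard_errors(fit))
        for k in (0, 1):
            ratio1 = ses[0][k] / ses[1][k]
            ratio2 = ses[1][k] / ses[2][k]
            assert ratio1 == pytest.approx(2.0, rel=0.15)
            assert ratio2 == pytest.approx(2.0, rel=0.15)

    def test_positive_for_well_conditioned_fit(self, cohort_25c):
        fit = newton_raphson_fit(cohort_25c)
        se = standard_errors(fit)
        assert se[0] > 0 and se[1] > 0

    def test_unconverged_fit_rejected(self, cohort_25c):
        fit = newton_raphson_fit(cohort_25c, init=WeibullParams(5.0, 0.2), max_iter=1)
        with pytest.raises(ValueError):
            standard_errors(fit)
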