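"""In vitro kinetic models: closed forms, conservation, DDE integration,
BSH regression, the composite deconjugation constant and the MCMC layer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import solve_ivp

from gutchol import (D8Params, XylParams, CellScaling, simulate_d8,
                     simulate_xyl, logistic_closed_form, fit_bsh_regression,
                     deconjugation_constant, infer_dram, default_priors,
                     geweke_score, log_phase_rate, NoiseSpec,
                     gen_growth_assay, gen_bsh_assay, D8_TRUE, XYL_TRUE)
from gutchol.kinetics import KineticsError, simulate_xyl_batch

TIMES = np.linspace(0.0, 24.0, 25)


class TestD8Model:
    def test_density_one_is_logistic_fixed_point(self):
        dens, _, _ = simulate_d8(D8_TRUE, (1.0, 0.7, 0.1), TIMES)
        assert np.allclose(dens, 1.0, atol=1e-12)

    def test_cholesterol_coprostanol_sum_conserved(self):
        _, cl, cp = simulate_d8(D8_TRUE, (0.01, 1.0, 0.0), TIMES)
        assert np.allclose(cl + cp, 1.0, atol=1e-12)
        assert cl[-1] < cl[0] and cp[-1] > cp[0]

    def test_zero_conversion_matches_logistic_closed_form(self):
        p = D8Params(mu=0.44772, k_cc=1e-12, K=1.0)
        dens, _, _ = simulate_d8(p, (0.01, 1.0, 0.0), TIMES)
        assert np.allclose(dens, logistic_closed_form(0.01, 0.44772, TIMES),
                           atol=1e-10)

    def test_quadrature_matches_stiff_integrator(self):
        """The closed-form/quadrature fast path agrees with a direct
        numerical integration of the governing equations."""
        def rhs(t, y, p):
            b, cl = y
            m = p.k_cc * b / (p.K + b)
            return [p.mu * b * (1 - b), -m * cl]

        sol = solve_ivp(rhs, (0, 24), [0.01, 1.0], args=(D8_TRUE,),
                        t_eval=TIMES, rtol=1e-11, atol=1e-13)
        dens, cl, _ = simulate_d8(D8_TRUE, (0.01, 1.0, 0.0), TIMES,
                                  n_refine=40)
        assert np.allclose(dens, sol.y[0], atol=1e-8)
        assert np.allclose(cl, sol.y[1], atol=1e-5)

    @given(mu=st.floats(0.1, 2.0), k=st.floats(0.01, 1.0),
           K=st.floats(0.01, 4.0), cl0=st.floats(0.1, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_metabolite_conservation_property(self, mu, k, K, cl0):
        p = D8Params(mu=mu, k_cc=k, K=K)
        _, cl, cp = simulate_d8(p, (0.05, cl0, 0.2), TIMES)
        assert np.allclose(cl + cp, cl0 + 0.2, atol=1e-10)

    def test_invalid_initial_density_rejected(self):
        with pytest.raises(KineticsError):
            simulate_d8(D8_TRUE, (0.0, 1.0, 0.0), TIMES)


class TestXylModel:
    def test_zero_pbs_history_reduces_to_logistic(self):
        dens, _, _ = simulate_xyl(XYL_TRUE, (0.01, 0.0, 0.0),
                                  np.linspace(0, 24, 20), step=0.02)
        expected = logistic_closed_form(0.01, XYL_TRUE.mu,
                                        np.linspace(0, 24, 20))
        assert np.allclose(dens, expected, atol=5e-5)

    def test_pbs_sbs_sum_conserved(self):
        _, pbs, sbs = simulate_xyl(XYL_TRUE, (0.01, 1.0, 0.5),
                                   np.linspace(0, 48, 30))
        assert np.allclose(pbs + sbs, 1.5, atol=1e-12)

    def test_step_halving_oracle(self):
        """Fixed-step trajectories at h and h/2 agree within the scheme's
        tolerance at the posterior-mean parameters, and the h/2 vs h/4
        error contracts (convergence of the method of steps)."""
        times = np.linspace(0, 48, 30)
        runs = {h: simulate_xyl(XYL_TRUE, (0.01, 1.0, 0.0), times, step=h)
                for h in (0.1, 0.05, 0.025)}
        err_coarse = max(np.max(np.abs(a - b))
                         for a, b in zip(runs[0.1], runs[0.05]))
        err_fine = max(np.max(np.abs(a - b))
                       for a, b in zip(runs[0.05], runs[0.025]))
        assert err_coarse < 1e-4
        assert err_fine < err_coarse / 2.0

    def test_dde_continuous_in_delay_at_zero(self):
        """With a constant history the DDE converges to the instantaneous
        model as the delay vanishes."""
        times = np.linspace(0, 30, 40)
        small = simulate_xyl(
            XylParams(mu=1.9, beta=1.1, delta=1e-3, K=0.1, k_bxyl=0.4),
            (0.01, 1.0, 0.0), times, step=5e-4)

        def rhs(t, y):
            b, pbs = y
            rep = pbs / (0.1 + pbs)
            return [1.9 * b * (1 - b) - 1.1 * b * rep, -0.4 * b * b * pbs]

        sol = solve_ivp(rhs, (0, 30), [0.01, 1.0], t_eval=times,
                        rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(small[0] - sol.y[0])) < 1e-4
        assert np.max(np.abs(small[1] - sol.y[1])) < 1e-4

    def test_missing_history_and_bad_delay_rejected(self):
        with pytest.raises(KineticsError):
            simulate_xyl(XYL_TRUE, None, TIMES)
        with pytest.raises(KineticsError):
            XylParams(mu=1.0, beta=1.0, delta=0.0, K=0.1, k_bxyl=0.1)

    def test_batch_matches_single(self):
        times = np.linspace(0, 48, 20)
        grid, B, P = simulate_xyl_batch(XYL_TRUE, [0.01, 0.02], [1.0, 2.0],
                                        48.0, step=0.1)
        for j, (b0, p0) in enumerate([(0.01, 1.0), (0.02, 2.0)]):
            dens, pbs, _ = simulate_xyl(XYL_TRUE, (b0, p0, 0.0), times,
                                        step=0.1)
            assert np.allclose(np.interp(times, grid, B[:, j]), dens,
                               atol=1e-12)
            assert np.allclose(np.interp(times, grid, P[:, j]), pbs,
                               atol=1e-12)


class TestBshRegression:
    def test_exact_line_through_origin(self):
        d = np.linspace(0.1, 1.0, 8)
        fit = fit_bsh_regression(d, 5.0 * d)
        assert fit.intercept_dropped
        assert fit.slope == pytest.approx(5.0, abs=1e-10)
        assert fit.intercept == 0.0

    def test_insignificant_intercept_dropped(self, rng):
        d = rng.uniform(0, 1, 24)
        y = 19.2466 * d + rng.normal(0, 2.0, 24)
        fit = fit_bsh_regression(d, y)
        assert fit.intercept_dropped
        assert fit.p_intercept > 0.05

    def test_significant_intercept_retained(self, rng):
        d = rng.uniform(0, 1, 40)
        y = 3.0 * d + 10.0 + rng.normal(0, 0.1, 40)
        fit = fit_bsh_regression(d, y)
        assert not fit.intercept_dropped
        assert fit.intercept == pytest.approx(10.0, abs=0.2)

    def test_slope_recovery_within_ci(self):
        d, y = gen_bsh_assay(slope=19.2466, intercept=0.0, noise_sd=1.5,
                             n=12, seed=3)
        fit = fit_bsh_regression(d, y)
        se = fit.result.bse[0]
        assert abs(fit.slope - 19.2466) < 1.96 * se

    def test_outlier_removed_before_fit(self, rng):
        d = np.linspace(0.05, 1.0, 20)
        y = 10.0 * d + rng.normal(0, 0.05, 20)
        y[7] += 25.0
        fit = fit_bsh_regression(d, y)
        assert fit.n_outliers_removed == 1
        assert fit.slope == pytest.approx(10.0, abs=0.2)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(KineticsError):
            fit_bsh_regression([0.5, 0.5, 0.5], [1, 2, 3])
        with pytest.raises(KineticsError):
            fit_bsh_regression([0.1, 0.2], [1, 2])


class TestDeconjugationConstant:
    def test_zero_activity_gives_zero(self):
        assert deconjugation_constant(0.0, 1000.0) == 0.0

    def test_linearity_in_activity(self):
        k1 = deconjugation_constant(19.2466, 1000.0)
        k2 = deconjugation_constant(2 * 19.2466, 1000.0)
        assert k2 == pytest.approx(2 * k1, rel=1e-12)

    def test_zero_bs0_rejected(self):
        with pytest.raises(KineticsError):
            deconjugation_constant(19.2466, 0.0)

    def test_unit_tracking_oracle(self):
        """Dimensional audit: multiply value and units factor by factor and
        check the product collapses to 1/h with the frozen composition."""
        sc = CellScaling()
        factors = [
            (sc.t_k, {"min": 1, "h": -1}),
            (19.2466, {"nmol": 1, "min": -1, "mg_prot": -1}),
            (1.0 / 10000.0, {"nmol": -1, "mL": 1}),        # 1/[BS]0
            (sc.c_lambda, {"mg_prot": 1, "g": -1, "mL": 1, "um": -3}),
            (sc.d_c, {"g": 1, "mL": -1}),
            (1.0 - sc.c_w, {}),
            (sc.c_p, {}),
            (sc.v_c, {"um": 3, "CFU": -1}),
            (sc.bxyl_max, {"CFU": 1, "mL": -1}),
        ]
        value = 1.0
        units: dict[str, int] = {}
        for v, u in factors:
            value *= v
            for k, e in u.items():
                units[k] = units.get(k, 0) + e
        units = {k: e for k, e in units.items() if e != 0}
        assert units == {"h": -1}
        assert value == pytest.approx(
            deconjugation_constant(19.2466, 10000.0, sc), rel=1e-12)


class TestGeweke:
    def test_iid_chain_null_distribution(self, rng):
        """For a stationary chain the two-sided score is approximately
        Uniform(0, 1): its mean sits near 1/2 and very small scores are
        rare — clearly separated from the trending-chain regime."""
        scores = np.array([geweke_score(rng.standard_normal(4000))
                           for _ in range(40)])
        assert 0.3 < scores.mean() < 0.7
        assert np.mean(scores > 0.05) >= 0.85

    def test_trending_chain_scores_near_zero(self):
        x = np.linspace(0, 5, 2000) + np.sin(np.arange(2000))
        assert geweke_score(x) < 1e-6

    def test_constant_chain_rejected(self):
        with pytest.raises(KineticsError):
            geweke_score(np.ones(500))

    def test_short_chain_rejected(self):
        with pytest.raises(KineticsError):
            geweke_score(np.arange(10.0))


class TestDram:
    def test_flat_likelihood_recovers_uniform_prior(self, d8_assays):
        """With a constant likelihood the chain must sample the prior box
        uniformly (Kolmogorov-Smirnov at fixed seed)."""
        priors = {"mu": (0.1, 0.9), "k_cc": (0.0, 1.0)}
        chain = infer_dram("d8", d8_assays, priors=priors, n_iter=20_000,
                           seed=123, log_likelihood=lambda t: 0.0)
        post = chain.posterior
        for i, (lo, hi) in enumerate([(0.1, 0.9), (0.0, 1.0)]):
            u = (post[::20, i] - lo) / (hi - lo)
            assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_d8_posterior_recovers_generating_parameters(self, d8_assays):
        chain = infer_dram("d8", d8_assays, n_iter=4000, seed=7)
        m, s = chain.mean(), chain.std()
        assert abs(m["mu"] - 0.44772) < 0.1 * 0.44772
        lo, hi = chain.credible_interval("mu")
        assert lo <= 0.44772 <= hi
        assert 0 < chain.acceptance_rate < 1

    def test_reproducible_under_seed(self, d8_assays):
        c1 = infer_dram("d8", d8_assays, n_iter=600, seed=9)
        c2 = infer_dram("d8", d8_assays, n_iter=600, seed=9)
        assert np.array_equal(c1.samples, c2.samples)

    def test_alpha_rule_and_priors(self, d8_assays):
        a = d8_assays[0]
        alpha = log_phase_rate(a.times, a.density)
        assert 0.2 < alpha < 0.6  # log-phase estimate of a 0.448/h logistic
        priors = default_priors("d8", d8_assays)
        lo, hi = priors["mu"]
        assert lo < 0.44772 < hi

    def test_empty_prior_box_rejected(self, d8_assays):
        with pytest.raises(KineticsError):
            infer_dram("d8", d8_assays, priors={"mu": (0.5, 0.5),
                                                "k_cc": (0, 1),
                                                "K": (0, 1)}, n_iter=100)

    def test_xyl_needs_deconjugation_constant(self):
        assays = gen_growth_assay("xyl", noise=NoiseSpec(
            seed=1, n_replicates=1, n_timepoints=6))
        with pytest.raises(KineticsError):
            infer_dram("xyl", assays, n_iter=100, seed=0)
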