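"""Marginal likelihood, quadrature accuracy, variants, and fitting."""

import copy

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from nccjoint.datatypes import JointModelSpec, ParameterSet, SubjectRecord
from nccjoint.estimation import (GenericEngine, ModelData, auto_init,
                                 build_engine, fit, marginal_loglik_subject,
                                 total_loglik)
from nccjoint.longitudinal import (LongitudinalDesign, loglik_conditional,
                                   marginal_gaussian_loglik)
from nccjoint.sampling import draw_controls, select_cases_and_censor
from nccjoint.simulate import SimConfig, simulate_cohort
from nccjoint.survival import loglik_survival_conditional


def _gaussian_subject(rng, T=2.0, delta=1, theta=np.sqrt(2.0)):
    times = np.array([0.0, 0.1, 0.2, 0.3, 0.4])
    Y = 0.1 * times + rng.normal(0, theta) + rng.normal(0, 1, times.size)
    return SubjectRecord(subject_id=0, T=T, delta=delta, X_surv=[1.0], R=1,
                         times=times, Y=Y)


@pytest.fixture
def params22():
    return ParameterSet(gamma=[0.1], log_disp=0.0, log_theta=0.5 * np.log(2.0),
                        beta=[0.3, 0.1], alpha=[[-0.2], [-0.2]],
                        log_xi=[[-5.0], [-4.0]])


@pytest.fixture
def spec22():
    return JointModelSpec(K=2, survival_covariate_names=("X2",),
                          baseline_knots=[0.0, 3.0], n_quadrature=15)


class TestMarginalLoglik:
    def test_degenerate_prior_equals_conditional_at_zero(self, rng, params22, spec22):
        """theta -> 0 collapses the integral onto b = 0."""
        rec = _gaussian_subject(rng)
        p0 = copy.deepcopy(params22)
        p0.log_theta = np.log(1e-8)
        marg = marginal_loglik_subject(rec, p0, spec22)
        design = LongitudinalDesign.from_times(rec.times)
        cond = (loglik_survival_conditional(rec, 0.0, p0, spec22)
                + loglik_conditional(rec.Y, design, p0.gamma, 1.0, 0.0, "gaussian"))
        assert marg == pytest.approx(cond, abs=1e-6)
        engine = build_engine([rec], spec22, "oracle")
        assert engine.value(p0.pack()) == pytest.approx(cond, abs=1e-6)

    def test_no_hazard_limit_matches_compound_symmetry_closed_form(self, rng):
        """With vanishing baselines the marginal is the CS normal density."""
        spec = JointModelSpec(K=2, survival_covariate_names=("X2",),
                              baseline_knots=[0.0, 3.0], n_quadrature=25)
        p = ParameterSet(gamma=[0.1], log_disp=0.0, log_theta=0.5 * np.log(2.0),
                         beta=[0.0, 0.0], alpha=[[0.0], [0.0]],
                         log_xi=[[-60.0], [-60.0]])
        for _ in range(5):
            rec = _gaussian_subject(rng, delta=0)
            ref = marginal_gaussian_loglik(
                rec.Y, LongitudinalDesign.from_times(rec.times), [0.1], 1.0,
                np.sqrt(2.0))
            assert marginal_loglik_subject(rec, p, spec) == pytest.approx(ref, abs=1e-8)
            eng = build_engine([rec], spec, "oracle")
            assert eng.value(p.pack()) == pytest.approx(ref, abs=1e-8)

    def test_node_count_insensitivity(self, rng, params22):
        """15 vs 25 quadrature nodes agree below 1e-5 per subject."""
        for delta in (0, 1, 2):
            rec = _gaussian_subject(rng, delta=delta)
            l15 = marginal_loglik_subject(
                rec, params22,
                JointModelSpec(K=2, survival_covariate_names=("X2",),
                               baseline_knots=[0.0, 3.0], n_quadrature=15))
            l25 = marginal_loglik_subject(
                rec, params22,
                JointModelSpec(K=2, survival_covariate_names=("X2",),
                               baseline_knots=[0.0, 3.0], n_quadrature=25))
            assert abs(l15 - l25) < 1e-5

    def test_matches_dense_adaptive_integration(self, rng, params22, spec22):
        """Quadrature result vs scipy adaptive integration over b."""
        design = LongitudinalDesign.from_times(np.array([0.0, 0.1, 0.2, 0.3, 0.4]))
        for i in range(8):
            rec = _gaussian_subject(rng, delta=i % 3)

            def integrand(b):
                ll = loglik_survival_conditional(rec, b, params22, spec22)
                ll += loglik_conditional(rec.Y, design, params22.gamma, 1.0, b,
                                         "gaussian")
                return np.exp(ll) * stats.norm.pdf(b, 0, np.sqrt(2.0))

            ref, _ = integrate.quad(integrand, -12, 12, limit=300,
                                    epsabs=1e-14, epsrel=1e-12)
            ours = marginal_loglik_subject(rec, params22, spec22)
            assert ours == pytest.approx(np.log(ref), abs=1e-6)

    def test_negative_binomial_marginal_against_dense_integration(self, rng):
        """Laplace-adapted quadrature for the count family vs scipy.quad."""
        times = np.array([0.0, 0.5, 1.0])
        Y = np.array([1.0, 3.0, 2.0])
        rec = SubjectRecord(subject_id=0, T=2.0, delta=1, R=1, times=times, Y=Y)
        p = ParameterSet(gamma=[0.3], log_disp=np.log(0.4), log_theta=np.log(0.7),
                         beta=[0.2], alpha=np.zeros((1, 0)), log_xi=[[-2.0]])
        spec = JointModelSpec(K=1, family="negative_binomial", link="log",
                              baseline_knots=[0.0, 2.5], n_quadrature=21,
                              gl_order=30)
        from nccjoint.longitudinal import LongitudinalDesign as LD

        design = LD.from_times(times)

        def integrand(b):
            try:
                ll = loglik_survival_conditional(rec, b, p, spec)
            except FloatingPointError:
                return 0.0          # hazard overflow far in the tail
            ll += loglik_conditional(Y, design, p.gamma, 0.4, b,
                                     "negative_binomial")
            return np.exp(ll) * stats.norm.pdf(b, 0, 0.7)

        ref, _ = integrate.quad(integrand, -8, 8, limit=300, epsabs=1e-14,
                                epsrel=1e-12)
        ours = marginal_loglik_subject(rec, p, spec)
        assert ours == pytest.approx(np.log(ref), abs=1e-6)

    def test_fast_engine_agrees_with_reference_engine(self, small_study):
        spec, data = small_study["spec"], small_study["data"]
        fast = build_engine(data, spec, "fjm_ncc")
        gen = GenericEngine(fast.data, spec, fast.weights, fast.incl)
        x = auto_init(fast).pack() + 0.1
        np.testing.assert_allclose(fast.per_subject_loglik(x),
                                   gen.per_subject_loglik(x), atol=1e-7)


class TestVariants:
    def test_fully_observed_cohort_fjm_equals_oracle_exactly(self, small_study, replication_params):
        observed = [copy.deepcopy(r) for r in small_study["observed"]]
        for r in observed:
            r.R = 1
        spec = small_study["spec"]
        a = total_loglik(observed, replication_params, spec, "oracle")
        b = total_loglik(observed, replication_params, spec, "fjm_ncc")
        assert a == b

    def test_unit_weights_wjm_equals_naive_exactly(self, small_study, replication_params):
        spec = small_study["spec"]
        data = small_study["data"]
        ones = np.ones(len(data.records))
        a = total_loglik(data, replication_params, spec, "wjm_ncc", weights=ones)
        b = total_loglik(data, replication_params, spec, "naive_jm")
        assert a == b

    def test_total_is_sum_of_per_subject_marginals(self, small_study, replication_params):
        spec = small_study["spec"]
        records = list(small_study["observed"][:5])
        total = total_loglik(records, replication_params, spec, "fjm_ncc")
        parts = sum(
            marginal_loglik_subject(r, replication_params, spec,
                                    include_longitudinal=(r.R == 1))
            for r in records
        )
        assert total == pytest.approx(parts, abs=1e-6)

    def test_missing_weights_rejected(self, small_study, replication_params):
        with pytest.raises(ValueError, match="weights"):
            total_loglik(small_study["data"], replication_params, small_study["spec"],
                         "wjm_ncc")


class TestGradient:
    def test_analytic_gradient_matches_central_differences(self, small_study):
        spec, data = small_study["spec"], small_study["data"]
        for variant, w in (("oracle", None), ("wjm_ncc", small_study["sample"].weights)):
            engine = build_engine(data, spec, variant, w)
            x = auto_init(engine).pack() + np.linspace(-0.15, 0.2, 9)
            _, g = engine.value_and_grad(x)
            for j in range(x.size):
                h = 1e-6 * max(1.0, abs(x[j]))
                xp, xm = x.copy(), x.copy()
                xp[j] += h
                xm[j] -= h
                fd = (engine.value(xp) - engine.value(xm)) / (2 * h)
                assert g[j] == pytest.approx(fd, rel=1e-4, abs=1e-4)


class TestFit:
    def test_oracle_recovers_truth_within_three_se(self):
        """Parameter recovery on a mid-size cohort at replication settings."""
        config = SimConfig(N=2000, n_cases_target=100,
                           beta=np.array([0.1, 0.1]), seed=77)
        cohort = simulate_cohort(config)
        case_ids, ct, observed = select_cases_and_censor(cohort, 100)
        spec = JointModelSpec(K=2, survival_covariate_names=("X2",),
                              baseline_knots=[0.0, ct])
        res = fit(observed, spec, "oracle")
        assert res.converged
        from nccjoint.inference import fisher_covariance
        cov = fisher_covariance(res, observed)
        truth = dict(gamma_time=0.1, log_sigma=0.0, log_theta=0.5 * np.log(2),
                     beta_1=0.1, beta_2=0.1, alpha_1_X2=-0.2, alpha_2_X2=-0.2,
                     log_xi_1_1=-5.0, log_xi_2_1=-4.0)
        for name, tv in truth.items():
            est, se = res.estimate(name), cov.se[res.names.index(name)]
            assert abs(est - tv) < 3 * se, f"{name}: {est} vs {tv} (se {se})"

    def test_longitudinal_only_matches_reference_mixed_model(self):
        """With no events the slope/variance estimates equal a LMM fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n, times = 150, np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        b0 = rng.normal(0, 1.2, n)
        Y = 0.4 * times[None, :] + b0[:, None] + rng.normal(0, 0.8, (n, times.size))
        records = [
            SubjectRecord(subject_id=i, T=2.0, delta=0, R=1, times=times, Y=Y[i])
            for i in range(n)
        ]
        spec = JointModelSpec(K=1, baseline_knots=[0.0, 2.0])
        res = fit(records, spec, "oracle")
        endog = Y.ravel()
        exog = np.tile(times, n)[:, None]
        groups = np.repeat(np.arange(n), times.size)
        lmm = sm.MixedLM(endog, exog, groups).fit(reml=False)
        assert res.estimate("gamma_time") == pytest.approx(lmm.fe_params[0], abs=1e-3)
        assert res.params.sigma**2 == pytest.approx(lmm.scale, abs=1e-3)
        assert res.params.theta**2 == pytest.approx(float(np.asarray(lmm.cov_re)[0, 0]),
                                                    abs=2e-3)

    def test_refit_from_solution_is_stationary(self, small_study):
        spec, data = small_study["spec"], small_study["data"]
        res = fit(data, spec, "fjm_ncc")
        res2 = fit(data, spec, "fjm_ncc", init=res.params)
        assert res2.n_iter <= 1
        assert res2.loglik == pytest.approx(res.loglik, abs=1e-8)

    def test_optimizer_trace_is_monotone(self, small_study):
        spec, data = small_study["spec"], small_study["data"]
        engine = build_engine(data, spec, "naive_jm")
        x0 = auto_init(engine).pack()
        trace = []

        def nll(x):
            v, g = engine.value_and_grad(x)
            return -v, -g

        optimize.minimize(nll, x0, jac=True, method="L-BFGS-B",
                          callback=lambda xk: trace.append(-engine.value(xk)),
                          options={"maxiter": 200, "ftol": 1e-11})
        trace = np.array(trace)
        assert np.all(np.diff(trace) <= 1e-7)

    def test_weighted_estimates_near_oracle_at_generous_sampling(self):
        """With m=5 the weighted sub-cohort fit tracks the full-cohort fit."""
        config = SimConfig(N=3000, n_cases_target=150,
                           beta=np.array([0.2, 0.1]), seed=21)
        cohort = simulate_cohort(config)
        case_ids, ct, observed = select_cases_and_censor(cohort, 150)
        sample = draw_controls(observed, case_ids, 5, np.random.default_rng(8))
        spec = JointModelSpec(K=2, survival_covariate_names=("X2",),
                              baseline_knots=[0.0, ct])
        data = ModelData(observed, spec)
        oracle = fit(data, spec, "oracle")
        wjm = fit(data, spec, "wjm_ncc", weights=sample.weights)
        from nccjoint.inference import sandwich_covariance
        cov = sandwich_covariance(wjm, data, weights=sample.weights)
        for k in (1, 2):
            name = f"beta_{k}"
            se = cov.se[wjm.names.index(name)]
            assert abs(wjm.estimate(name) - oracle.estimate(name)) < 3 * se

    def test_default_knots_cover_observed_times(self, small_study):
        from nccjoint.estimation import default_knots

        observed = small_study["observed"]
        for Q in (1, 3):
            knots = default_knots(observed, Q=Q)
            assert knots[0] == 0.0
            assert knots[-1] >= max(r.T for r in observed)
            assert np.all(np.diff(knots) > 0)

    def test_nonidentifiable_inputs_flagged_not_raised(self):
        records = [SubjectRecord(subject_id=i, T=1.0, delta=1 + i % 2,
                                 X_surv=[float(i % 2)], R=1,
                                 times=np.array([0.0]), Y=np.array([0.1]))
                   for i in range(6)]
        spec = JointModelSpec(K=2, survival_covariate_names=("X2",),
                              baseline_knots=[0.0, 1.0])
        res = fit(records, spec, "naive_jm", maxiter=20)
        assert isinstance(res.converged, bool)  # flagged result, no exception
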