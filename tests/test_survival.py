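"""Survival sub-model: piecewise hazards, cumulative hazards, densities."""

import numpy as np
import pytest

from nccjoint.datatypes import JointModelSpec, ParameterSet, SubjectRecord
from nccjoint.survival import (cumulative_hazard, hazard_at,
                               loglik_survival_conditional, piece_index)


def _params(beta=(0.0,), log_xi=((-5.0,),), alpha=None, gamma=(0.1,)):
    beta = np.asarray(beta, float)
    K = beta.size
    if alpha is None:
        alpha = np.zeros((K, 0))
    return ParameterSet(gamma=np.asarray(gamma), log_disp=0.0,
                        log_theta=0.5 * np.log(2.0), beta=beta,
                        alpha=np.asarray(alpha), log_xi=np.asarray(log_xi))


def _spec(K=1, knots=(0.0, 10.0), **kw):
    return JointModelSpec(K=K, baseline_knots=np.asarray(knots), **kw)


class TestHazard:
    def test_constant_baseline_with_null_effects(self):
        p = _params(beta=[0.0], log_xi=[[-5.0]])
        spec = _spec()
        for t in (0.5, 3.0, 9.9):
            assert hazard_at(t, 1, 0.0, [], [], p, spec) == pytest.approx(np.exp(-5))

    def test_linear_in_baseline_height(self):
        spec = _spec()
        h1 = hazard_at(2.0, 1, 0.4, [], [], _params(beta=[0.3]), spec)
        h2 = hazard_at(2.0, 1, 0.4, [], [],
                       _params(beta=[0.3], log_xi=[[-5.0 + np.log(2)]]), spec)
        assert h2 == pytest.approx(2 * h1)

    def test_matches_hand_formula_on_random_draws(self, rng):
        p = _params(beta=[0.3], alpha=[[-0.2]])
        spec = _spec(survival_covariate_names=("x",))
        for _ in range(10):
            t, b, x = rng.uniform(0.1, 9), rng.normal(), rng.integers(0, 2)
            expected = np.exp(-5) * np.exp(0.3 * (0.1 * t + b) - 0.2 * x)
            got = hazard_at(t, 1, b, [], [float(x)], p, spec)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_time_outside_knots_rejected(self):
        with pytest.raises(ValueError):
            hazard_at(11.0, 1, 0.0, [], [], _params(), _spec())

    def test_piece_convention_half_open(self):
        knots = np.array([0.0, 1.0, 2.0])
        assert piece_index(1.0, knots) == 0      # events at v_q belong to piece q
        assert piece_index(1.0 + 1e-12, knots) == 1
        assert piece_index(2.0, knots) == 1


class TestCumulativeHazard:
    def test_constant_hazard_is_rate_times_time(self):
        p = _params(beta=[0.0], alpha=[[0.5]])
        spec = _spec(survival_covariate_names=("x",))
        got = cumulative_hazard(4.0, 1, 1.7, [], [1.0], p, spec)
        assert got == pytest.approx(np.exp(-5) * np.exp(0.5) * 4.0, rel=1e-12)

    def test_closed_form_matches_64_node_gauss_legendre(self, rng):
        """Identity-link closed form vs an independent quadrature oracle."""
        p = _params(beta=[0.3], alpha=[[-0.2]], log_xi=[[-5.0, -4.5]])
        spec = _spec(survival_covariate_names=("x",), knots=(0.0, 1.5, 10.0))
        nodes, weights = np.polynomial.legendre.leggauss(64)
        for _ in range(5):
            b, T = rng.normal(), rng.uniform(0.5, 9.5)
            closed = cumulative_hazard(T, 1, b, [], [1.0], p, spec)
            ref = 0.0
            for a, c in ((0.0, min(T, 1.5)), (min(T, 1.5), T)):
                if c <= a:
                    continue
                s = 0.5 * (c - a) * nodes + 0.5 * (c + a)
                lam = np.array([hazard_at(si, 1, b, [], [1.0], p, spec) for si in s])
                ref += 0.5 * (c - a) * float(weights @ lam)
            assert closed == pytest.approx(ref, abs=1e-10, rel=1e-10)

    def test_refining_knots_with_equal_heights_is_invariant(self):
        p1 = _params(beta=[0.25], log_xi=[[-5.0]])
        p2 = _params(beta=[0.25], log_xi=[[-5.0, -5.0]])
        s1 = _spec(knots=(0.0, 10.0))
        s2 = _spec(knots=(0.0, 4.0, 10.0))
        for T in (1.0, 4.0, 7.3):
            a = cumulative_hazard(T, 1, 0.6, [], [], p1, s1)
            b = cumulative_hazard(T, 1, 0.6, [], [], p2, s2)
            assert a == pytest.approx(b, rel=1e-12)

    def test_generic_link_uses_quadrature(self, rng):
        """Log link (NB model) integrates exp(beta * e^eta) numerically."""
        p = ParameterSet(gamma=[0.2], log_disp=0.0, log_theta=0.0, beta=[0.4],
                         alpha=np.zeros((1, 0)), log_xi=[[-3.0]])
        spec = JointModelSpec(K=1, family="negative_binomial", link="log",
                              baseline_knots=[0.0, 5.0], gl_order=30)
        from scipy.integrate import quad
        b = 0.3
        ref, _ = quad(lambda s: np.exp(-3.0) * np.exp(0.4 * np.exp(0.2 * s + b)),
                      0, 2.0, epsabs=1e-13)
        got = cumulative_hazard(2.0, 1, b, [], [], p, spec)
        assert got == pytest.approx(ref, rel=1e-9)


class TestSurvivalLoglik:
    def test_censored_single_piece_closed_form(self):
        p = _params(beta=[0.0, 0.0], log_xi=[[-5.0], [-4.0]])
        spec = _spec(K=2)
        r = SubjectRecord(subject_id=0, T=3.0, delta=0)
        expected = -3.0 * (np.exp(-5) + np.exp(-4))
        assert loglik_survival_conditional(r, 0.0, p, spec) == pytest.approx(expected)

    def test_single_cause_matches_independent_piecewise_exponential(self):
        """K=1 reduces to a piecewise-exponential PH log-likelihood."""
        knots = np.array([0.0, 1.0, 3.0, 10.0])
        heights = np.array([0.05, 0.10, 0.02])
        beta, gamma, b = 0.2, 0.1, 0.4
        p = ParameterSet(gamma=[gamma], log_disp=0.0, log_theta=0.0,
                         beta=[beta], alpha=np.zeros((1, 0)),
                         log_xi=np.log(heights)[None, :])
        spec = _spec(K=1, knots=knots)
        rng = np.random.default_rng(5)
        Ts = rng.uniform(0.2, 9.5, size=10)
        deltas = rng.integers(0, 2, size=10)

        def reference(T, delta):
            # independent implementation: scan a fine grid for the integral
            grid = np.linspace(0, T, 200001)
            lam = heights[np.clip(np.searchsorted(knots, grid[1:], side="left") - 1,
                                  0, 2)] * np.exp(beta * (gamma * grid[1:] + b))
            Lam = np.trapezoid(np.concatenate([[lam[0]], lam]), grid)
            out = -Lam
            if delta:
                q = np.clip(np.searchsorted(knots, T, side="left") - 1, 0, 2)
                out += np.log(heights[q]) + beta * (gamma * T + b)
            return out

        for T, delta in zip(Ts, deltas):
            r = SubjectRecord(subject_id=0, T=float(T), delta=int(delta))
            ours = loglik_survival_conditional(r, b, p, spec)
            assert ours == pytest.approx(reference(T, delta), abs=5e-6)

    def test_density_integrates_to_at_most_one(self):
        """sum_k int f(t, k | b) dt + S(t_max) must equal 1 (within grid error)."""
        p = _params(beta=[0.3, -0.1], log_xi=[[-1.0], [-0.7]], gamma=(0.1,))
        spec = _spec(K=2, knots=(0.0, 8.0))
        b = 0.5
        grid = np.linspace(1e-6, 8.0, 4001)
        dens = np.array([
            sum(np.exp(loglik_survival_conditional(
                SubjectRecord(subject_id=0, T=float(t), delta=k), b, p, spec))
                for k in (1, 2))
            for t in grid
        ])
        total_events = np.trapezoid(dens, grid)
        surv_tail = np.exp(loglik_survival_conditional(
            SubjectRecord(subject_id=0, T=8.0, delta=0), b, p, spec))
        assert total_events + surv_tail == pytest.approx(1.0, abs=2e-3)
        assert total_events <= 1.0 + 1e-6

    def test_survival_function_monotone_from_one(self):
        p = _params(beta=[0.2], log_xi=[[-2.0]])
        spec = _spec(K=1)
        ts = np.linspace(0, 10, 50)
        S = [np.exp(loglik_survival_conditional(
            SubjectRecord(subject_id=0, T=float(t), delta=0), 0.3, p, spec))
            for t in ts]
        assert S[0] == pytest.approx(1.0)
        assert np.all(np.diff(S) <= 1e-12)

    def test_raising_height_lowers_censored_loglik(self):
        spec = _spec(K=1)
        r = SubjectRecord(subject_id=0, T=5.0, delta=0)
        lls = [loglik_survival_conditional(r, 0.0, _params(beta=[0.1], log_xi=[[lx]]), spec)
               for lx in (-5.0, -4.0, -3.0)]
        assert lls[0] > lls[1] > lls[2]

    def test_event_at_time_zero_rejected(self):
        r = SubjectRecord(subject_id=0, T=0.0, delta=1)
        with pytest.raises(ValueError):
            loglik_survival_conditional(r, 0.0, _params(), _spec())
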