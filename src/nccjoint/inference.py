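"""Covariance estimation and Wald inference.

Fisher covariance: inverse of the negative Hessian of the fitted variant's
total log-likelihood (the empirical information), with the Hessian formed by
central finite differences of the analytic gradient where available.

Sandwich covariance (for the inclusion-weighted likelihood, whose weighted
score is not an ordinary likelihood score): ``bread^-1 meat bread^-1`` with
the negative Hessian of the weighted log-likelihood as bread and the
mean-centered outer-product sum of per-subject weighted score vectors as
meat.  With the per-subject normalizations of the information and score
covariance written out, the scale factors cancel so the result is directly
the covariance of the estimates.

Wald tests and confidence intervals use the printed 1.96 multiplier at the
95% level; SEs for variance-type parameters are reported on the log scale.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .datatypes import CovarianceEstimate, FitResult, ParameterSet
from .estimation import GaussianEngine, build_engine

__all__ = [
    "fisher_covariance",
    "sandwich_covariance",
    "wald_test",
    "confidence_interval",
    "bonferroni",
    "hessian",
    "attach_covariance",
]

_FD_STEP = 1e-5  # relative central-difference step for scores/Hessians


def hessian(engine, x, step: float = _FD_STEP) -> np.ndarray:
    """Hessian of the engine's total log-likelihood at ``x``.

    Central differences of the analytic gradient for the fast engine,
    central second differences of the value otherwise.
    """
    x = np.asarray(x, dtype=float)
    P = x.size
    H = np.empty((P, P))
    if isinstance(engine, GaussianEngine) and hasattr(engine, "value_and_grad"):
        for j in range(P):
            h = step * max(1.0, abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            _, gp = engine.value_and_grad(xp)
            _, gm = engine.value_and_grad(xm)
            H[:, j] = (gp - gm) / (2 * h)
    else:
        hs = np.array([step * 10 * max(1.0, abs(xj)) for xj in x])
        f0 = engine.value(x)
        fp = np.empty(P)
        fm = np.empty(P)
        for j in range(P):
            xp, xm = x.copy(), x.copy()
            xp[j] += hs[j]
            xm[j] -= hs[j]
            fp[j] = engine.value(xp)
            fm[j] = engine.value(xm)
        for j in range(P):
            H[j, j] = (fp[j] - 2 * f0 + fm[j]) / hs[j] ** 2
            for l in range(j):
                xpp = x.copy(); xpp[[j, l]] += hs[[j, l]]
                xmm = x.copy(); xmm[[j, l]] -= hs[[j, l]]
                H[j, l] = H[l, j] = (
                    (engine.value(xpp) - fp[j] - fp[l] + 2 * f0
                     - fm[j] - fm[l] + engine.value(xmm)) / (2 * hs[j] * hs[l])
                )
    return 0.5 * (H + H.T)


def _invert(neg_hess: np.ndarray) -> tuple[np.ndarray, bool, float]:
    cond = float(np.linalg.cond(neg_hess))
    try:
        cov = np.linalg.inv(neg_hess)
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
        pinv = False
    except np.linalg.LinAlgError:
        warnings.warn("information matrix not invertible; using pseudo-inverse")
        cov = np.linalg.pinv(neg_hess)
        pinv = True
    return 0.5 * (cov + cov.T), pinv, cond


def fisher_from_engine(engine, x, names=None) -> CovarianceEstimate:
    """Inverse empirical information of an arbitrary likelihood engine."""
    H = hessian(engine, x)
    cov, pinv, cond = _invert(-H)
    names = names or [f"p{j}" for j in range(len(x))]
    return CovarianceEstimate("fisher", cov, names,
                              condition_number=cond, pseudo_inverse_used=pinv)


def sandwich_from_engine(engine, x, names=None) -> CovarianceEstimate:
    """bread^-1 meat bread^-1 from an engine with per-subject scores."""
    H = hessian(engine, x)
    bread_inv, pinv, cond = _invert(-H)
    S = engine.per_subject_scores(x, weighted=True)
    Sc = S - S.mean(axis=0, keepdims=True)
    meat = Sc.T @ Sc
    cov = bread_inv @ meat @ bread_inv
    names = names or [f"p{j}" for j in range(len(x))]
    return CovarianceEstimate("sandwich", 0.5 * (cov + cov.T), names,
                              condition_number=cond, pseudo_inverse_used=pinv)


def fisher_covariance(fit: FitResult, cohort, spec=None, variant=None,
                      weights=None) -> CovarianceEstimate:
    """Inverse empirical information of the fitted likelihood variant."""
    spec = spec or fit.spec
    variant = variant or fit.variant
    engine = build_engine(cohort, spec, variant, weights)
    return fisher_from_engine(engine, fit.estimates, ParameterSet.names(spec))


def sandwich_covariance(fit: FitResult, cohort, spec=None,
                        weights=None) -> CovarianceEstimate:
    """Robust covariance for the inclusion-weighted likelihood fit."""
    spec = spec or fit.spec
    engine = build_engine(cohort, spec, fit.variant, weights)
    return sandwich_from_engine(engine, fit.estimates, ParameterSet.names(spec))


def attach_covariance(fit: FitResult, cohort, method: str = "fisher",
                      weights=None) -> FitResult:
    """Convenience: compute and attach a covariance estimate to a fit."""
    if method == "fisher":
        fit.covariance = fisher_covariance(fit, cohort, weights=weights)
    elif method == "sandwich":
        fit.covariance = sandwich_covariance(fit, cohort, weights=weights)
    else:
        raise ValueError(f"unknown covariance method {method!r}")
    return fit


def wald_test(estimate: float, se: float) -> tuple[float, float]:
    """Two-sided Wald z statistic and p-value."""
    if not se > 0:
        raise ValueError("se must be > 0")
    z = estimate / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def confidence_interval(estimate: float, se: float, level: float = 0.95):
    """Wald confidence interval; the 95% level uses the printed 1.96."""
    if not se > 0:
        raise ValueError("se must be > 0")
    z = 1.96 if abs(level - 0.95) < 1e-12 else float(stats.norm.ppf(0.5 + level / 2))
    return estimate - z * se, estimate + z * se


def bonferroni(pvals) -> np.ndarray:
    """Bonferroni-adjusted p-values: ``min(1, p * n)`` elementwise."""
    p = np.atleast_1d(np.asarray(pvals, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)
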