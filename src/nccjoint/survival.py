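"""Survival sub-model: cause-specific hazards with piecewise-constant
baselines and the conditional survival density given the random effect.

For competing event ``k`` the hazard is

    lambda_k(t | b) = lambda_0k(t) * exp(beta_k * traj(t; b) + alpha_k' X^(2)),

with ``traj`` the current biomarker trajectory value (longitudinal
sub-model predictor passed through the inverse link) and
``lambda_0k(t) = sum_q xi_kq 1{v_{q-1} < t <= v_q}`` a piecewise-constant
baseline on the knot grid.  With the identity link and a time-linear
predictor the cumulative hazard has a closed form per piece; otherwise it is
integrated by fixed-order Gauss-Legendre within each piece.  With K=1 the
model is an ordinary piecewise-exponential proportional-hazards model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import JointModelSpec, ParameterSet, SubjectRecord
from .longitudinal import trajectory_value

__all__ = [
    "BaselineHazard",
    "piece_index",
    "hazard_at",
    "cumulative_hazard",
    "loglik_survival_conditional",
]


@dataclass
class BaselineHazard:
    """Piecewise-constant baseline hazards for all causes."""

    knots: np.ndarray       # v_0 = 0 < v_1 < ... < v_Q
    heights: np.ndarray     # (K, Q) positive

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.heights = np.atleast_2d(np.asarray(self.heights, dtype=float))
        if np.any(self.heights <= 0):
            raise ValueError("baseline heights must be positive")
        if self.heights.shape[1] != self.knots.size - 1:
            raise ValueError("heights must have one column per piece")

    def at(self, t, cause: int):
        """Baseline hazard of ``cause`` (1-based) at time(s) t."""
        q = piece_index(t, self.knots)
        return self.heights[cause - 1, q]


def piece_index(t, knots) -> np.ndarray:
    """Index of the half-open piece ``(v_{q-1}, v_q]`` containing t.

    Events at exactly ``t = v_q`` belong to piece q.
    """
    t = np.asarray(t, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if np.any(t <= 0) or np.any(t > knots[-1]):
        raise ValueError("time outside (0, v_Q]")
    return np.searchsorted(knots, t, side="left") - 1


def _traj(t, b, x_long, params: ParameterSet, spec: JointModelSpec):
    return trajectory_value(t, x_long, params.gamma, b, spec.link)


def hazard_at(t, cause: int, b, x_long, x_surv, params: ParameterSet,
              spec: JointModelSpec):
    """Cause-specific hazard ``lambda_k(t | b)`` (cause is 1-based)."""
    base = BaselineHazard(spec.baseline_knots, params.xi).at(t, cause)
    k = cause - 1
    x_surv = np.atleast_1d(np.asarray(x_surv, dtype=float)) if np.size(x_surv) else np.empty(0)
    lin = params.beta[k] * _traj(t, b, x_long, params, spec)
    if x_surv.size:
        lin = lin + params.alpha[k] @ x_surv
    return base * np.exp(lin)


def cumulative_hazard(T, cause: int, b, x_long, x_surv, params: ParameterSet,
                      spec: JointModelSpec) -> float:
    """Cumulative cause-specific hazard ``int_0^T lambda_k(s|b) ds``.

    Uses the exact piecewise closed form for the Gaussian/identity model
    (exponential-of-linear integrand) and Gauss-Legendre quadrature of order
    ``spec.gl_order`` per piece otherwise.
    """
    T = float(T)
    if T < 0 or T > spec.baseline_knots[-1] + 1e-12:
        raise ValueError("T outside [0, v_Q]")
    if T == 0.0:
        return 0.0
    k = cause - 1
    x_surv = np.atleast_1d(np.asarray(x_surv, dtype=float)) if np.size(x_surv) else np.empty(0)
    ax = float(params.alpha[k] @ x_surv) if x_surv.size else 0.0
    knots = spec.baseline_knots
    lo = knots[:-1]
    hi = np.minimum(knots[1:], T)
    active = hi > lo
    xi = params.xi[k]
    if xi.size != spec.Q:
        raise ValueError(f"expected {spec.Q} baseline heights per cause, got {xi.size}")

    if spec.link == "identity":
        # integrand per piece: xi * exp(beta*(gamma_t s + c)) with
        # c = gamma_x' x_long + b + alpha' x_surv / beta folded outside
        gamma_t = params.gamma[0]
        c = (params.gamma[1:] @ np.atleast_1d(x_long) if np.size(x_long) else 0.0) + b
        u = params.beta[k] * gamma_t
        pref = np.exp(params.beta[k] * c + ax)
        with np.errstate(over="raise"):
            if abs(u) > 1e-12:
                seg = (np.exp(u * hi[active]) - np.exp(u * lo[active])) / u
            else:
                seg = hi[active] - lo[active]
        out = pref * float(xi[active] @ seg)
    else:
        nodes, weights = np.polynomial.legendre.leggauss(spec.gl_order)
        out = 0.0
        for q in np.nonzero(active)[0]:
            a, bnd = lo[q], hi[q]
            s = 0.5 * (bnd - a) * nodes + 0.5 * (bnd + a)
            vals = np.exp(params.beta[k] * _traj(s, b, x_long, params, spec) + ax)
            out += xi[q] * 0.5 * (bnd - a) * float(weights @ vals)
    if not np.isfinite(out):
        raise FloatingPointError("nonfinite cumulative hazard")
    return float(out)


def loglik_survival_conditional(record: SubjectRecord, b, params: ParameterSet,
                                spec: JointModelSpec) -> float:
    """Conditional log-density of ``(T, delta)`` given the random effect.

    Event subjects contribute ``log lambda_delta(T|b)`` plus the common
    survival factor ``-sum_k Lambda_k(T|b)``; censored subjects contribute
    only the latter.
    """
    T, delta = record.T, record.delta
    if T == 0.0 and delta != 0:
        raise ValueError("event at T=0 has zero density")
    out = 0.0
    if delta != 0:
        out += float(np.log(hazard_at(T, delta, b, record.X_long, record.X_surv,
                                      params, spec)))
    for k in range(1, spec.K + 1):
        out -= cumulative_hazard(T, k, b, record.X_long, record.X_surv, params, spec)
    return out
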