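"""Longitudinal sub-model: conditional densities of the biomarker series
given the random intercept.

The biomarker follows a generalized linear mixed model: conditional on the
subject-specific random intercept ``b ~ N(0, theta^2)``, the linear
predictor is ``eta = X^(1) gamma + b`` where the fixed design ``X^(1)``
contains the observation time (first column) and baseline covariates.  Two
family/link pairs are supported:

- Gaussian / identity: ``Y_ij | b ~ N(eta_ij, sigma^2)``;
- negative binomial / log: mean ``mu_ij = exp(eta_ij)``, dispersion ``phi``
  with ``Var(Y_ij | b) = mu_ij + phi mu_ij^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "LongitudinalDesign",
    "linear_predictor",
    "loglik_conditional",
    "trajectory_value",
    "marginal_gaussian_loglik",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class LongitudinalDesign:
    """Per-observation fixed and random designs for one subject.

    ``X`` has one row per observation with the observation time in the first
    column; ``Z`` is the random-effect design (a column of ones for the
    random-intercept model).
    """

    X: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.X.shape[0] != self.Z.shape[0]:
            raise ValueError("X and Z must have the same number of rows")

    @classmethod
    def from_times(cls, times, x_long=()) -> "LongitudinalDesign":
        times = np.atleast_1d(np.asarray(times, dtype=float))
        x_long = np.atleast_1d(np.asarray(x_long, dtype=float))
        X = np.column_stack([times] + [np.full(times.size, v) for v in x_long]) \
            if x_long.size else times[:, None]
        return cls(X=X, Z=np.ones((times.size, 1)))


def linear_predictor(design: LongitudinalDesign, gamma, b) -> np.ndarray:
    """Linear predictor ``X gamma + Z b`` per observation."""
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if design.X.shape[1] != gamma.size:
        raise ValueError(
            f"gamma has length {gamma.size}, design has {design.X.shape[1]} columns"
        )
    if design.Z.shape[1] != b.size:
        raise ValueError("random-effect dimension mismatch")
    return design.X @ gamma + design.Z @ b


def loglik_conditional(Y, design: LongitudinalDesign, gamma, dispersion, b,
                       family: str = "gaussian") -> float:
    """Conditional log-likelihood of the series given the random effect.

    ``dispersion`` is sigma (residual SD) for the Gaussian family and phi
    (overdispersion) for the negative binomial.
    """
    Y = np.atleast_1d(np.asarray(Y, dtype=float))
    eta = linear_predictor(design, gamma, b)
    if family == "gaussian":
        sigma = float(dispersion)
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        r = Y - eta
        return float(-0.5 * Y.size * (_LOG_2PI + 2 * np.log(sigma))
                     - 0.5 * np.sum(r * r) / sigma**2)
    if family == "negative_binomial":
        phi = float(dispersion)
        if phi <= 0:
            raise ValueError("phi must be > 0")
        if np.any(Y < 0) or np.any(Y != np.round(Y)):
            raise ValueError("negative binomial requires nonnegative integer Y")
        mu = np.exp(eta)
        r = 1.0 / phi  # NB "size": Var = mu + phi mu^2
        return float(np.sum(
            special.gammaln(Y + r) - special.gammaln(r) - special.gammaln(Y + 1)
            + r * np.log(r / (r + mu)) + Y * np.log(mu / (r + mu))
        ))
    raise ValueError(f"unknown family {family!r}")


def trajectory_value(t, x_long, gamma, b, link: str = "identity"):
    """Biomarker trajectory ``g^{-1}(X^(1) gamma + Z b)`` at time ``t``.

    This is the time-varying quantity the cause-specific hazards act on.
    """
    t = np.asarray(t, dtype=float)
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    x_long = np.atleast_1d(np.asarray(x_long, dtype=float)) if np.size(x_long) else np.empty(0)
    eta = gamma[0] * t + (x_long @ gamma[1:] if x_long.size else 0.0) + b
    if link == "identity":
        return eta
    if link == "log":
        return np.exp(eta)
    raise ValueError(f"unknown link {link!r}")


def marginal_gaussian_loglik(Y, design: LongitudinalDesign, gamma, sigma, theta) -> float:
    """Closed-form marginal (over b) Gaussian log-likelihood.

    For the random-intercept model the marginal law of the series is
    multivariate normal with mean ``X gamma`` and compound-symmetry
    covariance ``theta^2 J + sigma^2 I``.  Used as an independent oracle for
    the quadrature-based marginal likelihood.
    """
    Y = np.atleast_1d(np.asarray(Y, dtype=float))
    n = Y.size
    mean = design.X @ np.atleast_1d(np.asarray(gamma, dtype=float))
    cov = theta**2 * np.ones((n, n)) + sigma**2 * np.eye(n)
    r = Y - mean
    sign, logdet = np.linalg.slogdet(cov)
    return float(-0.5 * (n * _LOG_2PI + logdet + r @ np.linalg.solve(cov, r)))
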