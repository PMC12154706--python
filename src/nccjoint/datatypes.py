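"""Core domain types.

The unit of analysis is a :class:`SubjectRecord`: one subject's observed
survival outcome (time, cause indicator), baseline covariates, nested
case-control (NCC) inclusion flag, and -- for subjects inside the NCC
sub-cohort -- a longitudinal biomarker series.  A :class:`JointModelSpec`
fixes the model structure (family/link, covariate maps, number of competing
events, baseline-hazard knots), and a :class:`ParameterSet` holds the packed
parameter vector the optimizer works on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SubjectRecord",
    "JointModelSpec",
    "ParameterSet",
    "FitResult",
    "CovarianceEstimate",
    "AbundanceTable",
]


@dataclass
class SubjectRecord:
    """One subject's outcome, covariates, and (optional) biomarker series.

    Parameters
    ----------
    subject_id : str or int
        Unique subject identifier.
    T : float
        Observed time: the minimum of the censoring time and the
        cause-specific event times.
    delta : int
        Event indicator in ``{0, ..., K}``; 0 means censored, ``k`` means
        competing event ``k`` occurred at ``T``.
    X_long : ndarray
        Baseline covariates entering the longitudinal fixed-effect design
        (besides time).  May be empty.
    X_surv : ndarray
        Baseline covariates entering the survival sub-model.  May be empty.
    match_vars : ndarray
        Values of the matching factors used by the NCC sampler.
    R : int
        NCC inclusion flag: 1 if the subject is in the sub-cohort (case or
        sampled control) and has biomarker data, else 0.
    times : ndarray or None
        Strictly increasing biomarker observation times, all ``<= T``.
        Present iff ``R == 1``.
    Y : ndarray or None
        Biomarker values, same length as ``times``.  Present iff ``R == 1``.
    """

    subject_id: object
    T: float
    delta: int
    X_long: np.ndarray = field(default_factory=lambda: np.empty(0))
    X_surv: np.ndarray = field(default_factory=lambda: np.empty(0))
    match_vars: np.ndarray = field(default_factory=lambda: np.empty(0))
    R: int = 0
    times: np.ndarray | None = None
    Y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X_long = np.atleast_1d(np.asarray(self.X_long, dtype=float))
        self.X_surv = np.atleast_1d(np.asarray(self.X_surv, dtype=float))
        self.match_vars = np.atleast_1d(np.asarray(self.match_vars))
        self.validate()

    def validate(self, K: int | None = None) -> None:
        if not np.isfinite(self.T) or self.T < 0:
            raise ValueError(f"subject {self.subject_id}: T must be finite and >= 0")
        if self.delta < 0 or (K is not None and self.delta > K):
            raise ValueError(
                f"subject {self.subject_id}: delta={self.delta} outside 0..{K}"
            )
        if self.R not in (0, 1):
            raise ValueError(f"subject {self.subject_id}: R must be 0 or 1")
        if self.R == 1:
            if self.times is None or self.Y is None:
                raise ValueError(
                    f"subject {self.subject_id}: R=1 requires times and Y"
                )
            self.times = np.asarray(self.times, dtype=float)
            self.Y = np.asarray(self.Y, dtype=float)
            if self.times.size == 0 or self.times.size != self.Y.size:
                raise ValueError(
                    f"subject {self.subject_id}: times and Y must have equal "
                    "positive length"
                )
            if np.any(np.diff(self.times) <= 0):
                raise ValueError(
                    f"subject {self.subject_id}: times must be strictly increasing"
                )
            if self.times[-1] > self.T + 1e-12:
                raise ValueError(
                    f"subject {self.subject_id}: longitudinal time "
                    f"{self.times[-1]} exceeds observed time {self.T}"
                )

    @property
    def n_obs(self) -> int:
        return 0 if self.times is None else int(self.times.size)


@dataclass
class JointModelSpec:
    """Structural specification of the joint model.

    ``gaussian`` pairs with the identity link and ``negative_binomial`` with
    the log link; other combinations are rejected.  ``baseline_knots`` is the
    increasing split ``0 = v_0 < v_1 < ... < v_Q`` of the time axis for the
    piecewise-constant cause-specific baseline hazards; every observed time
    must fall inside ``(0, v_Q]``.
    """

    K: int = 2
    family: str = "gaussian"
    link: str = "identity"
    longitudinal_covariate_names: tuple = ()
    survival_covariate_names: tuple = ()
    random_effects: str = "intercept_only"
    baseline_knots: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))
    n_quadrature: int = 15
    gl_order: int = 7  # Gauss-Legendre order per baseline piece (generic path)

    def __post_init__(self) -> None:
        self.baseline_knots = np.asarray(self.baseline_knots, dtype=float)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        pairs = {"gaussian": "identity", "negative_binomial": "log"}
        if self.family not in pairs:
            raise ValueError(f"unknown family {self.family!r}")
        if self.link != pairs[self.family]:
            raise ValueError(
                f"family {self.family!r} must use the {pairs[self.family]!r} link"
            )
        if self.random_effects != "intercept_only":
            raise NotImplementedError("only intercept_only random effects supported")
        kn = self.baseline_knots
        if kn.size < 2 or kn[0] != 0.0 or np.any(np.diff(kn) <= 0):
            raise ValueError("baseline_knots must be increasing with knots[0] == 0")
        if self.n_quadrature < 3:
            raise ValueError("n_quadrature must be >= 3")

    @property
    def Q(self) -> int:
        return self.baseline_knots.size - 1

    @property
    def p_long(self) -> int:
        """Length of gamma: time slope plus longitudinal baseline covariates."""
        return 1 + len(self.longitudinal_covariate_names)

    @property
    def p_surv(self) -> int:
        return len(self.survival_covariate_names)

    def with_knots(self, knots: Sequence[float]) -> "JointModelSpec":
        return replace(self, baseline_knots=np.asarray(knots, dtype=float))


@dataclass
class ParameterSet:
    """Packed/unpacked model parameters.

    Components (all unconstrained on the packed scale):

    - ``gamma``: longitudinal fixed effects, time slope first;
    - ``log_sigma`` (Gaussian residual log-SD) or ``log_phi`` (NB
      log-dispersion), depending on the family;
    - ``log_theta``: log-SD of the random intercept (log-Cholesky of the
      1x1 random-effect covariance);
    - ``beta``: trajectory association coefficients, one per competing event;
    - ``alpha``: (K, p_surv) survival covariate effects;
    - ``log_xi``: (K, Q) log baseline-hazard heights.
    """

    gamma: np.ndarray
    log_disp: float
    log_theta: float
    beta: np.ndarray
    alpha: np.ndarray
    log_xi: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        self.log_xi = np.atleast_2d(np.asarray(self.log_xi, dtype=float))

    # -- packing contract: unpack(pack(p)) == p exactly -------------------
    def pack(self) -> np.ndarray:
        return np.concatenate(
            [
                self.gamma,
                [self.log_disp, self.log_theta],
                self.beta,
                self.alpha.ravel(),
                self.log_xi.ravel(),
            ]
        )

    @classmethod
    def unpack(cls, x: np.ndarray, spec: JointModelSpec) -> "ParameterSet":
        x = np.asarray(x, dtype=float)
        p1, K, p2, Q = spec.p_long, spec.K, spec.p_surv, spec.Q
        n_expected = p1 + 2 + K + K * p2 + K * Q
        if x.size != n_expected:
            raise ValueError(f"expected {n_expected} packed parameters, got {x.size}")
        i = 0
        gamma = x[i : i + p1]; i += p1
        log_disp = float(x[i]); i += 1
        log_theta = float(x[i]); i += 1
        beta = x[i : i + K]; i += K
        alpha = x[i : i + K * p2].reshape(K, p2); i += K * p2
        log_xi = x[i:].reshape(K, Q)
        return cls(gamma, log_disp, log_theta, beta, alpha, log_xi)

    @staticmethod
    def names(spec: JointModelSpec) -> list[str]:
        disp = "log_sigma" if spec.family == "gaussian" else "log_phi"
        out = ["gamma_time"] + [f"gamma_{c}" for c in spec.longitudinal_covariate_names]
        out += [disp, "log_theta"]
        out += [f"beta_{k}" for k in range(1, spec.K + 1)]
        for k in range(1, spec.K + 1):
            out += [f"alpha_{k}_{c}" for c in spec.survival_covariate_names]
        for k in range(1, spec.K + 1):
            out += [f"log_xi_{k}_{q}" for q in range(1, spec.Q + 1)]
        return out

    # convenience accessors on the natural scale
    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_disp))

    @property
    def theta(self) -> float:
        return float(np.exp(self.log_theta))

    @property
    def xi(self) -> np.ndarray:
        return np.exp(self.log_xi)


@dataclass
class CovarianceEstimate:
    """Covariance of the packed parameter estimates."""

    method: str  # "fisher" or "sandwich"
    matrix: np.ndarray
    names: list[str]
    condition_number: float = np.nan
    pseudo_inverse_used: bool = False

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.matrix), 0.0, None))


@dataclass
class FitResult:
    """Maximum-likelihood fit of a joint-model likelihood variant."""

    variant: str
    spec: JointModelSpec
    params: ParameterSet
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    message: str = ""
    covariance: CovarianceEstimate | None = None
    n_subjects: int = 0

    @property
    def estimates(self) -> np.ndarray:
        return self.params.pack()

    @property
    def names(self) -> list[str]:
        return ParameterSet.names(self.spec)

    def estimate(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def se(self, name: str) -> float:
        if self.covariance is None:
            raise ValueError("fit has no covariance attached")
        return float(self.covariance.se[self.names.index(name)])

    def to_dict(self) -> dict:
        out = {
            "variant": self.variant,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "n_subjects": self.n_subjects,
            "estimates": dict(zip(self.names, map(float, self.estimates))),
        }
        if self.covariance is not None:
            out["se_method"] = self.covariance.method
            out["se"] = dict(zip(self.names, map(float, self.covariance.se)))
        return out


@dataclass
class AbundanceTable:
    """Samples-by-taxa relative abundance matrix with sample metadata.

    ``values`` holds relative abundances in ``[0, 1]`` (NaN marks a missing
    measurement, distinct from a structural zero); ``samples`` is a metadata
    frame indexed like the rows with at least ``subject_id`` and ``time``
    columns.
    """

    values: "pandas.DataFrame"  # noqa: F821 - imported lazily by io
    samples: "pandas.DataFrame"  # noqa: F821

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(v, initial=0.0) < -1e-12 or np.nanmax(v, initial=0.0) > 1 + 1e-12:
                raise ValueError("relative abundances must lie in [0, 1]")
            sums = np.nansum(v, axis=1)
        if np.any(sums > 1 + 1e-6):
            raise ValueError("per-sample abundance sums exceed 1")
        if not self.values.index.equals(self.samples.index):
            raise ValueError("values and samples must share an index")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]
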