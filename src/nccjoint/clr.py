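"""Conditional logistic regression (CLR) for matched case-control sets.

The standard cross-sectional comparator: each cause-specific case and its
matched controls form one stratum, the subject's *average* biomarker value
stands in for the longitudinal trajectory, and the conditional likelihood

    L(beta) = prod_sets exp(beta' x_case) / sum_{r in set} exp(beta' x_r)

is maximized directly.  CLR cannot use time-varying covariates or model
competing risks; it is included to quantify exactly that limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["MatchedSet", "CLRResult", "build_matched_sets", "clr_fit",
           "clr_loglik"]


@dataclass
class MatchedSet:
    """One case row plus its matched control rows (case row first)."""

    set_id: object
    X: np.ndarray                 # (1 + n_controls, p); row 0 is the case
    subject_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] < 2:
            raise ValueError("a matched set needs at least one control")


@dataclass
class CLRResult:
    names: list
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    separated: bool
    n_sets: int
    dropped_covariates: list = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def estimate(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        i = self.names.index(name)
        z = self.beta[i] / self.se[i]
        return float(2 * stats.norm.sf(abs(z)))


def build_matched_sets(sample, cohort, cause: int) -> list[MatchedSet]:
    """Matched sets for one competing event.

    One set per cause-``cause`` case with the controls drawn for it at
    sampling time; covariates are the subject's mean biomarker value over
    all available observations followed by the survival covariates.  Cases
    of other causes form no set here; a case whose control draw was empty is
    dropped with a warning.
    """
    by_id = {r.subject_id: r for r in cohort}

    def _row(sid):
        r = by_id[sid]
        if r.Y is None:
            raise ValueError(f"subject {sid} has no longitudinal data")
        return np.concatenate([[float(np.mean(r.Y))], r.X_surv])

    sets = []
    for j, cid in enumerate(sample.case_ids):
        if sample.delta[sample.case_index[j]] != cause:
            continue
        controls = sample.controls_per_case[j]
        if len(controls) == 0:
            warnings.warn(f"case {cid} has no controls; set dropped")
            continue
        rows = [_row(cid)] + [_row(c) for c in controls]
        sets.append(MatchedSet(set_id=cid, X=np.vstack(rows),
                               subject_ids=[cid, *controls]))
    return sets


def clr_loglik(sets, beta) -> float:
    """Conditional log-likelihood at ``beta``."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    out = 0.0
    for s in sets:
        eta = s.X @ beta
        out += eta[0] - (eta.max() + np.log(np.exp(eta - eta.max()).sum()))
    return float(out)


def _grad_hess(sets, beta):
    p = beta.size
    g = np.zeros(p)
    H = np.zeros((p, p))
    for s in sets:
        eta = s.X @ beta
        w = np.exp(eta - eta.max())
        w /= w.sum()
        xbar = w @ s.X
        g += s.X[0] - xbar
        Xc = s.X - xbar
        H -= (Xc * w[:, None]).T @ Xc
    return g, H


def clr_fit(sets, covariate_names) -> CLRResult:
    """Maximize the conditional likelihood by Newton/quasi-Newton.

    Covariates constant within every matched set (e.g. exact matching
    factors) are inestimable and dropped with a warning.  Separation
    (unbounded likelihood with diverging estimates) is flagged, not raised.
    """
    if not sets:
        raise ValueError("no matched sets")
    names = list(covariate_names)
    X0 = np.vstack([s.X for s in sets])
    keep = []
    dropped = []
    for j in range(X0.shape[1]):
        if all(np.ptp(s.X[:, j]) < 1e-12 for s in sets):
            dropped.append(names[j])
        else:
            keep.append(j)
    if dropped:
        warnings.warn(f"dropping within-set-constant covariates: {dropped}")
        sets = [MatchedSet(s.set_id, s.X[:, keep], s.subject_ids) for s in sets]
        names = [names[j] for j in keep]
    p = len(names)
    if p == 0:
        raise ValueError("no estimable covariates remain")

    # damped Newton on the (concave) conditional log-likelihood
    beta = np.zeros(p)
    ll = clr_loglik(sets, beta)
    converged = False
    for _ in range(100):
        g, H = _grad_hess(sets, beta)
        if np.max(np.abs(g)) < 1e-9 * (1 + abs(ll)):
            converged = True
            break
        try:
            step = np.linalg.solve(-H + 1e-12 * np.eye(p), g)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            ll_new = clr_loglik(sets, cand)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta, ll = cand, ll_new
        if np.max(np.abs(beta)) > 1e4:
            break
    g, H = _grad_hess(sets, beta)
    # separation: the fitted linear predictor perfectly orders some set,
    # so the within-set spread of eta diverges as the loglik approaches 0
    eta_spread = max(float(np.ptp(s.X @ beta)) for s in sets)
    separated = bool(eta_spread > 15 or np.linalg.cond(-H) > 1e12)
    if separated:
        warnings.warn("possible separation: estimates diverging with "
                      "nondecreasing conditional likelihood")
    cov = np.linalg.pinv(-H)
    return CLRResult(names=names, beta=beta, cov=0.5 * (cov + cov.T),
                     loglik=float(ll),
                     converged=converged and not separated,
                     separated=separated, n_sets=len(sets),
                     dropped_covariates=dropped)
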