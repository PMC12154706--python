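"""Nested case-control sampling: case selection, administrative censoring,
matched risk-set control draws, and inverse-inclusion-probability weights.

Case selection follows the first-``n_cases`` rule: the ``n_cases`` earliest
latent event times become the cases (with their true causes) and the
largest case event time becomes the administrative censoring time for
everyone else.  For each case, ``m`` controls are drawn uniformly without
replacement from its risk set: subjects still event-free and uncensored at
the case's event time that match the case exactly on the matching factors
(future cases may serve as controls).  A control's inclusion weight is the
inverse of its probability of ever being sampled,

    w_i = [1 - prod_{l in S_i} (1 - m_l / n_l)]^{-1},

where ``S_i`` is the set of cases for whose risk set subject i was eligible
(whether or not it was drawn), ``n_l`` the risk-set size of case l and
``m_l`` the number of controls actually drawn for it.  Cases always have
weight 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import SubjectRecord

__all__ = ["NCCSample", "select_cases_and_censor", "draw_controls", "compute_weights"]


@dataclass
class NCCSample:
    """Outcome of NCC sampling over one cohort.

    Per-cohort arrays are aligned with ``subject_ids``; per-case arrays are
    aligned with ``case_ids`` (ordered by event time, ties broken by id).
    """

    subject_ids: np.ndarray
    T: np.ndarray
    delta: np.ndarray
    stratum: np.ndarray          # integer stratum code per subject
    R: np.ndarray                # sub-cohort flag per subject
    censor_time: float
    case_ids: np.ndarray
    case_index: np.ndarray       # positions of cases in the cohort arrays
    n_risk: np.ndarray           # n_l per case
    m_drawn: np.ndarray          # m_l per case
    controls_per_case: list = field(default_factory=list)  # arrays of subject ids
    weights: np.ndarray | None = None  # per-subject; NaN outside sub-cohort

    def is_case(self, pos: int) -> bool:
        return self.delta[pos] != 0

    def eligible_cases(self, pos: int) -> np.ndarray:
        """Indices (into case arrays) of cases subject ``pos`` was eligible for."""
        at_risk = (self.T[pos] > self.T[self.case_index]) | (
            (self.T[pos] == self.T[self.case_index]) & (self.delta[pos] == 0)
        )
        same = self.stratum[self.case_index] == self.stratum[pos]
        not_self = self.case_index != pos
        return np.nonzero(at_risk & same & not_self)[0]

    def weight_of(self, subject_id) -> float:
        pos = int(np.nonzero(self.subject_ids == subject_id)[0][0])
        return float(self.weights[pos])


def _stratum_codes(records, match_vars_mask=None) -> np.ndarray:
    keys = [tuple(np.atleast_1d(r.match_vars)) for r in records]
    uniq = {k: i for i, k in enumerate(sorted(set(keys)))}
    return np.array([uniq[k] for k in keys])


def select_cases_and_censor(cohort, n_cases: int = 400):
    """Select the ``n_cases`` earliest events and censor everyone else.

    Returns ``(case_ids, censor_time, observed_cohort)`` where the observed
    cohort is a new list of records with ``T``/``delta`` replaced by their
    observed values and longitudinal observations trimmed to ``t <= T``.
    """
    events = [(r.T, r.subject_id, i) for i, r in enumerate(cohort) if r.delta != 0]
    if len(events) < n_cases:
        raise ValueError(f"cohort has {len(events)} events, fewer than {n_cases}")
    events.sort()
    chosen = events[:n_cases]
    censor_time = max(t for t, _, _ in chosen)
    case_pos = {i for _, _, i in chosen}
    case_ids = np.array([sid for _, sid, _ in chosen])

    observed = []
    for i, r in enumerate(cohort):
        if i in case_pos:
            T, delta = r.T, r.delta
        else:
            T, delta = censor_time, 0
        times = Y = None
        if r.times is not None:
            keep = r.times <= T + 1e-12
            times, Y = r.times[keep], r.Y[keep]
            if times.size == 0:
                times = Y = None
        observed.append(
            SubjectRecord(
                subject_id=r.subject_id, T=float(T), delta=int(delta),
                X_long=r.X_long, X_surv=r.X_surv, match_vars=r.match_vars,
                R=0, times=times, Y=Y,
            )
        )
    return case_ids, float(censor_time), observed


def draw_controls(cohort, case_ids, m: int, rng) -> NCCSample:
    """Draw ``m`` matched controls per case from its risk set.

    ``cohort`` must be the observed (censored) cohort.  When a risk set has
    fewer than ``m`` members, all are taken; an empty risk set yields zero
    controls with a warning.  Sets ``R=1`` on case and sampled-control
    records.  A subject may be sampled for several cases.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    ids = np.array([r.subject_id for r in cohort])
    T = np.array([r.T for r in cohort])
    delta = np.array([r.delta for r in cohort])
    stratum = _stratum_codes(cohort)
    pos_of = {sid: i for i, sid in enumerate(ids)}
    case_index = np.array([pos_of[sid] for sid in case_ids])
    order = np.lexsort((ids[case_index], T[case_index]))
    case_index = case_index[order]
    case_ids = ids[case_index]
    censor_time = float(T[case_index].max())

    R = np.zeros(len(cohort), dtype=int)
    R[case_index] = 1
    n_risk = np.zeros(case_index.size, dtype=int)
    m_drawn = np.zeros(case_index.size, dtype=int)
    controls_per_case: list[np.ndarray] = []
    for j, ci in enumerate(case_index):
        at_risk = (T > T[ci]) | ((T == T[ci]) & (delta == 0))
        eligible = at_risk & (stratum == stratum[ci])
        eligible[ci] = False
        pool = np.nonzero(eligible)[0]
        n_risk[j] = pool.size
        if pool.size == 0:
            warnings.warn(f"empty risk set for case {ids[ci]}; zero controls drawn")
            controls_per_case.append(np.empty(0, dtype=ids.dtype))
            continue
        take = min(m, pool.size)
        drawn = rng.choice(pool, size=take, replace=False)
        m_drawn[j] = take
        R[drawn] = 1
        controls_per_case.append(ids[np.sort(drawn)])

    for i, r in enumerate(cohort):
        r.R = int(R[i])
        if r.R == 1 and r.times is None:
            raise ValueError(f"sampled subject {r.subject_id} has no longitudinal data")

    sample = NCCSample(
        subject_ids=ids, T=T, delta=delta, stratum=stratum, R=R,
        censor_time=censor_time, case_ids=case_ids, case_index=case_index,
        n_risk=n_risk, m_drawn=m_drawn, controls_per_case=controls_per_case,
    )
    compute_weights(sample)
    return sample


def compute_weights(sample: NCCSample) -> np.ndarray:
    """Inverse inclusion-probability weights for every sub-cohort subject.

    Vectorized over strata: within a stratum the log non-inclusion
    probability of a subject is the sum of ``log(1 - m_l/n_l)`` over the
    cases whose risk sets contained it.
    """
    if np.any(sample.m_drawn > sample.n_risk):
        raise ValueError("m_drawn exceeds risk-set size")
    weights = np.full(sample.subject_ids.size, np.nan)
    cT = sample.T[sample.case_index]
    with np.errstate(divide="ignore"):
        log_miss = np.log1p(-sample.m_drawn / np.maximum(sample.n_risk, 1))
    for s in np.unique(sample.stratum):
        in_s = sample.stratum == s
        c_in_s = sample.stratum[sample.case_index] == s
        ct = cT[c_in_s]          # already time-ordered
        lm = log_miss[c_in_s]
        cum = np.concatenate([[0.0], np.cumsum(lm)])
        pos = np.nonzero(in_s & (sample.R == 1))[0]
        for i in pos:
            if sample.delta[i] != 0:
                weights[i] = 1.0
                continue
            # censored: at risk for every case with T_l < T_i, plus ties
            n_elig = int(np.searchsorted(ct, sample.T[i], side="right"))
            if n_elig == 0:
                raise ValueError(
                    f"sampled control {sample.subject_ids[i]} eligible for no case"
                )
            p_incl = -np.expm1(cum[n_elig])
            weights[i] = 1.0 / p_incl
    sample.weights = weights
    return weights
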