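"""Simulation-study harness and per-taxon association scans.

`run_scenario` repeats simulate -> NCC-sample -> fit for every requested
method and summarizes estimates into the usual operating characteristics:
Bias, mean estimated SE, empirical SE (SD of estimates across replicates,
n-1 denominator), MSE, mean 95% CI length, empirical coverage probability,
and the Wald rejection rate of H0: parameter = 0.  Non-convergent
replicates are excluded from the summaries and counted.

`taxon_scan` drives one joint-model fit per taxon of a pre-filtered,
transformed abundance table (the taxon's series as the longitudinal
outcome) with Bonferroni adjustment across taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import clr as clr_mod
from .datatypes import JointModelSpec, SubjectRecord
from .estimation import ModelData, fit
from .inference import fisher_covariance, sandwich_covariance, wald_test
from .sampling import draw_controls, select_cases_and_censor
from .simulate import SimConfig, simulate_cohort

__all__ = [
    "ScenarioGrid",
    "MetricRow",
    "TaxonMatrix",
    "run_replicate",
    "run_scenario",
    "summarize",
    "power_curve",
    "taxon_scan",
    "truth_values",
]

ALL_METHODS = ("oracle", "fjm_ncc", "wjm_ncc", "wjm_ncc_fisher", "naive_jm", "clr")


@dataclass
class TaxonMatrix:
    """Sample-by-taxon matrix of *transformed* biomarker values.

    Same layout as :class:`~nccjoint.datatypes.AbundanceTable` but without
    the raw relative-abundance bounds, so it can hold arcsine-sqrt (or any
    other) transformed series ready for the per-taxon scan.
    """

    values: pd.DataFrame
    samples: pd.DataFrame


@dataclass
class ScenarioGrid:
    """A sweep of simulation settings.

    The global-null scenario is ``beta1_values=(0,)`` with ``beta2=0``; the
    alternative fixes ``beta2=0.1`` and sweeps ``beta1``.
    """

    beta1_values: tuple = (0.0,)
    beta2: float = 0.0
    m_values: tuple = (1,)
    n_reps: int = 200
    seed_base: int = 1
    methods: tuple = ALL_METHODS
    sim: SimConfig = field(default_factory=SimConfig)
    track: tuple = ("beta_1", "beta_2")


@dataclass
class MetricRow:
    method: str
    m: int
    beta1: float
    parameter: str
    truth: float
    bias: float
    se: float
    ese: float
    mse: float
    ci_length: float
    ecp: float
    rejection_rate: float
    n_converged: int
    n_failed: int


def truth_values(config: SimConfig, spec: JointModelSpec) -> dict:
    """True parameter values on the fitted (packed) scale."""
    truth = {
        "gamma_time": config.gamma,
        "log_sigma": 0.5 * np.log(config.sigma2),
        "log_theta": 0.5 * np.log(config.theta2),
    }
    for k in range(config.K):
        truth[f"beta_{k + 1}"] = float(config.beta[k])
        for c in spec.survival_covariate_names:
            truth[f"alpha_{k + 1}_{c}"] = config.alpha
        for q in range(1, spec.Q + 1):
            truth[f"log_xi_{k + 1}_{q}"] = float(config.log_baselines[k])
    return truth


def _spec_for(config: SimConfig, max_T: float, Q: int = 1,
              n_quadrature: int = 15) -> JointModelSpec:
    knots = np.linspace(0.0, max_T, Q + 1)
    return JointModelSpec(K=config.K, survival_covariate_names=("X2",),
                          baseline_knots=knots, n_quadrature=n_quadrature)


def run_replicate(config: SimConfig, m: int, methods=ALL_METHODS,
                  sampling_seed: int | None = None, Q: int = 1,
                  n_quadrature: int = 15) -> list[dict]:
    """One simulate -> sample -> fit cycle; returns tidy estimate rows."""
    cohort = simulate_cohort(config)
    case_ids, censor_time, observed = select_cases_and_censor(
        cohort, config.n_cases_target
    )
    rng = np.random.default_rng(config.seed if sampling_seed is None else sampling_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sample = draw_controls(observed, case_ids, m, rng)
    spec = _spec_for(config, censor_time, Q=Q, n_quadrature=n_quadrature)
    data = ModelData(observed, spec)
    rows: list[dict] = []

    def emit(method, names_to_est_se, converged):
        for param, (est, se) in names_to_est_se.items():
            rows.append({
                "method": method, "m": m, "parameter": param,
                "estimate": est, "se": se, "converged": bool(converged),
            })

    def jm_results(res, cov):
        return {name: (float(res.estimates[i]), float(cov.se[i]))
                for i, name in enumerate(res.names)}

    wjm_fit = None
    for method in methods:
        if method == "oracle" or method == "fjm_ncc":
            res = fit(data, spec, variant=method)
            cov = fisher_covariance(res, data)
            emit(method, jm_results(res, cov), res.converged)
        elif method in ("wjm_ncc", "wjm_ncc_fisher"):
            if wjm_fit is None:
                wjm_fit = fit(data, spec, variant="wjm_ncc", weights=sample.weights)
            res = wjm_fit
            if method == "wjm_ncc":
                cov = sandwich_covariance(res, data, weights=sample.weights)
            else:
                cov = fisher_covariance(res, data, weights=sample.weights)
            emit(method, jm_results(res, cov), res.converged)
        elif method == "naive_jm":
            res = fit(data, spec, variant="naive_jm")
            cov = fisher_covariance(res, data)
            emit(method, jm_results(res, cov), res.converged)
        elif method == "clr":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for k in range(1, spec.K + 1):
                    sets = clr_mod.build_matched_sets(sample, observed, cause=k)
                    if not sets:
                        emit("clr", {f"beta_{k}": (np.nan, np.nan)}, False)
                        continue
                    res = clr_mod.clr_fit(sets, ["biomarker_mean", "X2"])
                    j = res.names.index("biomarker_mean")
                    emit("clr", {f"beta_{k}": (float(res.beta[j]), float(res.se[j]))},
                         res.converged)
        else:
            raise ValueError(f"unknown method {method!r}")
    return rows


def summarize(estimates: pd.DataFrame, truth: dict, beta1: float = np.nan,
              level_z: float = 1.96, alpha: float = 0.05) -> pd.DataFrame:
    """Aggregate tidy per-replicate estimates into MetricRow records."""
    out = []
    for (method, m, param), grp in estimates.groupby(
            ["method", "m", "parameter"], sort=False):
        ok = grp[grp["converged"] & np.isfinite(grp["estimate"]) & np.isfinite(grp["se"])]
        n_failed = len(grp) - len(ok)
        if not len(ok):
            out.append(MetricRow(method, m, beta1, param, truth.get(param, np.nan),
                                 *[np.nan] * 7, 0, n_failed))
            continue
        est = ok["estimate"].to_numpy()
        se = ok["se"].to_numpy()
        tv = truth.get(param, np.nan)
        lo, hi = est - level_z * se, est + level_z * se
        z = est / se
        from scipy.stats import norm
        pvals = 2 * norm.sf(np.abs(z))
        out.append(MetricRow(
            method=method, m=int(m), beta1=beta1, parameter=param, truth=tv,
            bias=float(np.mean(est) - tv),
            se=float(np.mean(se)),
            ese=float(np.std(est, ddof=1)) if len(est) > 1 else np.nan,
            mse=float(np.mean((est - tv) ** 2)),
            ci_length=float(np.mean(hi - lo)),
            ecp=float(np.mean((lo <= tv) & (tv <= hi))),
            rejection_rate=float(np.mean(pvals < alpha)),
            n_converged=len(ok), n_failed=n_failed,
        ))
    return pd.DataFrame([r.__dict__ for r in out])


def run_scenario(grid: ScenarioGrid, progress=None) -> pd.DataFrame:
    """Full scenario sweep; returns one MetricRow per cell.

    Replicate ``r`` uses simulation seed ``seed_base + r`` and a separate
    control-sampling stream, so any cell reruns bit-identically.
    """
    frames = []
    for beta1 in grid.beta1_values:
        config = replace(grid.sim, beta=np.array([beta1, grid.beta2]))
        for m in grid.m_values:
            rows = []
            for r in range(grid.n_reps):
                cfg = replace(config, seed=grid.seed_base + r)
                try:
                    rows += run_replicate(cfg, m, grid.methods,
                                          sampling_seed=grid.seed_base + r + 100_000)
                except Exception as exc:  # a failed replicate is reported, not fatal
                    warnings.warn(f"replicate {r} (m={m}, beta1={beta1}) failed: {exc}")
                if progress is not None:
                    progress(beta1, m, r)
            est = pd.DataFrame(rows)
            est = est[est["parameter"].isin(grid.track)] if grid.track else est
            spec = _spec_for(config, 1.0)
            frames.append(summarize(est, truth_values(config, spec), beta1=beta1))
    return pd.concat(frames, ignore_index=True)


def power_curve(grid: ScenarioGrid, method: str, cause: int = 1) -> pd.DataFrame:
    """Rejection rate of H0: beta_cause = 0 along the beta1 sweep."""
    g = replace(grid, methods=(method if isinstance(method, tuple) else (method,)),
                track=(f"beta_{cause}",))
    table = run_scenario(g)
    rows = table[table["parameter"] == f"beta_{cause}"]
    return rows[["method", "m", "beta1", "rejection_rate", "n_converged"]].reset_index(
        drop=True
    )


def taxon_scan(abundance, surv_records, spec: JointModelSpec,
               variant: str = "fjm_ncc", weights=None,
               alpha_level: float = 0.05) -> pd.DataFrame:
    """Per-taxon joint-model scan with Bonferroni adjustment across taxa.

    ``abundance`` must already be filtered and transformed; each taxon's
    series becomes the longitudinal outcome of one fit.  Per-taxon
    non-convergence is recorded and the scan continues.
    """
    results = []
    for taxon in abundance.values.columns:
        records = []
        for r in surv_records:
            mask = abundance.samples["subject_id"] == r.subject_id
            sub = abundance.samples[mask]
            vals = abundance.values.loc[mask, taxon]
            keep = sub["time"].to_numpy() <= r.T + 1e-12
            times = sub["time"].to_numpy()[keep]
            y = vals.to_numpy()[keep]
            order = np.argsort(times)
            times, y = times[order], y[order]
            finite = np.isfinite(y)
            times, y = times[finite], y[finite]
            has = times.size > 0
            records.append(SubjectRecord(
                subject_id=r.subject_id, T=r.T, delta=r.delta, X_long=r.X_long,
                X_surv=r.X_surv, match_vars=r.match_vars,
                R=1 if (r.R == 1 and has) else 0,
                times=times if has else None, Y=y if has else None,
            ))
        row = {"taxon": taxon, "converged": False}
        try:
            res = fit(records, spec, variant=variant, weights=weights)
            if variant == "wjm_ncc":
                cov = sandwich_covariance(res, records, weights=weights)
            else:
                cov = fisher_covariance(res, records, weights=weights)
            row["converged"] = res.converged
            for k in range(1, spec.K + 1):
                est = res.estimate(f"beta_{k}")
                se = float(cov.se[res.names.index(f"beta_{k}")])
                _, p = wald_test(est, se)
                row[f"beta_{k}"] = est
                row[f"se_{k}"] = se
                row[f"p_{k}"] = p
        except Exception as exc:
            row["error"] = str(exc)
        results.append(row)
    out = pd.DataFrame(results)
    for k in range(1, spec.K + 1):
        if f"p_{k}" in out:
            p = out[f"p_{k}"].to_numpy(dtype=float)
            adj = np.minimum(1.0, p * len(out))
            out[f"p_adj_{k}"] = adj
            out[f"significant_{k}"] = adj < alpha_level
    return out
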