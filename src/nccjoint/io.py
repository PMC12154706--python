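"""Delimited-table readers and writers for study data.

Table dialect: comma-separated, header row required, UTF-8.  The
longitudinal table has columns ``subject_id, time, value`` plus any
longitudinal covariate columns; the survival table has
``subject_id, T, delta, R`` plus survival-covariate and matching columns.
Abundance tables have ``sample_id, subject_id, time`` plus one column per
taxon (empty cells mark missing measurements).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import AbundanceTable, JointModelSpec, SubjectRecord

__all__ = [
    "read_study",
    "write_study",
    "read_abundance",
    "write_abundance",
    "load_config",
]

_SURV_REQUIRED = ["subject_id", "T", "delta", "R"]
_LONG_REQUIRED = ["subject_id", "time", "value"]


def _require(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing required columns: {missing}")


def read_study(
    long_table_path,
    surv_table_path,
    spec: JointModelSpec,
    match_columns: Sequence[str] = (),
) -> list[SubjectRecord]:
    """Read longitudinal + survival CSVs into one SubjectRecord per subject.

    Longitudinal rows may exist only for subjects flagged ``R=1`` in the
    survival table; all record invariants are validated on read.
    """
    surv = pd.read_csv(surv_table_path)
    _require(surv, _SURV_REQUIRED + list(spec.survival_covariate_names) + list(match_columns), "survival")
    long = pd.read_csv(long_table_path)
    if len(long):
        _require(long, _LONG_REQUIRED + list(spec.longitudinal_covariate_names), "longitudinal")
    if surv["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in survival table")

    by_subject = dict(tuple(long.groupby("subject_id", sort=False))) if len(long) else {}
    unknown = set(by_subject) - set(surv["subject_id"])
    if unknown:
        raise ValueError(f"longitudinal rows for subjects absent from survival table: {sorted(unknown)[:5]}")

    records: list[SubjectRecord] = []
    for row in surv.itertuples(index=False):
        sid = row.subject_id
        delta = int(row.delta)
        if delta < 0 or delta > spec.K:
            raise ValueError(f"subject {sid}: unknown delta value {delta}")
        R = int(row.R)
        grp = by_subject.pop(sid, None)
        times = Y = None
        x_long = np.empty(0)
        if R == 1:
            if grp is None or not len(grp):
                raise ValueError(f"subject {sid}: R=1 but no longitudinal rows")
            grp = grp.sort_values("time")
            times = grp["time"].to_numpy(float)
            Y = grp["value"].to_numpy(float)
            if spec.longitudinal_covariate_names:
                x_long = grp[list(spec.longitudinal_covariate_names)].iloc[0].to_numpy(float)
                if grp[list(spec.longitudinal_covariate_names)].isna().any().any():
                    raise ValueError(f"subject {sid}: missing longitudinal covariates")
        elif grp is not None and len(grp):
            raise ValueError(f"subject {sid}: longitudinal rows present but R=0")
        records.append(
            SubjectRecord(
                subject_id=sid,
                T=float(row.T),
                delta=delta,
                X_long=x_long,
                X_surv=np.array([getattr(row, c) for c in spec.survival_covariate_names], float),
                match_vars=np.array([getattr(row, c) for c in match_columns]),
                R=R,
                times=times,
                Y=Y,
            )
        )
        records[-1].validate(K=spec.K)
    return records


def write_study(
    records: Sequence[SubjectRecord],
    long_table_path,
    surv_table_path,
    spec: JointModelSpec,
    match_columns: Sequence[str] = (),
    extra_surv_columns: dict | None = None,
) -> None:
    """Write records back to the two study CSVs (inverse of read_study)."""
    surv_rows = []
    long_rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "T": r.T, "delta": r.delta, "R": r.R}
        for j, c in enumerate(spec.survival_covariate_names):
            row[c] = r.X_surv[j]
        for j, c in enumerate(match_columns):
            row[c] = r.match_vars[j]
        surv_rows.append(row)
        if r.R == 1:
            for t, y in zip(r.times, r.Y):
                lrow = {"subject_id": r.subject_id, "time": t, "value": y}
                for j, c in enumerate(spec.longitudinal_covariate_names):
                    lrow[c] = r.X_long[j]
                long_rows.append(lrow)
    surv = pd.DataFrame(surv_rows)
    if extra_surv_columns:
        for name, values in extra_surv_columns.items():
            surv[name] = values
    surv.to_csv(surv_table_path, index=False)
    cols = _LONG_REQUIRED + list(spec.longitudinal_covariate_names)
    pd.DataFrame(long_rows, columns=cols).to_csv(long_table_path, index=False)


def read_abundance(path) -> AbundanceTable:
    """Read a sample-by-taxon relative-abundance CSV."""
    df = pd.read_csv(path)
    _require(df, ["sample_id", "subject_id", "time"], "abundance")
    df = df.set_index("sample_id")
    samples = df[["subject_id", "time"]]
    values = df.drop(columns=["subject_id", "time"]).astype(float)
    return AbundanceTable(values=values, samples=samples)


def write_abundance(table: AbundanceTable, path) -> None:
    out = pd.concat([table.samples, table.values], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path)


def load_config(path) -> dict:
    """Load a YAML key-value configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of keys to values")
    return cfg
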