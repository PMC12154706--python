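"""Microbiome abundance preprocessing: QC filters and variance-stabilizing
transform.

Samples are filtered before taxa: a sample is dropped when more than
``max_sample_missing_frac`` of its taxon entries are missing, or when every
non-missing entry is zero.  A taxon is then dropped when it is detected
(nonzero) in fewer than ``min_prevalence_frac`` of the *retained* samples or
its mean relative abundance over retained samples falls below
``min_mean_relabund``.  Zeros are valid abundances; only explicitly missing
entries (NaN) count toward missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import AbundanceTable

__all__ = ["filter_abundance", "arcsine_sqrt", "FilterReport"]


@dataclass
class FilterReport:
    removed_samples: list = field(default_factory=list)
    removed_taxa: list = field(default_factory=list)


def filter_abundance(
    table: AbundanceTable,
    max_sample_missing_frac: float = 0.10,
    min_prevalence_frac: float = 0.10,
    min_mean_relabund: float = 0.0001,
) -> tuple[AbundanceTable, FilterReport]:
    """Apply sample-level then taxon-level QC filters.

    Returns the filtered table and a report of removed sample/taxon ids.
    Raises ``ValueError`` if no samples survive.
    """
    if table.n_samples == 0 or table.n_taxa == 0:
        raise ValueError("abundance table is empty")
    v = table.values.to_numpy(dtype=float)

    missing_frac = np.isnan(v).mean(axis=1)
    with np.errstate(invalid="ignore"):
        all_zero = np.nansum(np.abs(v), axis=1) == 0
    keep_samples = (missing_frac <= max_sample_missing_frac) & ~all_zero
    if not keep_samples.any():
        raise ValueError("empty after filtering: all samples removed")
    removed_samples = list(table.values.index[~keep_samples])

    vk = v[keep_samples]
    with np.errstate(invalid="ignore"):
        prevalence = np.nanmean(vk > 0, axis=0)
        mean_ab = np.nanmean(vk, axis=0)
    keep_taxa = (prevalence >= min_prevalence_frac) & (mean_ab >= min_mean_relabund)
    removed_taxa = list(table.values.columns[~keep_taxa])

    out = AbundanceTable(
        values=table.values.loc[keep_samples, keep_taxa],
        samples=table.samples.loc[keep_samples],
    )
    return out, FilterReport(removed_samples, removed_taxa)


def arcsine_sqrt(x):
    """Arcsine square-root transform ``arcsin(sqrt(x))`` for x in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("arcsine_sqrt requires values in [0, 1]")
    return np.arcsin(np.sqrt(x))
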