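"""Spectral-count preprocessing: normalization, prevalence filtering,
F-ratio differential-expression selection and per-condition presence calls.

A protein is *identified* in a sample when its spectral count is positive;
every rule below builds on that detection convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .conditions import BASE_CONDITIONS, validate_metadata

__all__ = [
    "validate_counts",
    "normalize_spc",
    "prevalence_filter",
    "f_ratio_selection",
    "condition_presence",
]


def validate_counts(counts: pd.DataFrame) -> None:
    """Validate a proteins × samples spectral-count matrix."""
    if counts.index.has_duplicates:
        raise ValueError("duplicate protein ids")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids")
    if (counts.to_numpy() < 0).any():
        raise ValueError("spectral counts must be non-negative")


def normalize_spc(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each protein row to [0, 100], mapping its maximum count to 100.

    All-zero rows stay zero. The transform is per-protein affine, so it
    preserves within-protein rank order (rank-based statistics are invariant
    to it) and is idempotent.
    """
    values = counts.to_numpy(dtype=float)
    row_max = values.max(axis=1, keepdims=True)
    # divide before scaling so the row maximum maps to exactly 100.0
    ratio = np.divide(values, row_max, out=np.zeros_like(values), where=row_max > 0)
    return pd.DataFrame(ratio * 100.0, index=counts.index, columns=counts.columns)


def prevalence_filter(
    counts: pd.DataFrame,
    samples: list[str] | None = None,
    min_fraction: float = 0.51,
) -> list[str]:
    """Proteins identified in at least ``min_fraction`` of the given samples.

    The boundary is inclusive: 7 of 13 samples (53.8%) passes the default
    51% threshold, 7 of 14 (50.0%) does not.
    """
    if samples is None:
        samples = list(counts.columns)
    if len(samples) == 0:
        raise ValueError("prevalence_filter needs a non-empty sample set")
    missing = set(samples) - set(counts.columns)
    if missing:
        raise KeyError(f"samples not in matrix: {sorted(missing)}")
    sub = counts[samples]
    frac = (sub > 0).sum(axis=1) / len(samples)
    return list(counts.index[frac >= min_fraction])


def f_ratio_selection(
    normalized: pd.DataFrame,
    meta: pd.Series,
    alpha: float = 0.05,
    f_min: float = 3.0,
) -> pd.DataFrame:
    """One-way fixed-effects F ratio of each protein across base conditions.

    The differential-expression filter: between-group mean square over
    within-group mean square on (k−1, N−k) degrees of freedom, with a protein
    selected when ``p < alpha`` and ``F > f_min`` (both strict). This is the
    single-feature discriminant F ratio, i.e. the univariate reduction of a
    linear discriminant analysis over the four conditions.

    Degenerate proteins with zero within-group variance get ``F = inf`` and
    ``p = 0`` when group means differ (selected), and ``F = 0``, ``p = 1``
    when all values are equal (not selected).

    Returns a DataFrame indexed by protein with columns
    ``F_ratio``, ``p_value``, ``selected``.
    """
    validate_metadata(meta)
    missing = set(normalized.columns) - set(meta.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    conds = [c for c in BASE_CONDITIONS if (meta[list(normalized.columns)] == c).any()]
    groups = {
        c: normalized.loc[:, [s for s in normalized.columns if meta[s] == c]].to_numpy(
            dtype=float
        )
        for c in conds
    }
    sizes = {c: g.shape[1] for c, g in groups.items()}
    if len(conds) < 2 or any(n < 2 for n in sizes.values()):
        raise ValueError("need >=2 conditions with >=2 samples each")

    n_total = sum(sizes.values())
    k = len(conds)
    all_values = np.concatenate([groups[c] for c in conds], axis=1)
    grand = all_values.mean(axis=1)

    ssb = np.zeros(len(normalized))
    ssw = np.zeros(len(normalized))
    for c in conds:
        g = groups[c]
        gm = g.mean(axis=1)
        ssb += sizes[c] * (gm - grand) ** 2
        ssw += ((g - gm[:, None]) ** 2).sum(axis=1)

    df_b, df_w = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    # zero within-group variance: F=inf when means differ, F=0 when all equal
    degenerate = ssw == 0
    f[degenerate & (ssb > 0)] = np.inf
    f[degenerate & (ssb == 0)] = 0.0
    p = stats.f.sf(f, df_b, df_w)
    p[np.isinf(f)] = 0.0
    selected = (p < alpha) & (f > f_min)
    return pd.DataFrame(
        {"F_ratio": f, "p_value": p, "selected": selected}, index=normalized.index
    )


def condition_presence(
    counts: pd.DataFrame,
    meta: pd.Series,
    condition: str,
    min_samples: int = 1,
) -> set[str]:
    """Proteins identified (SpC > 0) in at least ``min_samples`` samples of
    one base condition."""
    validate_metadata(meta)
    if condition not in set(meta):
        raise ValueError(f"condition {condition!r} has no samples in metadata")
    samples = [s for s in counts.columns if s in meta.index and meta[s] == condition]
    hits = (counts[samples] > 0).sum(axis=1)
    return set(counts.index[hits >= min_samples])
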