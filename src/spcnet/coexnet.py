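"""Signed Spearman co-expression networks per condition grouping.

An edge joins two proteins whose abundance profiles over a grouping's pooled
samples have |Spearman rho| above a fixed threshold at a two-sided p-value
below a second threshold (both strict). Zero counts are treated as observed
zero abundances, not missing values, so every pair uses the grouping's full
sample count.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .conditions import GROUPING_ORDER, samples_for_grouping
from .preprocess import prevalence_filter

__all__ = [
    "CorrelationResult",
    "spearman_all_pairs",
    "build_coexpression_network",
    "build_grouping_networks",
]


@dataclass(frozen=True)
class CorrelationResult:
    """All-pairs Spearman correlations over one sample set.

    ``rho`` and ``p_value`` are symmetric proteins × proteins DataFrames;
    pairs involving a rank-degenerate protein (constant across the samples)
    are NaN and listed in ``degenerate``.
    """

    rho: pd.DataFrame
    p_value: pd.DataFrame
    n_used: int
    degenerate: frozenset[str]

    @property
    def proteins(self) -> list[str]:
        return list(self.rho.index)


def spearman_all_pairs(
    counts: pd.DataFrame, samples: list[str] | None = None
) -> CorrelationResult:
    """Spearman rho and two-sided p for every protein pair.

    rho is the Pearson correlation of average-ranked values; the p-value uses
    the t transform ``t = rho * sqrt((n-2)/(1-rho^2))`` on n−2 degrees of
    freedom, with p = 0 at rho = ±1. Requires at least 3 samples (the t
    approximation is poor below ~10; the study groupings have 12–15).
    """
    if samples is None:
        samples = list(counts.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for correlation")
    x = counts[samples].to_numpy(dtype=float)
    n = x.shape[1]

    ranks = stats.rankdata(x, axis=1)
    constant = ranks.std(axis=1) == 0

    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    safe = np.where(norm > 0, norm, 1.0)
    unit = centered / safe[:, None]
    rho = unit @ unit.T
    np.clip(rho, -1.0, 1.0, out=rho)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) == 1.0] = 0.0
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, np.where(constant, np.nan, 0.0))

    idx = counts.index
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p_value=pd.DataFrame(p, index=idx, columns=idx),
        n_used=n,
        degenerate=frozenset(counts.index[constant]),
    )


def build_coexpression_network(
    corr: CorrelationResult,
    rho_min: float = 0.7,
    p_max: float = 0.01,
    drop_isolated: bool = True,
) -> nx.Graph:
    """Threshold a correlation result into a signed co-expression network.

    An edge requires |rho| > ``rho_min`` AND p < ``p_max`` (both strict; a
    pair at exactly rho = 0.7 gets no edge). Edge attributes: ``rho``, ``p``
    and ``sign`` ("positive"/"negative"). By default only proteins with at
    least one passing edge become nodes; with ``drop_isolated=False`` every
    non-degenerate protein is a node.
    """
    rho = corr.rho.to_numpy()
    p = corr.p_value.to_numpy()
    proteins = corr.proteins
    with np.errstate(invalid="ignore"):
        passing = (np.abs(rho) > rho_min) & (p < p_max)
    passing &= np.triu(np.ones_like(passing, dtype=bool), k=1)

    g = nx.Graph()
    g.graph["n_samples"] = corr.n_used
    if not drop_isolated:
        g.add_nodes_from(p_ for p_ in proteins if p_ not in corr.degenerate)
    for i, j in zip(*np.nonzero(passing)):
        r = float(rho[i, j])
        g.add_edge(
            proteins[i],
            proteins[j],
            rho=r,
            p=float(p[i, j]),
            sign="positive" if r > 0 else "negative",
        )
    return g


def build_grouping_networks(
    counts: pd.DataFrame,
    meta: pd.Series,
    rho_min: float = 0.7,
    p_max: float = 0.01,
    prevalence: float = 0.51,
    groupings: tuple[str, ...] = GROUPING_ORDER,
    drop_isolated: bool = True,
) -> dict[str, nx.Graph]:
    """One signed co-expression network per condition grouping.

    For each grouping the matrix is restricted to the grouping's pooled
    samples, prevalence-filtered on those same samples, and thresholded.
    """
    networks = {}
    for grouping in groupings:
        samples = samples_for_grouping(meta, grouping)
        kept = prevalence_filter(counts, samples, min_fraction=prevalence)
        corr = spearman_all_pairs(counts.loc[kept], samples)
        net = build_coexpression_network(corr, rho_min, p_max, drop_isolated)
        net.graph["grouping"] = grouping
        networks[grouping] = net
    return networks
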