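"""Topological analysis: centralities, hub calling, condition-specific hub
algebra, differential-correlation detection, ego networks and PPI overlap.

Hubs follow the above-average rule: a node is a hub when its centrality
strictly exceeds the mean of that centrality over the whole network. PPI
networks are scored on betweenness and centroid centrality; co-expression
networks on degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .conditions import FACTOR_LEVELS, GROUPING_ORDER

__all__ = [
    "betweenness",
    "centroid",
    "CentralityTable",
    "centrality_table",
    "call_hubs",
    "condition_specific_hubs",
    "differential_correlation",
    "ego_network",
    "edge_overlap",
    "EdgeOverlap",
]


def betweenness(net: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness (Brandes accumulation).

    Each unordered node pair is counted once and path endpoints are excluded,
    so a leaf scores 0 and the middle of a 3-path scores 1. Disconnected
    graphs are handled per component (unreachable pairs contribute nothing).
    """
    return nx.betweenness_centrality(net, normalized=False, weight=None)


def centroid(net: nx.Graph) -> dict[str, int]:
    """Centroid centrality: C(v) = min over reachable w of γ_v(w) − γ_w(v).

    γ_v(w) counts the nodes strictly closer to v than to w (equidistant nodes
    count for neither side, and a node is closer to itself than to anything
    else). Positive values mark nodes near the topological center of their
    component; computed per connected component, with isolated nodes at 0.
    """
    result: dict[str, int] = {}
    for comp in nx.connected_components(net):
        nodes = sorted(comp)
        n = len(nodes)
        if n == 1:
            result[nodes[0]] = 0
            continue
        sub = net.subgraph(nodes)
        index = {v: i for i, v in enumerate(nodes)}
        dist = np.full((n, n), np.inf)
        for v, lengths in nx.all_pairs_shortest_path_length(sub):
            for w, d in lengths.items():
                dist[index[v], index[w]] = d
        # gamma[v, w] = #{u : d(u, v) < d(u, w)}
        gamma = np.zeros((n, n), dtype=np.int64)
        for u in range(n):
            du = dist[u]
            gamma += du[:, None] < du[None, :]
        f = gamma - gamma.T
        np.fill_diagonal(f, np.iinfo(np.int64).max)
        values = f.min(axis=1)
        for v, c in zip(nodes, values):
            result[v] = int(c)
    return result


@dataclass(frozen=True)
class CentralityTable:
    """Per-node centralities of one network plus the network-wide means."""

    table: pd.DataFrame  # columns: degree, betweenness, centroid
    mean_degree: float
    mean_betweenness: float
    mean_centroid: float

    def __post_init__(self) -> None:
        degrees = self.table["degree"]
        assert degrees.sum() % 2 == 0, "degree sum must be even"


def centrality_table(net: nx.Graph) -> CentralityTable:
    """Degree, betweenness and centroid centrality for every node."""
    nodes = list(net.nodes)
    deg = dict(net.degree())
    btw = betweenness(net)
    cen = centroid(net)
    table = pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "centroid": [cen[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    if len(nodes) == 0:
        return CentralityTable(table, 0.0, 0.0, 0.0)
    return CentralityTable(
        table,
        mean_degree=float(table["degree"].mean()),
        mean_betweenness=float(table["betweenness"].mean()),
        mean_centroid=float(table["centroid"].mean()),
    )


def call_hubs(
    ct: CentralityTable, mode: str = "ppi", combine: str = "and"
) -> set[str]:
    """Nodes whose centralities strictly exceed the network means.

    ``mode="ppi"`` uses betweenness and centroid, combined with AND by
    default (``combine="or"`` for the permissive variant); a k-regular
    network therefore has no hubs. ``mode="coexpression"`` uses degree only.
    """
    t = ct.table
    if len(t) == 0:
        return set()
    if mode == "coexpression":
        mask = t["degree"] > ct.mean_degree
    elif mode == "ppi":
        above_b = t["betweenness"] > ct.mean_betweenness
        above_c = t["centroid"] > ct.mean_centroid
        if combine == "and":
            mask = above_b & above_c
        elif combine == "or":
            mask = above_b | above_c
        else:
            raise ValueError("combine must be 'and' or 'or'")
    else:
        raise ValueError("mode must be 'ppi' or 'coexpression'")
    return set(t.index[mask])


def condition_specific_hubs(
    hub_sets: Mapping[str, set[str]],
    factor: str,
    rule: str = "both",
) -> dict[str, set[str]]:
    """Hubs specific to one level of a nutritional factor.

    ``hub_sets`` maps each base-condition network to its hub set. For factor
    level L (e.g. "+Fe"), a protein is L-specific when it is a hub in both
    networks of level L (``rule="both"``; ``rule="any"`` requires only one)
    and a hub in neither network of the opposite level.
    """
    if factor not in FACTOR_LEVELS:
        raise ValueError(f"factor must be one of {sorted(FACTOR_LEVELS)}")
    if rule not in ("both", "any"):
        raise ValueError("rule must be 'both' or 'any'")
    levels = FACTOR_LEVELS[factor]
    needed = {c for conds in levels.values() for c in conds}
    missing = needed - set(hub_sets)
    if missing:
        raise ValueError(f"missing hub sets for networks: {sorted(missing)}")

    out: dict[str, set[str]] = {}
    level_names = list(levels)
    for level in level_names:
        own = [hub_sets[c] for c in sorted(levels[level])]
        opposite_level = next(l for l in level_names if l != level)
        opposite = [hub_sets[c] for c in sorted(levels[opposite_level])]
        in_own = set.intersection(*own) if rule == "both" else set.union(*own)
        out[level] = in_own - set.union(*opposite)
    return out


def differential_correlation(
    degree_by_grouping: pd.DataFrame,
    mean_degree_by_grouping: Mapping[str, float],
) -> pd.DataFrame:
    """Differentially correlated proteins from per-grouping degrees.

    ``degree_by_grouping`` holds each protein's degree in the four grouping
    co-expression networks (0 where absent). A protein is called with focal
    grouping g when its degree there strictly exceeds that network's mean
    degree AND is the strict maximum over the four groupings — so a protein
    has at most one focal grouping, and ties are never called.

    Returns a DataFrame with the degree columns plus ``called`` (bool) and
    ``focal_grouping`` (grouping name or None).
    """
    groupings = [g for g in GROUPING_ORDER if g in degree_by_grouping.columns]
    missing = set(groupings) ^ set(degree_by_grouping.columns)
    if missing:
        raise ValueError(f"unexpected/missing grouping columns: {sorted(missing)}")
    deg = degree_by_grouping[groupings].to_numpy(dtype=float)
    means = np.array([mean_degree_by_grouping[g] for g in groupings])

    order = np.sort(deg, axis=1)
    strict_max = order[:, -1] > order[:, -2] if deg.shape[1] > 1 else np.ones(len(deg), bool)
    argmax = deg.argmax(axis=1)
    above_mean = deg[np.arange(len(deg)), argmax] > means[argmax]
    called = strict_max & above_mean

    focal = [groupings[j] if ok else None for j, ok in zip(argmax, called)]
    out = degree_by_grouping[groupings].copy()
    out["called"] = called
    out["focal_grouping"] = focal
    return out


def ego_network(net: nx.Graph, hub: str) -> nx.Graph:
    """The hub, its first neighbors, and all edges among them (attributes
    retained). A hub absent from the network yields an empty graph."""
    if hub not in net:
        return nx.Graph()
    return nx.ego_graph(net, hub, radius=1).copy()


@dataclass(frozen=True)
class EdgeOverlap:
    """Overlap between a co-expression network and a PPI network.

    ``pair_pct`` (the headline number): % of co-expression edges also present
    as PPI edges. ``protein_pct``: % of co-expression nodes incident to at
    least one shared edge. Both are None when the co-expression network has
    no edges.
    """

    shared_edges: int
    coex_edges: int
    pair_pct: float | None
    protein_pct: float | None


def edge_overlap(coex: nx.Graph, ppi: nx.Graph) -> EdgeOverlap:
    """Pair-level and protein-level overlap of co-expression with PPI."""
    coex_edges = {frozenset(e) for e in coex.edges}
    if not coex_edges:
        return EdgeOverlap(0, 0, None, None)
    ppi_edges = {frozenset(e) for e in ppi.edges}
    shared = coex_edges & ppi_edges
    touched = {v for e in shared for v in e}
    n_nodes = coex.number_of_nodes()
    return EdgeOverlap(
        shared_edges=len(shared),
        coex_edges=len(coex_edges),
        pair_pct=100.0 * len(shared) / len(coex_edges),
        protein_pct=100.0 * len(touched) / n_nodes if n_nodes else None,
    )
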