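"""Homology-transferred protein–protein interaction networks.

Interactions catalogued between reference-species genes (with per-channel
evidence scores in the style of STRING's "database" and "experimental"
channels) are filtered on those scores and transferred to the study species
through an ortholog map: every protein pair whose genes interact inherits an
edge (the interolog convention). Condition-specific subnetworks are induced
subgraphs on the proteins identified in each condition.
"""

from __future__ import annotations

import warnings
from typing import Collection, Iterable

import networkx as nx
import pandas as pd

__all__ = [
    "validate_interactions",
    "validate_ortholog_map",
    "filter_interactions",
    "transfer_interactions",
    "extract_condition_subnetwork",
    "drop_isolated_nodes",
    "mean_homology",
]


def validate_ortholog_map(ortholog_map: pd.DataFrame) -> None:
    """Check protein→gene map: required columns, one gene per protein,
    homology in (0, 100]."""
    required = {"protein", "gene", "homology_pct"}
    missing = required - set(ortholog_map.columns)
    if missing:
        raise ValueError(f"ortholog map missing columns: {sorted(missing)}")
    if ortholog_map["protein"].duplicated().any():
        dups = ortholog_map.loc[ortholog_map["protein"].duplicated(), "protein"]
        raise ValueError(f"proteins mapped to several genes: {sorted(set(dups))}")
    hom = ortholog_map["homology_pct"]
    if ((hom <= 0) | (hom > 100)).any():
        raise ValueError("homology_pct must be in (0, 100]")


def validate_interactions(table: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize an interaction table.

    Orders each pair lexicographically, rejects self-interactions, and merges
    duplicate pairs by taking the per-channel maximum score.
    """
    required = {"gene_a", "gene_b", "database_score", "experimental_score"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    if (table["gene_a"] == table["gene_b"]).any():
        raise ValueError("self-interactions are not allowed")
    t = table.copy()
    swap = t["gene_a"] > t["gene_b"]
    t.loc[swap, ["gene_a", "gene_b"]] = t.loc[swap, ["gene_b", "gene_a"]].to_numpy()
    return (
        t.groupby(["gene_a", "gene_b"], as_index=False)[
            ["database_score", "experimental_score"]
        ].max()
    )


def filter_interactions(
    table: pd.DataFrame, db_min: float = 0.15, exp_min: float = 0.35
) -> pd.DataFrame:
    """Keep interactions with database score > ``db_min`` OR experimental
    score > ``exp_min`` (strict: a row at exactly the thresholds is dropped).
    """
    for name, v in (("db_min", db_min), ("exp_min", exp_min)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    t = validate_interactions(table)
    keep = (t["database_score"] > db_min) | (t["experimental_score"] > exp_min)
    return t[keep].reset_index(drop=True)


def transfer_interactions(
    table: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    proteome: Collection[str] | None = None,
) -> nx.Graph:
    """Transfer gene–gene interactions to protein–protein edges.

    Every mapped protein becomes a node. For each interacting gene pair
    (G1, G2), all protein pairs (p1→G1, p2→G2) receive an edge carrying the
    channel scores and the source gene pair as an audit trail. Two proteins
    mapping to the same gene never receive an edge (the table cannot contain
    self-pairs). When a ``proteome`` is given, mapped proteins outside it are
    kept with a warning.
    """
    validate_ortholog_map(ortholog_map)
    table = validate_interactions(table)

    if proteome is not None:
        extra = set(ortholog_map["protein"]) - set(proteome)
        if extra:
            warnings.warn(
                f"{len(extra)} mapped proteins absent from the proteome; keeping them",
                stacklevel=2,
            )

    by_gene: dict[str, list[str]] = {}
    for protein, gene in zip(ortholog_map["protein"], ortholog_map["gene"]):
        by_gene.setdefault(gene, []).append(protein)

    g = nx.Graph()
    g.add_nodes_from(ortholog_map["protein"])
    for row in table.itertuples(index=False):
        for p1 in by_gene.get(row.gene_a, ()):
            for p2 in by_gene.get(row.gene_b, ()):
                if p1 == p2:
                    continue
                g.add_edge(
                    p1,
                    p2,
                    database_score=float(row.database_score),
                    experimental_score=float(row.experimental_score),
                    source_genes=f"{row.gene_a}|{row.gene_b}",
                )
    return g


def extract_condition_subnetwork(
    net: nx.Graph,
    present: Iterable[str],
    drop_isolated: bool = False,
    largest_component: bool = False,
) -> nx.Graph:
    """Induced subgraph on the proteins identified in one condition.

    ``drop_isolated`` removes nodes left without edges; ``largest_component``
    further restricts to the largest connected component.
    """
    sub = net.subgraph(set(present) & set(net.nodes)).copy()
    if drop_isolated:
        sub.remove_nodes_from(list(nx.isolates(sub)))
    if largest_component and sub.number_of_nodes():
        biggest = max(nx.connected_components(sub), key=len)
        sub = sub.subgraph(biggest).copy()
    return sub


def drop_isolated_nodes(net: nx.Graph) -> nx.Graph:
    """Copy of the network without degree-0 nodes."""
    out = net.copy()
    out.remove_nodes_from(list(nx.isolates(out)))
    return out


def mean_homology(
    ortholog_map: pd.DataFrame, proteins: Iterable[str] | None = None
) -> float:
    """Arithmetic mean homology % over the given proteins (all if None)."""
    validate_ortholog_map(ortholog_map)
    if proteins is None:
        sub = ortholog_map
    else:
        wanted = set(proteins)
        sub = ortholog_map[ortholog_map["protein"].isin(wanted)]
    if len(sub) == 0:
        raise ValueError("no mapped proteins to average over")
    return float(sub["homology_pct"].mean())
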