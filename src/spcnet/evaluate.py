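"""Evaluation of planted-structure recovery on synthetic datasets.

Convenience layer tying the generator's ground truth to the pipeline's
outputs: per-grouping degree tables, differential-correlation calls and
precision/recall of planted-hub and differential-expression recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import pandas as pd

from .conditions import GROUPING_ORDER
from .synth import GroundTruth
from .topo import differential_correlation

__all__ = [
    "degree_table",
    "mean_degrees",
    "diffcorr_calls",
    "PrecisionRecall",
    "hub_recovery",
    "de_recovery",
    "module_edge_recall",
]


def degree_table(networks: Mapping[str, nx.Graph]) -> pd.DataFrame:
    """Per-protein degree in each grouping network (0 where absent)."""
    proteins = sorted(set().union(*(set(n.nodes) for n in networks.values())))
    return pd.DataFrame(
        {
            g: [networks[g].degree(p) if p in networks[g] else 0 for p in proteins]
            for g in GROUPING_ORDER
            if g in networks
        },
        index=pd.Index(proteins, name="protein"),
    )


def mean_degrees(networks: Mapping[str, nx.Graph]) -> dict[str, float]:
    return {
        g: (2 * n.number_of_edges() / n.number_of_nodes()) if n.number_of_nodes() else 0.0
        for g, n in networks.items()
    }


def diffcorr_calls(networks: Mapping[str, nx.Graph]) -> pd.DataFrame:
    """Differential-correlation calls straight from grouping networks."""
    return differential_correlation(degree_table(networks), mean_degrees(networks))


@dataclass(frozen=True)
class PrecisionRecall:
    true_positives: int
    called: int
    planted: int

    @property
    def precision(self) -> float:
        return self.true_positives / self.called if self.called else 1.0

    @property
    def recall(self) -> float:
        return self.true_positives / self.planted if self.planted else 1.0


def hub_recovery(
    calls: pd.DataFrame, truth: GroundTruth
) -> PrecisionRecall:
    """Precision/recall of (protein, focal grouping) calls against the
    planted hub sets."""
    called = {
        (p, row["focal_grouping"])
        for p, row in calls[calls["called"]].iterrows()
    }
    planted = {(p, g) for g, ps in truth.planted_hubs.items() for p in ps}
    return PrecisionRecall(len(called & planted), len(called), len(planted))


def de_recovery(de_result: pd.DataFrame, truth: GroundTruth) -> tuple[float, float]:
    """(sensitivity on planted DE proteins, false-positive rate on proteins
    with no planted mean shift). Module proteins are excluded from the FPR
    denominator: their abundance is genuinely structured."""
    selected = set(de_result.index[de_result["selected"]])
    de = truth.de_proteins
    sens = len(selected & de) / len(de) if de else 1.0
    unshifted = set(de_result.index) - de - set(truth.module_assignment)
    fpr = len(selected & unshifted) / len(unshifted) if unshifted else 0.0
    return sens, fpr


def module_edge_recall(
    networks: Mapping[str, nx.Graph], truth: GroundTruth
) -> float:
    """Fraction of within-module pairs recovered as edges in the module's
    active grouping network."""
    hits = total = 0
    members_by_module: dict[int, list[str]] = {}
    for p, k in truth.module_assignment.items():
        members_by_module.setdefault(k, []).append(p)
    for k, members in members_by_module.items():
        net = networks[truth.module_grouping[k]]
        members = sorted(members)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                total += 1
                hits += net.has_edge(a, b)
    return hits / total if total else 1.0
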