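import networkx as nx
import numpy as np
import pandas as pd
import pytest

import spcnet
from spcnet.conditions import GROUPING_ORDER


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset, shared across tests."""
    return spcnet.generate_spc_dataset(spcnet.default_config(seed=11))


@pytest.fixture(scope="session")
def grouping_networks(default_dataset):
    counts, meta, _ = default_dataset
    return spcnet.build_grouping_networks(counts, meta)


@pytest.fixture()
def tiny_counts():
    """4 proteins × 6 samples with hand-checkable values."""
    return pd.DataFrame(
        [
            [2, 5, 10, 1, 0, 4],
            [0, 0, 0, 0, 0, 0],
            [7, 7, 7, 7, 7, 7],
            [1, 2, 3, 4, 5, 6],
        ],
        index=pd.Index(["a", "b", "c", "d"], name="protein"),
        columns=pd.Index([f"s{i}" for i in range(6)], name="sample"),
    )


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Oracle: enumerate all shortest paths per pair, count interior visits."""
    result = {v: 0.0 for v in g}
    nodes = sorted(g)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            for path in paths:
                for v in path[1:-1]:
                    result[v] += 1.0 / len(paths)
    return result


def brute_force_centroid(g: nx.Graph) -> dict:
    """Oracle: direct gamma computation from BFS distances, triple loop."""
    result = {}
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) == 1:
            result[comp[0]] = 0
            continue
        dist = {v: nx.single_source_shortest_path_length(g, v) for v in comp}
        for v in comp:
            best = None
            for w in comp:
                if w == v:
                    continue
                gamma_vw = sum(1 for u in comp if dist[u][v] < dist[u][w])
                gamma_wv = sum(1 for u in comp if dist[u][w] < dist[u][v])
                f = gamma_vw - gamma_wv
                best = f if best is None else min(best, f)
            result[v] = best
    return result


def random_graph(rng: np.random.Generator, max_nodes: int = 8) -> nx.Graph:
    n = int(rng.integers(2, max_nodes + 1))
    p = rng.uniform(0.3, 0.7)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g
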