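"""Readers and writers for the pipeline's plain-text formats.

Everything is TSV with ``#``-comment headers, except networks, which are
written both as SIF (for Cytoscape) and GraphML (attribute-preserving), and
reports, which are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import pandas as pd


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a proteins × samples count matrix TSV (first column = protein)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "protein"
    df.columns.name = "sample"
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_samples(path: str | Path) -> pd.Series:
    """Read sample metadata TSV (columns: sample, base_condition)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"sample", "base_condition"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'sample' and 'base_condition'")
    return pd.Series(
        df["base_condition"].to_numpy(),
        index=pd.Index(df["sample"], name="sample"),
        name="base_condition",
    )


def write_samples(meta: pd.Series, path: str | Path) -> None:
    meta.rename("base_condition").rename_axis("sample").to_frame().to_csv(
        path, sep="\t"
    )


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"protein", "gene", "homology_pct"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_ortholog_map(ortholog_map: pd.DataFrame, path: str | Path) -> None:
    ortholog_map.to_csv(path, sep="\t", index=False)


def read_interactions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"gene_a", "gene_b", "database_score", "experimental_score"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_interactions(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Edge-attribute TSV: one row per edge with all edge attributes."""
    rows = []
    for a, b, data in sorted(net.edges(data=True)):
        row = {"protein_a": a, "protein_b": b}
        row.update(data)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_sif(net: nx.Graph, path: str | Path, relation: str = "interacts") -> None:
    """SIF export; isolated nodes are written as single-column rows."""
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for v in sorted(nx.isolates(net)):
            fh.write(f"{v}\n")


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def write_json(obj: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
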