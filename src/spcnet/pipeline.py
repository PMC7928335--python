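"""End-to-end orchestration: simulate → preprocess → PPI → co-expression →
topology → report, with every artifact written to plain-text files and a
manifest recording input hashes and configuration."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import pandas as pd
import yaml

from . import __version__, coexnet, io, ppinet, preprocess, synth, topo
from .conditions import BASE_CONDITIONS, GROUPING_ORDER, validate_metadata

log = logging.getLogger("spcnet")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "report_tables"]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, thresholds and switches of the full pipeline.

    With ``simulate=True`` the input paths are ignored and a synthetic
    dataset (under the default study conditions, seeded by ``seed``) is
    generated and written alongside the outputs.
    """

    outdir: str = "spcnet_out"
    counts_path: str | None = None
    samples_path: str | None = None
    orthologs_path: str | None = None
    interactions_path: str | None = None
    simulate: bool = False

    db_min: float = 0.15
    exp_min: float = 0.35
    rho_min: float = 0.7
    p_max: float = 0.01
    prevalence: float = 0.51
    alpha: float = 0.05
    f_min: float = 3.0
    hub_combine: str = "and"
    presence_min_samples: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name, v, lo, hi in (
            ("db_min", self.db_min, 0, 1),
            ("exp_min", self.exp_min, 0, 1),
            ("rho_min", self.rho_min, 0, 1),
            ("p_max", self.p_max, 0, 1),
            ("prevalence", self.prevalence, 0, 1),
            ("alpha", self.alpha, 0, 1),
        ):
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.f_min < 0:
            raise ValueError("f_min must be >= 0")
        if self.hub_combine not in ("and", "or"):
            raise ValueError("hub_combine must be 'and' or 'or'")
        if not self.simulate:
            missing = [
                n
                for n, p in (
                    ("counts_path", self.counts_path),
                    ("samples_path", self.samples_path),
                    ("orthologs_path", self.orthologs_path),
                    ("interactions_path", self.interactions_path),
                )
                if p is None
            ]
            if missing:
                raise ValueError(
                    f"missing input paths (or set simulate=True): {missing}"
                )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    config: PipelineConfig
    counts: pd.DataFrame
    meta: pd.Series
    ortholog_map: pd.DataFrame
    interactions: pd.DataFrame
    truth: synth.GroundTruth | None
    de_result: pd.DataFrame
    ppi_full: nx.Graph
    ppi_condition: dict[str, nx.Graph]
    ppi_hubs: dict[str, set[str]]
    ppi_specific_hubs: dict[str, dict[str, set[str]]]
    coex_networks: dict[str, nx.Graph]
    coex_hubs: dict[str, set[str]]
    degree_by_grouping: pd.DataFrame
    mean_degree_by_grouping: dict[str, float]
    diffcorr: pd.DataFrame
    overlap: dict[str, topo.EdgeOverlap]
    manifest: dict[str, Any]


def _network_summary(name: str, net: nx.Graph, hubs: set[str]) -> dict[str, Any]:
    n, e = net.number_of_nodes(), net.number_of_edges()
    return {
        "network": name,
        "nodes": n,
        "edges": e,
        "mean_degree": (2 * e / n) if n else 0.0,
        "hub_count": len(hubs),
    }


def report_tables(result: PipelineResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein table (ortholog, homology, F, p, per-grouping degree,
    differential call) and per-network summary table."""
    orth = result.ortholog_map.set_index("protein")
    rows = []
    for protein in result.counts.index:
        row: dict[str, Any] = {"protein": protein}
        if protein in orth.index:
            row["gene"] = orth.loc[protein, "gene"]
            row["homology_pct"] = float(orth.loc[protein, "homology_pct"])
        else:
            row["gene"], row["homology_pct"] = None, None
        if protein in result.de_result.index:
            de = result.de_result.loc[protein]
            row["F_ratio"] = float(de["F_ratio"])
            row["p_value"] = float(de["p_value"])
            row["de_selected"] = bool(de["selected"])
        for g in GROUPING_ORDER:
            row[f"degree_{g}"] = int(
                result.degree_by_grouping.loc[protein, g]
                if protein in result.degree_by_grouping.index
                else 0
            )
        if protein in result.diffcorr.index:
            row["diffcorr_called"] = bool(result.diffcorr.loc[protein, "called"])
            row["focal_grouping"] = result.diffcorr.loc[protein, "focal_grouping"]
        rows.append(row)
    per_protein = pd.DataFrame(rows).set_index("protein")

    summaries = [
        _network_summary("ppi_full", result.ppi_full, set())
    ]
    for cond in BASE_CONDITIONS:
        summaries.append(
            _network_summary(
                f"ppi_{cond}", result.ppi_condition[cond], result.ppi_hubs[cond]
            )
        )
    for g in GROUPING_ORDER:
        summaries.append(
            _network_summary(
                f"coex_{g}", result.coex_networks[g], result.coex_hubs[g]
            )
        )
    return per_protein, pd.DataFrame(summaries)


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.simulate:
        sim = synth.default_config(seed=cfg.seed)
        counts, meta, truth = synth.generate_spc_dataset(sim)
        ortholog_map = synth.generate_ortholog_map(list(counts.index), seed=cfg.seed)
        interactions = synth.generate_interaction_table(
            truth, seed=cfg.seed, ortholog_map=ortholog_map
        )
        inputs = outdir / "inputs"
        inputs.mkdir(parents=True, exist_ok=True)
        io.write_counts(counts, inputs / "counts.tsv")
        io.write_samples(meta, inputs / "samples.tsv")
        io.write_ortholog_map(ortholog_map, inputs / "orthologs.tsv")
        io.write_interactions(interactions, inputs / "interactions.tsv")
        return counts, meta, ortholog_map, interactions, truth
    counts = io.read_counts(cfg.counts_path)
    meta = io.read_samples(cfg.samples_path)
    ortholog_map = io.read_ortholog_map(cfg.orthologs_path)
    interactions = io.read_interactions(cfg.interactions_path)
    return counts, meta, ortholog_map, interactions, None


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage and write all artifacts under ``cfg.outdir``."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts, meta, ortholog_map, interactions, truth = _load_inputs(cfg, outdir)
    preprocess.validate_counts(counts)
    validate_metadata(meta)
    missing = set(counts.columns) - set(meta.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")

    # --- preprocessing ---------------------------------------------------
    normalized = preprocess.normalize_spc(counts)
    io.write_counts(normalized.round(4), outdir / "normalized.tsv")
    de_result = preprocess.f_ratio_selection(normalized, meta, cfg.alpha, cfg.f_min)
    de_result.to_csv(outdir / "de_table.tsv", sep="\t")
    presence = {
        cond: preprocess.condition_presence(
            counts, meta, cond, cfg.presence_min_samples
        )
        for cond in BASE_CONDITIONS
    }

    # --- PPI branch -------------------------------------------------------
    filtered = ppinet.filter_interactions(interactions, cfg.db_min, cfg.exp_min)
    ppi_full = ppinet.transfer_interactions(
        filtered, ortholog_map, proteome=list(counts.index)
    )
    ppi_trimmed = ppinet.drop_isolated_nodes(ppi_full)
    log.info(
        "PPI network: %d nodes, %d edges (%d mapped proteins)",
        ppi_trimmed.number_of_nodes(),
        ppi_trimmed.number_of_edges(),
        ppi_full.number_of_nodes(),
    )

    ppi_condition, ppi_hubs = {}, {}
    for cond in BASE_CONDITIONS:
        sub = ppinet.extract_condition_subnetwork(
            ppi_full, presence[cond], drop_isolated=True
        )
        ct = topo.centrality_table(sub)
        hubs = topo.call_hubs(ct, mode="ppi", combine=cfg.hub_combine)
        ppi_condition[cond], ppi_hubs[cond] = sub, hubs
        ct.table.assign(is_hub=ct.table.index.isin(hubs)).to_csv(
            outdir / f"ppi_centrality_{_safe(cond)}.tsv", sep="\t"
        )
        io.write_sif(sub, outdir / f"ppi_{_safe(cond)}.sif")
        io.write_graphml(sub, outdir / f"ppi_{_safe(cond)}.graphml")
        log.info(
            "PPI %s: %d nodes, %d edges, %d hubs",
            cond, sub.number_of_nodes(), sub.number_of_edges(), len(hubs),
        )
    ppi_specific = {
        factor: topo.condition_specific_hubs(ppi_hubs, factor)
        for factor in ("Fe", "Mo")
    }

    # --- co-expression branch --------------------------------------------
    coex_networks = coexnet.build_grouping_networks(
        counts, meta, cfg.rho_min, cfg.p_max, cfg.prevalence
    )
    coex_hubs: dict[str, set[str]] = {}
    mean_degree: dict[str, float] = {}
    all_proteins: set[str] = set()
    for g, net in coex_networks.items():
        ct = topo.centrality_table(net)
        coex_hubs[g] = topo.call_hubs(ct, mode="coexpression")
        mean_degree[g] = ct.mean_degree
        all_proteins |= set(net.nodes)
        io.write_edge_list(net, outdir / f"coex_{g}_edges.tsv")
        io.write_sif(net, outdir / f"coex_{g}.sif")
        io.write_graphml(net, outdir / f"coex_{g}.graphml")
        log.info(
            "co-expression %s: %d nodes, %d edges, %d hubs",
            g, net.number_of_nodes(), net.number_of_edges(), len(coex_hubs[g]),
        )

    degree_by_grouping = pd.DataFrame(
        {
            g: [coex_networks[g].degree(p) if p in coex_networks[g] else 0
                for p in sorted(all_proteins)]
            for g in GROUPING_ORDER
        },
        index=pd.Index(sorted(all_proteins), name="protein"),
    )
    diffcorr = topo.differential_correlation(degree_by_grouping, mean_degree)

    egodir = outdir / "egos"
    egodir.mkdir(exist_ok=True)
    for protein, row in diffcorr[diffcorr["called"]].iterrows():
        ego = topo.ego_network(coex_networks[row["focal_grouping"]], protein)
        io.write_graphml(ego, egodir / f"{protein}_{row['focal_grouping']}.graphml")

    overlap = {g: topo.edge_overlap(coex_networks[g], ppi_full) for g in GROUPING_ORDER}

    # --- report -----------------------------------------------------------
    hub_report = {
        "ppi_hubs": {c: sorted(h) for c, h in ppi_hubs.items()},
        "ppi_condition_specific": {
            f: {lvl: sorted(h) for lvl, h in levels.items()}
            for f, levels in ppi_specific.items()
        },
        "coexpression_hubs": {g: sorted(h) for g, h in coex_hubs.items()},
        "differentially_correlated": {
            p: row["focal_grouping"]
            for p, row in diffcorr[diffcorr["called"]].iterrows()
        },
        "overlap_pct": {
            g: {"pair_pct": ov.pair_pct, "protein_pct": ov.protein_pct}
            for g, ov in overlap.items()
        },
    }
    io.write_json(hub_report, outdir / "hub_report.json")

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "inputs": {
            name: io.sha256_file(outdir / "inputs" / f"{name}.tsv")
            if cfg.simulate
            else io.sha256_file(getattr(cfg, f"{name}_path"))
            for name in ("counts", "samples", "orthologs", "interactions")
        },
    }
    io.write_json(manifest, outdir / "manifest.json")

    result = PipelineResult(
        config=cfg, counts=counts, meta=meta, ortholog_map=ortholog_map,
        interactions=interactions, truth=truth, de_result=de_result,
        ppi_full=ppi_full, ppi_condition=ppi_condition, ppi_hubs=ppi_hubs,
        ppi_specific_hubs=ppi_specific, coex_networks=coex_networks,
        coex_hubs=coex_hubs, degree_by_grouping=degree_by_grouping,
        mean_degree_by_grouping=mean_degree, diffcorr=diffcorr,
        overlap=overlap, manifest=manifest,
    )
    per_protein, summary = report_tables(result)
    per_protein.to_csv(outdir / "report_proteins.tsv", sep="\t")
    summary.to_csv(outdir / "report_networks.tsv", sep="\t", index=False)
    return result


def _safe(name: str) -> str:
    return name.replace("+", "p").replace("-", "m")
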