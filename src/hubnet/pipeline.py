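"""Pipeline driver chaining every analysis stage.

Stages run in order: seed-gene assembly, graph construction, topological
prioritization, leave-k-out validation, regulatory-network ranking, and
comparative-Ct expression analysis.  Inputs may be file paths or, when
absent, are produced by the seeded synthetic generators.  Each stage
writes its outputs under the configured directory, and the run ends
with a JSON summary validated against the shipped pydantic schema.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import expression, genelist, graph, io, prioritize, regnet, simulate, validate

logger = logging.getLogger("hubnet")

__all__ = ["PipelineConfig", "PipelineSummary", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class PipelineConfig(BaseModel):
    """All thresholds default to the published study values."""

    edges_path: Optional[str] = None
    gene_list_path: Optional[str] = None
    tf_table_path: Optional[str] = None
    ct_path: Optional[str] = None
    min_confidence: float = Field(0.7, ge=0.0, le=1.0)
    degree_cut: int = Field(50, ge=0)
    bc_cut: float = Field(0.05, ge=0.0, le=1.0)
    pool_size: int = Field(22, ge=5)
    repeats: int = Field(5, ge=1)
    levels: list[int] = [1, 2, 3, 4]
    min_sites: int = Field(2, ge=0)
    z_min: float = 1.0
    seed: int = 0
    out_dir: str = "results"


class GroupComparisonRow(BaseModel):
    gene: str
    mean_case: float
    sem_case: float
    mean_ctrl: float
    sem_ctrl: float
    t: float
    p: float


class PipelineSummary(BaseModel):
    """Schema of the run summary JSON."""

    seed: int
    n_seed_genes: int
    n_nodes: int
    n_edges: int
    power_law_r_squared: float
    hubs: list[str]
    backbone_nodes: int
    backbone_edges: int
    hub_edge_fraction: float
    accuracy_table: list[dict]  # level, per-hub frequencies, accuracy, n_networks
    overall_accuracy: float
    n_unique_tfs: int
    top_tfs: list[tuple[str, int]]
    group_comparisons: list[GroupComparisonRow]


def run_pipeline(cfg: PipelineConfig) -> PipelineSummary:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start; resolved config: %s", cfg.model_dump())

    def stage(name):
        logger.info("stage %s", name)
        return name

    # --- seed genes -------------------------------------------------
    name = stage("genelist")
    try:
        if cfg.gene_list_path:
            raw = io.read_gene_list_tsv(cfg.gene_list_path)
            tm = [g for g in raw if "curated" not in g.source]
            curated = [g for g in raw if "curated" in g.source]
        else:
            tm, curated = simulate.simulate_gene_lists(seed=cfg.seed)
        seeds = genelist.assemble_seed_genes(tm, curated, z_min=cfg.z_min)
        io.write_gene_list_tsv(seeds, out / "seed_genes.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(name, exc) from exc

    # --- graph ------------------------------------------------------
    name = stage("graph")
    try:
        if cfg.edges_path:
            rows = io.read_edge_tsv(cfg.edges_path)
            g = graph.build_graph(rows, min_confidence=cfg.min_confidence)
            stats = prioritize.compute_node_stats(g)
            sel = prioritize.select_hubs(stats, cfg.degree_cut, cfg.bc_cut)
            hubs = list(sel.hubs)
        else:
            g, planted = simulate.simulate_ppi(
                simulate.NetworkSimConfig(seed=cfg.seed)
            )
            stats = prioritize.compute_node_stats(g)
            sel = prioritize.select_hubs(stats, cfg.degree_cut, cfg.bc_cut)
            hubs = list(sel.hubs)
        fit = graph.fit_power_law({s.node: s.degree for s in stats})
        io.write_stats_tsv(stats, out / "node_stats.tsv")
        io.write_edge_tsv(g, out / "network_edges.tsv")
        io.write_graphml(g, out / "network.graphml")
        io.write_sif(g, out / "network.sif")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(name, exc) from exc

    # --- backbone ---------------------------------------------------
    name = stage("prioritize")
    try:
        backbone = prioritize.extract_backbone(g, hubs)
        frac = prioritize.hub_edge_fraction(backbone, hubs)
        io.write_sif(backbone, out / "backbone.sif")
        io.write_graphml(backbone, out / "backbone.graphml")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(name, exc) from exc

    # --- validation -------------------------------------------------
    name = stage("validate")
    try:
        acc_table, detail = validate.run_validation(
            g,
            hubs,
            pool_size=cfg.pool_size,
            repeats=cfg.repeats,
            levels=cfg.levels,
            seed=cfg.seed,
        )
        acc_table.to_csv(out / "accuracy_table.tsv", sep="\t", index=False)
        detail.to_csv(out / "test_networks.tsv", sep="\t", index=False)
        overall = float(
            acc_table.loc[acc_table["level"] == "Overall", "accuracy"].iloc[0]
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(name, exc) from exc

    # --- regulatory network -----------------------------------------
    name = stage("regnet")
    try:
        if cfg.tf_table_path:
            records = io.read_tf_table_tsv(cfg.tf_table_path)
        else:
            records = simulate.simulate_tf_table(seed=cfg.seed)
        io.write_tf_table_tsv(records, out / "tf_evidence.tsv")
        tf_sets = regnet.filter_evidence(records, min_sites=cfg.min_sites)
        union = regnet.unique_tf_union(tf_sets)
        net = regnet.build_regulatory_network(tf_sets)
        top = regnet.rank_tf_connectivity(net, top_n=3)
        io.write_sif(net, out / "regulatory.sif", relation="reg")
        pd.DataFrame(top, columns=["tf", "connectivity"]).to_csv(
            out / "top_tfs.tsv", sep="\t", index=False
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(name, exc) from exc

    # --- expression -------------------------------------------------
    name = stage("expression")
    try:
        if cfg.ct_path:
            ct = io.read_ct_csv(cfg.ct_path)
        else:
            ct = simulate.simulate_ct(simulate.CtSimConfig(seed=cfg.seed))
        expr = expression.expression_table(ct)
        expr.to_csv(out / "relative_expression.tsv", sep="\t", index=False)
        comp_df = expression.group_comparison_table(expr)
        comparisons = [
            GroupComparisonRow(**row) for row in comp_df.to_dict(orient="records")
        ]
        comp_df.to_csv(out / "group_comparison.tsv", sep="\t", index=False)
        wide = expr.pivot_table(index="sample_id", columns="gene",
                                values="rel_expr")
        r, _ = expression.correlation_matrix(wide)
        r.to_csv(out / "correlation_matrix.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(name, exc) from exc

    summary = PipelineSummary(
        seed=cfg.seed,
        n_seed_genes=len(seeds),
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        power_law_r_squared=fit.r_squared,
        hubs=hubs,
        backbone_nodes=backbone.number_of_nodes(),
        backbone_edges=backbone.number_of_edges(),
        hub_edge_fraction=frac,
        accuracy_table=acc_table.to_dict(orient="records"),
        overall_accuracy=overall,
        n_unique_tfs=len(union),
        top_tfs=top,
        group_comparisons=comparisons,
    )
    (out / "summary.json").write_text(summary.model_dump_json(indent=2))
    (out / "summary.schema.json").write_text(
        json.dumps(PipelineSummary.model_json_schema(), indent=2)
    )
    logger.info("pipeline complete; summary written to %s", out / "summary.json")
    return summary
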