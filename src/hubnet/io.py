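"""Readers and writers for the pipeline's tabular and graph formats.

Formats: STRING-style edge-list TSV, SIF and GraphML graph exports,
node-stats TSV, gene-list TSV, TF evidence TSV, and long Ct CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .genelist import ScoredGene
from .prioritize import NodeStats
from .regnet import TFBindingRecord

__all__ = [
    "read_edge_tsv",
    "write_edge_tsv",
    "write_sif",
    "write_graphml",
    "read_graphml",
    "write_stats_tsv",
    "read_stats_tsv",
    "read_gene_list_tsv",
    "write_gene_list_tsv",
    "read_tf_table_tsv",
    "write_tf_table_tsv",
    "read_ct_csv",
]


def read_edge_tsv(path: str | Path) -> list[tuple[str, str, float]]:
    """Edge rows from a TSV with header node_a, node_b, score;
    '#'-prefixed comment lines are skipped."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"node_a", "node_b", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return list(df[["node_a", "node_b", "score"]].itertuples(index=False, name=None))


def write_edge_tsv(g: nx.Graph, path: str | Path) -> None:
    rows = [
        {"node_a": a, "node_b": b, "score": d.get("confidence", 1.0)}
        for a, b, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "score"]).to_csv(
        path, sep="\t", index=False
    )


def write_sif(g: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Cytoscape SIF export; isolated nodes get a bare-node line."""
    with open(path, "w") as fh:
        for a, b in g.edges:
            fh.write(f"{a}\t{relation}\t{b}\n")
        for v in g.nodes:
            if g.degree(v) == 0:
                fh.write(f"{v}\n")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def write_stats_tsv(stats: Sequence[NodeStats], path: str | Path) -> None:
    pd.DataFrame(
        [{"node": s.node, "degree": s.degree, "betweenness": s.bc} for s in stats]
    ).to_csv(path, sep="\t", index=False)


def read_stats_tsv(path: str | Path) -> list[NodeStats]:
    df = pd.read_csv(path, sep="\t")
    return [
        NodeStats(node=str(r.node), degree=int(r.degree), bc=float(r.betweenness))
        for r in df.itertuples(index=False)
    ]


def read_gene_list_tsv(path: str | Path) -> list[ScoredGene]:
    """Gene list TSV with columns symbol, z_score (optional), source."""
    df = pd.read_csv(path, sep="\t")
    genes = []
    for r in df.itertuples(index=False):
        z = getattr(r, "z_score", None)
        z = None if z is None or pd.isna(z) else float(z)
        genes.append(
            ScoredGene(symbol=str(r.symbol), z_score=z,
                       source=str(getattr(r, "source", "unknown")))
        )
    return genes


def write_gene_list_tsv(genes: Iterable[ScoredGene], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "symbol": g.symbol,
                "z_score": g.z_score,
                "source": "+".join(sorted(g.source)),
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_tf_table_tsv(path: str | Path) -> list[TFBindingRecord]:
    """TF evidence TSV with columns tf, family, target, n_sites."""
    df = pd.read_csv(path, sep="\t")
    return [
        TFBindingRecord(
            tf=str(r.tf),
            target=str(r.target),
            n_sites=int(r.n_sites),
            family=None if pd.isna(getattr(r, "family", None)) else str(r.family),
        )
        for r in df.itertuples(index=False)
    ]


def write_tf_table_tsv(records: Iterable[TFBindingRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"tf": r.tf, "family": r.family or "", "target": r.target,
             "n_sites": r.n_sites}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    """Long Ct CSV: sample_id, group, gene, replicate, ct."""
    df = pd.read_csv(path)
    required = {"sample_id", "group", "gene", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
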