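"""Hub-gene selection by dual topological cutoff and backbone extraction.

A node is a hub when it clears EITHER strict cutoff: degree > degree_cut
or betweenness > bc_cut.  The union-of-strict-criteria reading is forced
by the published worked example, in which one hub (degree 49, BC 0.0524)
passes on betweenness alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .graph import betweenness_centrality, node_degrees

__all__ = [
    "NodeStats",
    "HubSelection",
    "compute_node_stats",
    "rank_nodes",
    "select_hubs",
    "extract_backbone",
    "hub_edge_fraction",
]

DEGREE_CUT_DEFAULT = 50
BC_CUT_DEFAULT = 0.05


@dataclass(frozen=True)
class NodeStats:
    node: str
    degree: int
    bc: float


@dataclass(frozen=True)
class HubSelection:
    hubs: tuple[str, ...]
    degree_cut: int
    bc_cut: float


def compute_node_stats(g: nx.Graph) -> list[NodeStats]:
    """Degree and normalized betweenness for every node of *g*."""
    deg = node_degrees(g)
    bc = betweenness_centrality(g)
    return [NodeStats(node=v, degree=deg[v], bc=bc[v]) for v in g.nodes]


def rank_nodes(stats: Sequence[NodeStats]) -> list[str]:
    """Canonical node ranking: bc desc, then degree desc, then symbol asc."""
    if not stats:
        raise ValueError("rank_nodes requires at least one NodeStats record")
    ordered = sorted(stats, key=lambda s: (-s.bc, -s.degree, s.node))
    return [s.node for s in ordered]


def select_hubs(
    stats: Sequence[NodeStats],
    degree_cut: int = DEGREE_CUT_DEFAULT,
    bc_cut: float = BC_CUT_DEFAULT,
) -> HubSelection:
    """Nodes passing either strict cutoff, in canonical rank order."""
    if degree_cut < 0 or bc_cut < 0:
        raise ValueError("cutoffs must be non-negative")
    passing = [s for s in stats if s.degree > degree_cut or s.bc > bc_cut]
    hubs = tuple(rank_nodes(passing)) if passing else ()
    return HubSelection(hubs=hubs, degree_cut=degree_cut, bc_cut=bc_cut)


def extract_backbone(g: nx.Graph, hubs: Iterable[str]) -> nx.Graph:
    """Node-induced subgraph on the hubs and all their direct neighbors.

    Edges between two hub-neighbors are retained (full induced subgraph).
    """
    hubs = list(hubs)
    for h in hubs:
        if h not in g:
            raise KeyError(f"hub {h!r} not present in graph")
    keep = set(hubs)
    for h in hubs:
        keep.update(g.neighbors(h))
    return g.subgraph(keep).copy()


def hub_edge_fraction(backbone: nx.Graph, hubs: Iterable[str]) -> float:
    """Fraction of backbone edges incident to at least one hub."""
    hubset = set(hubs)
    missing = hubset - set(backbone.nodes)
    if missing:
        raise KeyError(f"hubs not in backbone: {sorted(missing)}")
    m = backbone.number_of_edges()
    if m == 0:
        raise ValueError("backbone has no edges; fraction undefined")
    incident = sum(1 for a, b in backbone.edges if a in hubset or b in hubset)
    return incident / m
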