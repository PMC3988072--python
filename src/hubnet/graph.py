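"""Undirected PPI graph construction and topological statistics.

The graph is an unweighted, undirected simple graph over gene symbols.
Edge confidences (STRING-style combined scores) are used only as an
inclusion filter at construction time; all shortest-path computations
are hop-count based.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as _sps

__all__ = [
    "GraphInputError",
    "PowerLawFit",
    "build_graph",
    "node_degrees",
    "betweenness_centrality",
    "fit_power_law",
]


class GraphInputError(ValueError):
    """Raised for malformed or empty edge-list input."""


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares log-log fit of a degree histogram, count(d) ~ a * d**b."""

    coefficient_a: float
    exponent_b: float
    r_squared: float


def build_graph(
    edge_rows: Iterable[Sequence],
    min_confidence: float = 0.7,
) -> nx.Graph:
    """Build the interaction graph from (node_a, node_b, score) rows.

    Scores may be on the [0, 1] scale or STRING's 0-999 integer scale;
    if any score exceeds 1 the whole input is assumed to be on the
    integer scale and divided by 1000 before thresholding.  Duplicate
    rows for the same unordered pair are collapsed keeping the maximum
    confidence; self-loop rows are dropped with a warning.

    Parameters
    ----------
    edge_rows:
        Iterable of ``(symbol_a, symbol_b, confidence)`` triples.
    min_confidence:
        Inclusion threshold; edges with confidence >= this are kept.

    Raises
    ------
    GraphInputError
        On a malformed row (naming its position) or when no edge
        survives the confidence filter.
    """
    parsed: list[tuple[str, str, float]] = []
    for i, row in enumerate(edge_rows, start=1):
        try:
            a, b, score = row
            a, b = str(a).strip(), str(b).strip()
            score = float(score)
        except (TypeError, ValueError) as exc:
            raise GraphInputError(f"malformed edge row {i}: {row!r}") from exc
        if not a or not b:
            raise GraphInputError(f"malformed edge row {i}: empty node symbol")
        if score < 0:
            raise GraphInputError(f"malformed edge row {i}: negative score {score}")
        parsed.append((a, b, score))

    if parsed and max(s for _, _, s in parsed) > 1.0:
        # STRING exports combined scores as integers in [0, 999]
        parsed = [(a, b, s / 1000.0) for a, b, s in parsed]

    g = nx.Graph()
    for a, b, score in parsed:
        if a == b:
            warnings.warn(f"dropping self-loop on {a!r}", stacklevel=2)
            continue
        if score < min_confidence:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], score)
        else:
            g.add_edge(a, b, confidence=score)

    if g.number_of_edges() == 0:
        raise GraphInputError("empty graph: no edge passed the confidence filter")
    return g


def node_degrees(g: nx.Graph) -> dict[str, int]:
    """Per-node edge count; isolated nodes report 0."""
    return dict(g.degree())


def betweenness_centrality(g: nx.Graph) -> dict[str, float]:
    """Normalized betweenness centrality over unweighted shortest paths.

    bc(v) = sum over unordered pairs s != t != v of sigma_st(v)/sigma_st,
    divided by (n-1)(n-2)/2 where n counts every node in the graph
    (disconnected nodes included).  Pairs in different components
    contribute zero.  Graphs with fewer than 3 nodes have no interior
    pairs; all centralities are defined as 0 with a warning.
    """
    n = g.number_of_nodes()
    if n < 3:
        warnings.warn(
            "betweenness centrality undefined for < 3 nodes; returning zeros",
            stacklevel=2,
        )
        return {v: 0.0 for v in g.nodes}
    return nx.betweenness_centrality(g, normalized=True, weight=None)


def fit_power_law(degrees: Mapping[str, int]) -> PowerLawFit:
    """Fit count(d) ~ a * d**b by least squares on log-log axes.

    The raw degree histogram is used (no binning, no cumulative
    transform); degrees with zero count and degree 0 are skipped.

    Raises
    ------
    GraphInputError
        If fewer than 3 distinct positive degree values are present.
    """
    values = np.asarray([d for d in degrees.values() if d >= 1], dtype=int)
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size < 3:
        raise GraphInputError(
            "insufficient degree diversity: need >= 3 distinct positive degrees, "
            f"got {uniq.size}"
        )
    logx = np.log(uniq.astype(float))
    logy = np.log(counts.astype(float))
    res = _sps.linregress(logx, logy)
    return PowerLawFit(
        coefficient_a=math.exp(res.intercept),
        exponent_b=float(res.slope),
        r_squared=float(res.rvalue**2),
    )
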