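"""TF -> target regulatory network from promoter-scan evidence tables.

Each record is one TF/target pair with a binding-site count from a
promoter scan.  Pairs with at least `min_sites` sites (default 2, i.e.
strictly more than one site) form edges of a bipartite regulatory
network; TFs are then ranked by how many targets they regulate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "TFBindingRecord",
    "filter_evidence",
    "unique_tf_union",
    "build_regulatory_network",
    "rank_tf_connectivity",
]

MIN_SITES_DEFAULT = 2


@dataclass(frozen=True)
class TFBindingRecord:
    tf: str
    target: str
    n_sites: int
    family: str | None = None


def filter_evidence(
    records: Iterable[TFBindingRecord],
    min_sites: int = MIN_SITES_DEFAULT,
) -> dict[str, set[str]]:
    """Map each target to the TFs with sufficient binding evidence.

    Site counts for duplicate (tf, target) records are summed before
    the filter is applied.
    """
    totals: dict[tuple[str, str], int] = {}
    for rec in records:
        if rec.n_sites < 0:
            raise ValueError(
                f"negative binding-site count in record {rec.tf!r} -> "
                f"{rec.target!r}: {rec.n_sites}"
            )
        key = (rec.tf, rec.target)
        totals[key] = totals.get(key, 0) + rec.n_sites

    out: dict[str, set[str]] = {}
    for (tf, target), n in totals.items():
        if n >= min_sites:
            out.setdefault(target, set()).add(tf)
    return out


def unique_tf_union(tf_sets: Mapping[str, set[str]]) -> list[str]:
    """Sorted union of TFs across all targets (redundancy removed)."""
    union: set[str] = set()
    for tfs in tf_sets.values():
        union |= tfs
    return sorted(union)


def build_regulatory_network(tf_sets: Mapping[str, set[str]]) -> nx.Graph:
    """Bipartite TF/target graph; edge (tf, target) iff evidence passed.

    Nodes carry a ``kind`` attribute ("tf" or "target").  A symbol
    appearing on both sides is disambiguated by prefixing the TF node
    with ``TF:`` and a warning is emitted.
    """
    targets = set(tf_sets)
    net = nx.Graph()
    for target in sorted(targets):
        net.add_node(target, kind="target")
    for target, tfs in tf_sets.items():
        for tf in tfs:
            name = tf
            if tf in targets:
                name = f"TF:{tf}"
                warnings.warn(
                    f"symbol {tf!r} is both TF and target; TF node renamed {name!r}",
                    stacklevel=2,
                )
            net.add_node(name, kind="tf")
            net.add_edge(name, target)
    return net


def rank_tf_connectivity(
    net: nx.Graph,
    top_n: int = 3,
) -> list[tuple[str, int]]:
    """TFs ranked by target connectivity (desc), ties lexicographic."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty regulatory network")
    tfs = [v for v, d in net.nodes(data=True) if d.get("kind") == "tf"]
    ranked = sorted(tfs, key=lambda v: (-net.degree(v), v))
    return [(v, net.degree(v)) for v in ranked[:top_n]]
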