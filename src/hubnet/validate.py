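"""Leave-k-out robustness validation of hub genes.

Test networks are copies of the main network with 1-4 nodes deleted from
the pool of top-ranked nodes.  Level 1 deletes each pool member once.
At levels 2-4 each deletion set contains exactly one designated hub plus
randomly drawn pool companions, repeated a fixed number of times per
hub, so the default design yields 22 + 3*25 = 97 test networks.  A
hub's retention frequency counts the test networks whose recomputed
top-5 ranking still contains it; the per-level accuracy is the retained
fraction of the hub set, and the overall accuracy is the unweighted
mean of the level accuracies.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .prioritize import compute_node_stats, rank_nodes

__all__ = [
    "DeletionSet",
    "DeletionDesign",
    "RetentionTable",
    "design_deletions",
    "run_test_network",
    "retention_frequencies",
    "level_accuracy",
    "overall_accuracy",
    "run_validation",
]

TOP_N = 5


@dataclass(frozen=True)
class DeletionSet:
    """One test network's removed nodes; the designated hub (levels >= 2)
    is the hub whose (hub, repeat) slot this set fills."""

    nodes: frozenset[str]
    designated_hub: str | None = None


@dataclass(frozen=True)
class DeletionDesign:
    levels: dict[int, list[DeletionSet]]
    seed: int

    @property
    def n_networks(self) -> int:
        return sum(len(sets) for sets in self.levels.values())


@dataclass(frozen=True)
class RetentionTable:
    """Per-level hub retention counts and network counts."""

    frequencies: pd.DataFrame  # index: level, columns: hubs, values: counts
    n_networks: dict[int, int]


def design_deletions(
    pool: Sequence[str],
    hubs: Sequence[str],
    repeats: int = 5,
    levels: Iterable[int] = (1, 2, 3, 4),
    seed: int = 0,
) -> DeletionDesign:
    """Construct the deletion design over the top-ranked pool.

    Level 1: one singleton per pool member.  Level k >= 2: for each hub
    and each of `repeats` repeats, the hub plus k-1 companions sampled
    without replacement from the rest of the pool.  Duplicate sets
    across repeats are permitted.
    """
    pool = list(pool)
    hubs = list(hubs)
    levels = sorted(set(levels))
    if not set(levels) <= {1, 2, 3, 4}:
        raise ValueError(f"levels must be within 1..4, got {levels}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    missing = set(hubs) - set(pool)
    if missing:
        raise ValueError(f"hubs not in pool: {sorted(missing)}")
    for k in levels:
        if k - 1 > len(pool) - 1:
            raise ValueError(f"level {k} needs {k - 1} companions, pool too small")

    rng = random.Random(seed)
    design: dict[int, list[DeletionSet]] = {}
    for k in levels:
        if k == 1:
            design[k] = [
                DeletionSet(nodes=frozenset([m]),
                            designated_hub=m if m in hubs else None)
                for m in pool
            ]
            continue
        sets: list[DeletionSet] = []
        for h in hubs:
            others = [m for m in pool if m != h]
            for _ in range(repeats):
                companions = rng.sample(others, k - 1)
                sets.append(
                    DeletionSet(nodes=frozenset([h, *companions]),
                                designated_hub=h)
                )
        design[k] = sets
    return DeletionDesign(levels=design, seed=seed)


def run_test_network(g: nx.Graph, deletion: Iterable[str]) -> list[str]:
    """Delete the given nodes, recompute stats, return the new top-5."""
    deletion = set(deletion)
    missing = deletion - set(g.nodes)
    if missing:
        raise KeyError(f"deletion names absent nodes: {sorted(missing)}")
    if g.number_of_nodes() - len(deletion) < TOP_N:
        raise ValueError(
            f"only {g.number_of_nodes() - len(deletion)} nodes would remain; "
            f"need >= {TOP_N}"
        )
    h = g.copy()
    h.remove_nodes_from(deletion)
    return rank_nodes(compute_node_stats(h))[:TOP_N]


def retention_frequencies(
    results: Mapping[int, Sequence[Sequence[str]]],
    hubs: Sequence[str],
) -> RetentionTable:
    """Count, per level and hub, the test networks retaining the hub in
    their top-5."""
    if not results:
        raise ValueError("no test-network results supplied")
    rows = {}
    n_networks = {}
    for level, top5_lists in sorted(results.items()):
        rows[level] = {h: sum(h in t for t in top5_lists) for h in hubs}
        n_networks[level] = len(top5_lists)
    freq = pd.DataFrame.from_dict(rows, orient="index", columns=list(hubs))
    freq.index.name = "level"
    return RetentionTable(frequencies=freq, n_networks=n_networks)


def level_accuracy(
    frequencies: Sequence[int],
    n_networks: int,
    n_hubs: int = 5,
) -> float:
    """Retained fraction of the hub set at one deletion level:
    sum(frequencies) / (n_hubs * n_networks)."""
    if n_networks == 0:
        raise ValueError("n_networks must be positive")
    if any(f > n_networks for f in frequencies):
        raise ValueError("a frequency exceeds the number of test networks")
    return sum(frequencies) / (n_hubs * n_networks)


def overall_accuracy(level_accuracies: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-level accuracies."""
    if not level_accuracies:
        raise ValueError("no level accuracies supplied")
    return sum(level_accuracies) / len(level_accuracies)


def run_validation(
    g: nx.Graph,
    hubs: Sequence[str],
    pool_size: int = 22,
    repeats: int = 5,
    levels: Iterable[int] = (1, 2, 3, 4),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end robustness run on one graph.

    Ranks the nodes, takes the top `pool_size` as the deletion pool,
    builds the design, reruns every test network, and returns
    (accuracy_table, detail) where accuracy_table mirrors the published
    layout (level, per-hub frequencies, accuracy, n_networks, plus an
    Overall row) and detail lists each test network's deleted nodes and
    recomputed top-5.
    """
    ranked = rank_nodes(compute_node_stats(g))
    pool = ranked[:pool_size]
    design = design_deletions(pool, hubs, repeats=repeats, levels=levels, seed=seed)

    results: dict[int, list[list[str]]] = {}
    detail_rows = []
    for level, sets in sorted(design.levels.items()):
        results[level] = []
        for i, ds in enumerate(sets, start=1):
            top5 = run_test_network(g, ds.nodes)
            results[level].append(top5)
            detail_rows.append(
                {
                    "level": level,
                    "network": i,
                    "designated_hub": ds.designated_hub or "",
                    "deleted": ",".join(sorted(ds.nodes)),
                    "top5": ",".join(top5),
                }
            )

    table = retention_frequencies(results, hubs)
    acc_rows = []
    level_accs = []
    for level in sorted(results):
        freqs = table.frequencies.loc[level, list(hubs)]
        acc = level_accuracy(list(freqs), table.n_networks[level], n_hubs=len(hubs))
        level_accs.append(acc)
        acc_rows.append(
            {
                "level": str(level),
                **{h: int(freqs[h]) for h in hubs},
                "accuracy": round(acc, 3),
                "n_networks": table.n_networks[level],
            }
        )
    acc_rows.append(
        {
            "level": "Overall",
            **{h: int(table.frequencies[h].sum()) for h in hubs},
            "accuracy": round(overall_accuracy(level_accs), 3),
            "n_networks": sum(table.n_networks.values()),
        }
    )
    return pd.DataFrame(acc_rows), pd.DataFrame(detail_rows)
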