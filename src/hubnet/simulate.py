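"""Seeded generators for synthetic study inputs.

These emulate the statistical structure of the pipeline's real inputs —
a scale-free PPI network with a handful of dominant hubs, a promoter-scan
TF evidence table with a few core regulators bound to every target, and
a case/control qPCR Ct table with known fold changes — so every analysis
stage runs and is testable without database access.

Defaults mirror the published study conditions: a 145-node / 1234-edge
network with 5 planted hubs, per-target TF counts (69, 75, 74, 70, 37)
whose union has 184 members with 3 core TFs, and 64 cases vs 64 controls
assayed in duplicate against a GUSB endogenous control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genelist import ScoredGene
from .regnet import TFBindingRecord

__all__ = [
    "NetworkSimConfig",
    "CtSimConfig",
    "simulate_ppi",
    "simulate_tf_table",
    "simulate_ct",
    "simulate_gene_lists",
    "HUB_GENES",
    "CORE_TFS",
    "EXPRESSION_DEFAULTS",
]

HUB_GENES = ("IL6", "VEGFA", "IL1B", "TNF", "PTGS2")
CORE_TFS = ("NFKB1", "STAT3", "JUN")

# (control mean rel. expression, case mean rel. expression) per gene;
# fold change = case / control.
EXPRESSION_DEFAULTS: dict[str, tuple[float, float]] = {
    "IL6": (1.48, 2.08),
    "VEGFA": (1.15, 1.91),
    "IL1B": (0.93, 1.19),
    "TNF": (1.26, 1.93),
    "PTGS2": (1.63, 6.12),
    "NFKB1": (0.21, 0.31),
    "STAT3": (0.41, 0.61),
    "JUN": (1.43, 2.95),
}


@dataclass(frozen=True)
class NetworkSimConfig:
    n_nodes: int = 145
    target_edges: int = 1234
    n_hubs: int = 5
    hub_degree_min: int = 55
    attachment_edges_per_node: int = 8
    edge_tolerance: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_hubs >= self.n_nodes:
            raise ValueError("n_hubs must be < n_nodes")
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if self.target_edges > max_edges:
            raise ValueError("target_edges exceeds the simple-graph maximum")
        if not 1 <= self.attachment_edges_per_node < self.n_nodes:
            raise ValueError("attachment_edges_per_node out of range")


@dataclass(frozen=True)
class CtSimConfig:
    n_cases: int = 64
    n_controls: int = 64
    # gene -> (control mean dCt, case-vs-control fold change)
    genes: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            g: (-math.log2(ctrl), case / ctrl)
            for g, (ctrl, case) in EXPRESSION_DEFAULTS.items()
        }
    )
    reference_gene: str = "GUSB"
    reference_mean_ct: float = 25.0
    replicate_sd: float = 0.15  # cycles, technical
    biological_sd: float = 0.6  # dCt units, between samples
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if any(fc <= 0 for _, fc in self.genes.values()):
            raise ValueError("fold changes must be positive")
        if self.replicate_sd < 0 or self.biological_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def simulate_ppi(cfg: NetworkSimConfig) -> tuple[nx.Graph, list[str]]:
    """Scale-free interaction network with planted high-degree hubs.

    A preferential-attachment graph is grown to `n_nodes`; the
    `n_hubs` highest-degree nodes are designated hubs and receive extra
    edges until each exceeds `hub_degree_min` and the total edge count
    reaches `target_edges` (within `edge_tolerance`).  Edge confidences
    are drawn uniformly from [0.7, 1.0].  Node symbols are G001..Gnnn;
    planted hubs are renamed to the canonical hub-gene symbols.

    Returns ``(graph, hubs)`` with hubs sorted by decreasing degree.
    """
    rng = np.random.default_rng(cfg.seed)
    g = nx.barabasi_albert_graph(
        cfg.n_nodes, cfg.attachment_edges_per_node, seed=int(rng.integers(2**31))
    )
    tol = int(round(cfg.target_edges * cfg.edge_tolerance))
    if cfg.n_hubs == 0 and g.number_of_edges() < cfg.target_edges - tol:
        raise ValueError(
            "infeasible config: no hubs to wire extra edges to, yet the "
            "attachment graph is below target_edges"
        )
    if g.number_of_edges() > cfg.target_edges + tol:
        raise ValueError(
            "infeasible config: attachment graph already exceeds target_edges; "
            "lower attachment_edges_per_node"
        )

    degs = dict(g.degree())
    hubs = sorted(degs, key=lambda v: (-degs[v], v))[: cfg.n_hubs]

    def boostable(h):
        return [v for v in g.nodes if v != h and not g.has_edge(h, v)]

    # Phase 1: lift every hub strictly above hub_degree_min.
    for h in hubs:
        while g.degree(h) <= cfg.hub_degree_min:
            cand = boostable(h)
            if not cand:
                raise ValueError("infeasible config: hub saturated before target")
            g.add_edge(h, cand[rng.integers(len(cand))])
    # Phase 2: round-robin extra hub edges up to the exact edge target.
    i = 0
    while g.number_of_edges() < cfg.target_edges and hubs:
        h = hubs[i % len(hubs)]
        cand = boostable(h)
        if cand:
            g.add_edge(h, cand[rng.integers(len(cand))])
        i += 1
        if i > 10 * cfg.target_edges:
            raise ValueError("infeasible config: cannot reach target_edges")
    if abs(g.number_of_edges() - cfg.target_edges) > tol:
        raise ValueError("infeasible config: edge count outside tolerance")

    for a, b in g.edges:
        g[a][b]["confidence"] = float(rng.uniform(0.7, 1.0))

    width = len(str(cfg.n_nodes))
    names = {v: f"G{v + 1:0{width}d}" for v in g.nodes}
    for i, h in enumerate(hubs):
        if i < len(HUB_GENES):
            names[h] = HUB_GENES[i]
    g = nx.relabel_nodes(g, names)
    hub_names = [names[h] for h in hubs]
    hub_names.sort(key=lambda v: -g.degree(v))
    return g, hub_names


def simulate_tf_table(
    n_targets: int = 5,
    per_target_tf_counts: Sequence[int] = (69, 75, 74, 70, 37),
    n_core: int = 3,
    union_size: int = 184,
    decoy_fraction: float = 0.2,
    seed: int = 0,
    targets: Sequence[str] | None = None,
) -> list[TFBindingRecord]:
    """Promoter-scan evidence table with planted core regulators.

    `n_core` core TFs bind every target with >= 2 sites; the remaining
    TFs are allocated so that, after the >= 2-site evidence filter, each
    target has exactly its configured TF count and the union across
    targets has exactly `union_size` members.  `decoy_fraction` of the
    emitted rows are decoys — fresh TF names with a single binding site
    — which the evidence filter removes; a fraction of 1.0 emits decoys
    only.
    """
    counts = list(per_target_tf_counts)
    if len(counts) != n_targets:
        raise ValueError("per_target_tf_counts length must equal n_targets")
    if targets is None:
        targets = list(HUB_GENES[:n_targets])
        if len(targets) < n_targets:
            targets += [f"TGT{i}" for i in range(len(targets), n_targets)]
    targets = list(targets)
    if n_core > min(counts, default=0):
        raise ValueError("n_core exceeds the smallest per-target TF count")
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)

    records: list[TFBindingRecord] = []
    if decoy_fraction < 1.0:
        # Non-core TFs: degrees in {1, 2} chosen so memberships add up.
        residual = [c - n_core for c in counts]
        n_noncore = union_size - n_core
        memberships = sum(residual)
        if not n_noncore <= memberships <= n_noncore * n_targets:
            raise ValueError(
                "infeasible overlap arithmetic: union_size incompatible with "
                "per-target counts"
            )
        extra = memberships - n_noncore  # memberships beyond one per TF
        degrees = np.ones(n_noncore, dtype=int)
        i = 0
        while extra > 0:
            if degrees[i % n_noncore] < n_targets:
                degrees[i % n_noncore] += 1
                extra -= 1
            i += 1

        core = list(CORE_TFS[:n_core])
        core += [f"CORE{i}" for i in range(len(core), n_core)]
        noncore = [f"TF{i + 1:03d}" for i in range(n_noncore)]
        families = {
            tf: f"F{rng.integers(1, 21):02d}" for tf in [*core, *noncore]
        }

        capacity = dict(zip(targets, residual))
        for tf in core:
            for t in targets:
                records.append(
                    TFBindingRecord(
                        tf=tf, target=t,
                        n_sites=int(rng.integers(2, 9)),
                        family=families[tf],
                    )
                )
        order = rng.permutation(n_noncore)
        for idx in order:
            tf = noncore[idx]
            # assign to the targets with the most remaining capacity
            avail = sorted(targets, key=lambda t: (-capacity[t], t))
            chosen = avail[: degrees[idx]]
            if any(capacity[t] <= 0 for t in chosen):
                raise ValueError("infeasible overlap arithmetic: capacity exhausted")
            for t in chosen:
                capacity[t] -= 1
                records.append(
                    TFBindingRecord(
                        tf=tf, target=t,
                        n_sites=int(rng.integers(2, 7)),
                        family=families[tf],
                    )
                )
        assert all(v == 0 for v in capacity.values())

    if decoy_fraction > 0:
        if decoy_fraction < 1.0:
            n_decoys = int(round(decoy_fraction / (1 - decoy_fraction) * len(records)))
        else:
            n_decoys = sum(counts)
        for i in range(n_decoys):
            records.append(
                TFBindingRecord(
                    tf=f"DECOY{i + 1:03d}",
                    target=targets[int(rng.integers(len(targets)))],
                    n_sites=1,
                    family="F00",
                )
            )
    return records


def simulate_ct(cfg: CtSimConfig) -> pd.DataFrame:
    """Case/control qPCR Ct table with known per-gene fold changes.

    Per sample, the reference-gene Ct is Normal(reference_mean_ct,
    biological_sd); each target gene's dCt is its control mean dCt,
    shifted by -log2(fold change) in cases, plus Normal(0,
    biological_sd) biological noise.  Technical replicates add
    Normal(0, replicate_sd) per well.  log2 mapping of fold change to
    a dCt shift encodes the efficiency-2 doubling assumption.

    Returns a long DataFrame: sample_id, group, gene, replicate, ct.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = [(f"CASE{i + 1:03d}", "case") for i in range(cfg.n_cases)]
    samples += [(f"CTRL{i + 1:03d}", "control") for i in range(cfg.n_controls)]

    rows = []
    for sample_id, group in samples:
        ref_ct = rng.normal(cfg.reference_mean_ct, cfg.biological_sd)
        true_ct = {cfg.reference_gene: ref_ct}
        for gene, (ctrl_dct, fold) in cfg.genes.items():
            shift = -math.log2(fold) if group == "case" else 0.0
            dct = ctrl_dct + shift + rng.normal(0.0, cfg.biological_sd)
            true_ct[gene] = ref_ct + dct
        for gene, ct0 in true_ct.items():
            for rep in range(1, cfg.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "gene": gene,
                        "replicate": rep,
                        "ct": float(ct0 + rng.normal(0.0, cfg.replicate_sd)),
                    }
                )
    return pd.DataFrame(rows)


def simulate_gene_lists(
    n_text_mining: int = 78,
    n_curated: int = 68,
    n_overlap: int = 22,
    n_subthreshold: int = 15,
    seed: int = 0,
) -> tuple[list[ScoredGene], list[ScoredGene]]:
    """Two seed-gene sources: text-mining hits with relevancy Z-scores
    and a curated list without scores.

    The text-mining list has `n_text_mining` genes with Z > 1 plus
    `n_subthreshold` genes with Z <= 1 (removed by the relevancy
    filter); `n_overlap` symbols are shared with the curated list, so
    the filtered merge has n_text_mining + n_curated - n_overlap
    members.
    """
    if n_overlap > min(n_text_mining, n_curated):
        raise ValueError("overlap larger than a source list")
    rng = np.random.default_rng(seed)
    total = n_text_mining + n_curated - n_overlap + n_subthreshold
    symbols = [f"GENE{i + 1:03d}" for i in range(total)]

    tm_pass = symbols[:n_text_mining]
    shared = tm_pass[:n_overlap]
    curated_only = symbols[n_text_mining : n_text_mining + n_curated - n_overlap]
    sub = symbols[n_text_mining + n_curated - n_overlap :]

    text_mining = [
        ScoredGene(s, z_score=float(1.0 + rng.exponential(1.0) + 1e-6),
                   source="text-mining")
        for s in tm_pass
    ] + [
        ScoredGene(s, z_score=float(rng.uniform(-1.0, 1.0)), source="text-mining")
        for s in sub
    ]
    curated = [ScoredGene(s, source="curated") for s in [*shared, *curated_only]]
    return text_mining, curated
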