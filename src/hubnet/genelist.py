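"""Seed-gene assembly: relevancy-score filtering and cross-source merging.

Candidate genes come from two kinds of sources: text-mining hits with a
relevancy Z-score (filtered at Z > 1) and curated disease-database
entries without scores (which bypass the filter).  The merged,
deduplicated union forms the seed list for network construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

__all__ = [
    "ScoredGene",
    "canonical_symbol",
    "filter_by_zscore",
    "merge_gene_lists",
    "assemble_seed_genes",
]

Z_MIN_DEFAULT = 1.0


@dataclass(frozen=True)
class ScoredGene:
    symbol: str
    z_score: float | None = None
    source: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "symbol", canonical_symbol(self.symbol))
        if isinstance(self.source, str):
            object.__setattr__(self, "source", frozenset([self.source]))
        else:
            object.__setattr__(self, "source", frozenset(self.source))
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")


def canonical_symbol(symbol: str) -> str:
    """Upper-case, whitespace-stripped gene symbol."""
    return str(symbol).strip().upper()


def filter_by_zscore(
    genes: Sequence[ScoredGene],
    z_min: float = Z_MIN_DEFAULT,
) -> list[ScoredGene]:
    """Keep genes with z_score strictly greater than `z_min`, in order."""
    for g in genes:
        if g.z_score is None:
            raise ValueError(f"gene {g.symbol!r} has no z_score; cannot filter")
    return [g for g in genes if g.z_score > z_min]


def merge_gene_lists(
    list_a: Sequence[ScoredGene],
    list_b: Sequence[ScoredGene],
) -> list[ScoredGene]:
    """Deduplicated union by symbol; merged records carry both sources.

    The first non-None z_score wins; output preserves first-seen order.
    """
    merged: dict[str, ScoredGene] = {}
    for g in [*list_a, *list_b]:
        if g.symbol in merged:
            prev = merged[g.symbol]
            merged[g.symbol] = replace(
                prev,
                z_score=prev.z_score if prev.z_score is not None else g.z_score,
                source=prev.source | g.source,
            )
        else:
            merged[g.symbol] = g
    return list(merged.values())


def assemble_seed_genes(
    text_mining: Sequence[ScoredGene],
    curated: Sequence[ScoredGene],
    z_min: float = Z_MIN_DEFAULT,
) -> list[ScoredGene]:
    """Z-filter the text-mining list, then merge with the curated list
    (curated entries bypass the relevancy filter)."""
    return merge_gene_lists(filter_by_zscore(text_mining, z_min), curated)
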