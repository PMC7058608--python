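"""Hypergeometric gene-set enrichment of modules and gene lists.

Collections are filtered to the analysis background (sets intersected with
the gene universe; sets below a minimum size dropped), each (module, set)
pair gets a one-sided hypergeometric p-value P(X >= k), and BH correction
runs jointly over all module x set pairs within a collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["filter_collection", "hypergeom_p", "enrich", "EnrichmentAnalysis"]


def filter_collection(
    collection: dict[str, set[str]],
    background: set[str],
    min_size: int = 10,
) -> dict[str, set[str]]:
    """Intersect sets with the background and drop those below ``min_size``."""
    if not background:
        raise ValueError("background must be non-empty")
    background = set(background)
    out: dict[str, set[str]] = {}
    dropped = 0
    for name, members in collection.items():
        trimmed = set(members) & background
        if len(trimmed) >= min_size:
            out[name] = trimmed
        else:
            dropped += 1
    if dropped:
        logger.info("filter_collection: dropped %d of %d sets (< %d in-background genes)",
                    dropped, len(collection), min_size)
    return out


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """One-sided hypergeometric tail P(X >= k).

    ``k`` genes of a size-``n`` module fall in a size-``K`` set, drawn from a
    background of ``N`` genes.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    gene_lists: dict,
    collections: dict[str, dict[str, set[str]]],
    background: set[str],
    alpha: float = 0.05,
    set_min_size: int = 10,
    min_overlap: int = 0,
) -> pd.DataFrame:
    """Test every gene list against every set of every collection.

    ``gene_lists`` maps a module label (or any name) to its member genes;
    every list is intersected with the background first.  BH runs jointly
    across all (list, set) pairs within each collection; pairs significant
    at q < ``alpha`` (and, if ``min_overlap`` > 0, with at least that many
    overlapping genes) are flagged.
    """
    background = set(background)
    n_bg = len(background)
    rows = []
    for coll_name, collection in collections.items():
        filtered = filter_collection(collection, background, min_size=set_min_size)
        for module, genes in gene_lists.items():
            mod_genes = set(genes) & background
            for set_name, members in sorted(filtered.items()):
                k = len(mod_genes & members)
                rows.append(
                    (coll_name, module, set_name, k, len(mod_genes),
                     len(members), n_bg,
                     hypergeom_p(k, len(mod_genes), len(members), n_bg))
                )
    table = pd.DataFrame(
        rows,
        columns=["collection", "module", "set", "k", "n", "K", "N", "p"],
    )
    table["q"] = float("nan")
    for coll_name in collections:
        mask = table["collection"] == coll_name
        if mask.any():
            table.loc[mask, "q"] = bh_adjust(table.loc[mask, "p"].to_numpy())
    table["significant"] = (table["q"] < alpha) & (table["k"] >= min_overlap)
    return table


@dataclass
class EnrichmentAnalysis:
    """Convenience wrapper carrying background and collections across calls."""

    background: set[str]
    collections: dict[str, dict[str, set[str]]] = field(repr=False)
    alpha: float = 0.05
    set_min_size: int = 10
    min_overlap: int = 0

    def run(self, gene_lists: dict) -> pd.DataFrame:
        return enrich(
            gene_lists, self.collections, self.background,
            alpha=self.alpha, set_min_size=self.set_min_size,
            min_overlap=self.min_overlap,
        )
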