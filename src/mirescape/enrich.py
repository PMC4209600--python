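"""Gene-set over-representation analysis on GMT collections.

For each query gene list (e.g. up-regulated, down-regulated, or
seed-containing genes) and each gene set, overlap significance is the
hypergeometric upper tail P(X >= k) with X ~ Hypergeometric(N, K, n):
N genes in the universe, K in the set, n in the query, k in both.
p-values are Benjamini-Hochberg adjusted within each query list and
sets are ranked by ascending p (ties: descending overlap, then name).

Identifier matching is case-insensitive symbol equality; alias/ID
mapping is out of scope.  The universe defaults to the genes with
detectable expression in the screen's counts table (overridable to the
GMT union).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich_list",
    "rank_pathways",
]

logger = logging.getLogger(__name__)


def _norm(gene: str) -> str:
    return gene.strip().upper()


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets restricted to a universe of identifiers."""

    sets: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, Iterable[str]],
        universe: Iterable[str] | None = None,
    ) -> "GeneSetCollection":
        """Build a collection, normalising symbols and restricting each
        set to the universe (default: the union of all sets).  Sets that
        become empty after restriction are dropped with a log message.
        """
        raw = {name: frozenset(_norm(g) for g in members) for name, members in sets.items()}
        if universe is None:
            uni = frozenset().union(*raw.values()) if raw else frozenset()
        else:
            uni = frozenset(_norm(g) for g in universe)
        restricted = {}
        for name, members in raw.items():
            kept = members & uni
            if not kept:
                logger.warning("gene set %r empty after universe restriction; dropped", name)
                continue
            restricted[name] = kept
        return cls(sets=restricted, universe=uni)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` universe size, ``K`` set size, ``n`` query size, ``k`` overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    # survival function P(X > k-1); scipy evaluates the tail stably in
    # log-space internally
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_list(
    query: Iterable[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Over-representation of one query list against every set.

    Query genes outside the universe are dropped (their count is
    logged).  Returns one row per set, ranked by ascending p, ties by
    descending overlap then set name; empty on an empty query.
    """
    q = {_norm(g) for g in query}
    dropped = len(q - collection.universe)
    if dropped:
        logger.info("%d query gene(s) outside the universe dropped", dropped)
    q &= collection.universe
    columns = ["set_name", "k", "K", "n", "N", "p_value", "q_value"]
    if not q or not collection.sets:
        if not q:
            logger.warning("query list empty after universe restriction")
        return pd.DataFrame(columns=columns)
    N = len(collection.universe)
    n = len(q)
    rows = []
    for name, members in collection.sets.items():
        k = len(q & members)
        rows.append((name, k, len(members), n, N, hypergeom_upper_tail(k, len(members), n, N)))
    table = pd.DataFrame(rows, columns=columns[:-1])
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table = table.sort_values(
        ["p_value", "k", "set_name"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return table


def rank_pathways(
    query_lists: Mapping[str, Iterable[str]],
    collection: GeneSetCollection,
) -> dict[str, pd.DataFrame]:
    """Ranked enrichment tables for several query lists (e.g. up / down /
    seed_containing), one table per list."""
    return {name: enrich_list(genes, collection) for name, genes in query_lists.items()}
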