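"""Overrepresentation analysis against gene-set collections.

One-sided hypergeometric upper-tail p-values (is the query enriched for the
set beyond chance, drawing without replacement from the universe) with BH
correction across the sets of one call.  The universe is the set of features
actually tested in the corresponding differential result, not the genome.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg
from .io import GeneSetCollection


def hypergeom_tail(k, big_n, big_k, n):
    """``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)`` (vectorized).

    The upper-tail probability used by :func:`ora` for every gene set.
    """
    return stats.hypergeom.sf(np.asarray(k) - 1, big_n, big_k, n)


@dataclasses.dataclass
class EnrichmentResult:
    table: pd.DataFrame  # set, k, K, n, N, p_hyper, fdr
    n_dropped_query: int
    status: str = "ok"


def ora(query: set[str], sets: GeneSetCollection, universe: set[str],
        direction: str = "pooled") -> EnrichmentResult:
    """Hypergeometric overrepresentation of ``query`` in each gene set.

    ``p = P(X >= k)`` with ``X ~ Hypergeometric(N, K, n)`` where N is the
    universe size, K the set size within the universe, n the query size
    within the universe and k the overlap.  Query genes outside the universe
    are dropped and counted.  ``direction`` is a context label carried into
    the result (callers may run up/down lists separately or pooled).
    """
    universe = set(universe)
    if not universe:
        return EnrichmentResult(pd.DataFrame(), 0, status="empty universe")
    query_in = set(query) & universe
    dropped = len(set(query)) - len(query_in)
    if not query_in:
        return EnrichmentResult(pd.DataFrame(), dropped, status="empty query")
    n = len(query_in)
    big_n = len(universe)
    records = []
    for name in sorted(sets.sets):
        genes = set(sets.sets[name]) & universe
        big_k = len(genes)
        if big_k == 0:
            continue
        k = len(genes & query_in)
        p = float(hypergeom_tail(k, big_n, big_k, n))
        records.append((name, k, big_k, n, big_n, min(max(p, 0.0), 1.0)))
    table = pd.DataFrame(
        records, columns=["set", "k", "K", "n", "N", "p_hyper"]
    )
    table["fdr"] = benjamini_hochberg(table["p_hyper"].to_numpy())
    table["direction"] = direction
    table = table.sort_values(["p_hyper", "set"], kind="stable").reset_index(
        drop=True)
    return EnrichmentResult(table, dropped)


def significant_sets(result: EnrichmentResult, max_fdr: float = 0.05
                     ) -> pd.DataFrame:
    """Sets passing the chosen FDR threshold (0.05 or the stricter 0.001)."""
    if result.status != "ok":
        return pd.DataFrame()
    return result.table[result.table["fdr"] < max_fdr].reset_index(drop=True)
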