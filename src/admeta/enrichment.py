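"""Hypergeometric over-representation analysis of gene sets.

Given a query (the significant meta-analysis genes), a GMT collection and
a background universe, each set is tested with the upper hypergeometric
tail P(X ≥ k) where k is the query/set overlap, K the set size and n the
query size within the universe of N genes. BH correction runs across the
tested sets; sets with adjusted p < 0.05 are called significant and the
ten smallest adjusted p-values form the headline view.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .types import GeneSetCollection

logger = logging.getLogger(__name__)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X ≥ k) of Hypergeometric(N, K, n).

    p = Σ_{i=k}^{min(K,n)} C(K,i)·C(N−K,n−i)/C(N,n); evaluated through
    the survival function, which works in log space internally.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_enrichment(
    query: set[str],
    sets: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
    min_set_size: int = 3,
    max_set_size: int = 1000,
) -> pd.DataFrame:
    """ORA of ``query`` against ``sets`` within ``universe``.

    Query symbols outside the universe are dropped (logged). Sets are
    restricted to the universe and kept when their restricted size lies in
    [min_set_size, max_set_size]. Output columns: set_id, N, K, n, k, p,
    p_adj, genes (pipe-separated overlap), sorted by (p_adj, p, set_id).
    """
    if not universe:
        raise ValueError("empty universe")
    dropped = len(query - universe)
    if dropped:
        logger.info("%d query symbols outside the universe dropped", dropped)
    query_in = query & universe
    if not query_in:
        raise ValueError("empty query after universe restriction")
    N = len(universe)
    n = len(query_in)
    rows = []
    for set_id in sorted(sets.sets):
        members = set(sets.sets[set_id]) & universe
        K = len(members)
        if K < max(1, min_set_size) or K > max_set_size:
            continue
        overlap = sorted(query_in & members)
        k = len(overlap)
        p = hypergeom_tail(N, K, n, k)
        rows.append((set_id, N, K, n, k, p, "|".join(overlap)))
    table = pd.DataFrame(rows, columns=["set_id", "N", "K", "n", "k", "p", "genes"])
    if table.empty:
        logger.warning("no gene set survived the universe/size restriction")
        table["p_adj"] = []
    else:
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table = table[["set_id", "N", "K", "n", "k", "p", "p_adj", "genes"]]
    return table.sort_values(["p_adj", "p", "set_id"], kind="mergesort").reset_index(drop=True)


def top_sets(result: pd.DataFrame, n_top: int = 10, alpha: float = 0.05) -> pd.DataFrame:
    """The top-``n_top`` significant sets (adjusted p < alpha)."""
    return result[result["p_adj"] < alpha].head(n_top)
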