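"""Interactome construction, degree-distribution fit, DIAMOnD, and hubs.

The protein–protein interaction network is induced from a STRING-style
edge table on the significant meta-analysis genes, keeping edges at or
above the high-confidence cutoff (0.9). Disease-module detection follows
the DIAMOnD iteration: starting from GWAS seed genes, the candidate whose
links into the current module are most hypergeometrically surprising is
added at each step. Module nodes with degree strictly above the 95th
percentile are reported as candidate pathogenic factors.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import DegreeFit, DiseaseModule

logger = logging.getLogger(__name__)


def build_ppin(edges: pd.DataFrame, members: set[str], cutoff: float = 0.9) -> nx.Graph:
    """Induce the high-confidence interactome on ``members``.

    Keeps rows with score ≥ ``cutoff`` (inclusive) and both endpoints in
    ``members``; isolated members are not added. Raises if nothing
    survives.
    """
    if not members:
        raise ValueError("empty member set")
    graph = nx.Graph()
    kept = edges[
        (edges["score"] >= cutoff)
        & edges["node_a"].isin(members)
        & edges["node_b"].isin(members)
    ]
    for row in kept.itertuples(index=False):
        if row.node_a == row.node_b:
            continue
        prev = graph.get_edge_data(row.node_a, row.node_b)
        score = max(row.score, prev["confidence"]) if prev else row.score
        graph.add_edge(row.node_a, row.node_b, confidence=float(score))
    if graph.number_of_edges() == 0:
        raise ValueError("no edges survive the confidence/membership filter")
    return graph


def fit_power_law(graph: nx.Graph) -> DegreeFit:
    """OLS fit of log10(count) on log10(degree) over the degree histogram.

    Returns the power law count ≈ C·degree^b with the regression R².
    Requires at least three distinct nonzero-count degree classes.
    """
    degrees = np.array([d for _, d in graph.degree() if d > 0])
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 3:
        raise ValueError("need >=3 distinct degree classes for the fit")
    x = np.log10(values.astype(float))
    y = np.log10(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    yhat = intercept + slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DegreeFit(coefficient=float(10.0**intercept), exponent=float(slope), r2=r2)


def diamond_connectivity_p(N: int, s0: int, k: int, k_s: int) -> float:
    """Connectivity p-value of a candidate with k links, k_s into the module.

    The hypergeometric tail of drawing the candidate's k neighbors from a
    graph of N nodes partitioned into s0 module and N−s0 non-module nodes
    (uniform DIAMOnD variant, seed weight α = 1):
    p = Σ_{i=k_s}^{min(k,s0)} C(s0,i)·C(N−s0,k−i)/C(N,k).
    """
    if not (0 <= k_s <= min(k, s0)) or s0 >= N or k > N:
        raise ValueError(f"inconsistent arguments N={N}, s0={s0}, k={k}, k_s={k_s}")
    if k_s == 0:
        return 1.0
    return float(stats.hypergeom.sf(k_s - 1, N, s0, k))


def diamond_expand(graph: nx.Graph, seeds, n_iter: int = 200) -> DiseaseModule:
    """Grow a disease module by iterative most-significant-connection.

    ``seeds`` is an iterable of symbols or a seed-gene table with a
    ``symbol`` column; seeds absent from the graph are dropped (logged).
    Each iteration scores every non-module node with ≥1 link to the module
    by its connectivity p at the current module size and adds the argmin;
    ties break by higher k_s, then lower k, then lexicographic symbol.
    Stops after ``n_iter`` additions or when no candidate remains.
    """
    if isinstance(seeds, pd.DataFrame):
        seeds = seeds["symbol"].tolist()
    seeds = set(seeds)
    present = seeds & set(graph.nodes)
    absent = len(seeds) - len(present)
    if absent:
        logger.info("%d seed genes absent from the graph dropped", absent)
    if not present:
        raise ValueError("no seed gene present in the graph")

    N = graph.number_of_nodes()
    module = set(present)
    # k_s bookkeeping: links from each boundary node into the module
    ks_count: dict[str, int] = {}
    for s in module:
        for nb in graph.neighbors(s):
            if nb not in module:
                ks_count[nb] = ks_count.get(nb, 0) + 1

    additions = []
    for it in range(1, n_iter + 1):
        if not ks_count:
            break
        s0 = len(module)
        best = None
        for node, k_s in ks_count.items():
            k = graph.degree(node)
            p = diamond_connectivity_p(N, s0, k, k_s)
            key = (p, -k_s, k, node)
            if best is None or key < best[0]:
                best = (key, node, p, k, k_s)
        _, node, p, k, k_s = best
        additions.append((node, it, p, k, k_s))
        module.add(node)
        del ks_count[node]
        for nb in graph.neighbors(node):
            if nb not in module:
                ks_count[nb] = ks_count.get(nb, 0) + 1

    table = pd.DataFrame(
        additions, columns=["symbol", "iteration", "connectivity_p", "k", "k_s"]
    )
    return DiseaseModule(seeds=present, additions=table)


def select_hubs(graph: nx.Graph, module: DiseaseModule, percentile: float = 95.0) -> pd.DataFrame:
    """High-degree nodes of the module-induced subgraph.

    The threshold is the empirical ``percentile`` (linear interpolation)
    of module-node degrees in the induced subgraph; nodes strictly above
    it are returned, sorted by degree descending then symbol. If no node
    exceeds the threshold (all degrees equal) the maximum-degree nodes are
    returned with ``degenerate=True``.
    """
    members = sorted(module.members & set(graph.nodes))
    if not members:
        raise ValueError("module has no node in the graph")
    sub = graph.subgraph(members)
    degrees = pd.Series({n: sub.degree(n) for n in members})
    threshold = float(np.percentile(degrees.to_numpy(), percentile))
    hubs = degrees[degrees > threshold]
    degenerate = hubs.empty
    if degenerate:
        hubs = degrees[degrees == degrees.max()]
    out = pd.DataFrame(
        {
            "symbol": hubs.index,
            "degree": hubs.to_numpy(),
            "is_seed": [s in module.seeds for s in hubs.index],
            "degenerate": degenerate,
        }
    )
    return out.sort_values(["degree", "symbol"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )
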