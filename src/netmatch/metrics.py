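"""Connectivity statistics: degree distribution, path length, clustering."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netgrow import Graph

__all__ = [
    "NetworkMetrics",
    "degree_distribution",
    "characteristic_path_length",
    "mean_local_clustering",
    "ccdf_slope",
    "compute_metrics",
]


@dataclass(frozen=True)
class NetworkMetrics:
    degree_counts: dict[int, int]
    ccdf: dict[int, float]
    char_path_length: float
    mean_clustering: float
    path_length_exact: bool

    def to_dict(self) -> dict:
        return {
            "degree_counts": {str(k): v for k, v in self.degree_counts.items()},
            "ccdf": {str(k): v for k, v in self.ccdf.items()},
            "char_path_length": self.char_path_length,
            "mean_clustering": self.mean_clustering,
            "path_length_exact": self.path_length_exact,
        }


def degree_distribution(graph: Graph) -> tuple[dict[int, int], dict[int, float]]:
    """Exact degree counts and the complementary CDF P(degree >= d)."""
    if graph.node_count == 0:
        raise ValueError("graph is empty")
    deg = graph.degrees()
    values, counts = np.unique(deg, return_counts=True)
    degree_counts = {int(v): int(c) for v, c in zip(values, counts)}
    # fraction of nodes with degree >= d, for each observed d
    tail = np.cumsum(counts[::-1])[::-1]
    ccdf = {int(v): float(t) / graph.node_count for v, t in zip(values, tail)}
    return degree_counts, ccdf


def characteristic_path_length(
    graph: Graph,
    max_exact_n: int = 2000,
    n_sources: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, bool]:
    """Mean shortest-path distance over distinct node pairs.

    Exact (all sources) when the graph has at most ``max_exact_n`` nodes;
    otherwise averaged over ``n_sources`` uniformly sampled sources and
    flagged as sampled.
    """
    n = graph.node_count
    if n < 2:
        raise ValueError("need at least 2 nodes")
    g = graph.to_networkx()
    if not nx.is_connected(g):
        raise ValueError("graph is disconnected; path length undefined")

    exact = n <= max_exact_n or n_sources >= n
    if exact:
        sources = range(n)
    else:
        if rng is None:
            rng = np.random.default_rng()
        sources = rng.choice(n, size=n_sources, replace=False)

    total = 0
    pairs = 0
    for s in sources:
        lengths = nx.single_source_shortest_path_length(g, int(s))
        total += sum(lengths.values())
        pairs += len(lengths) - 1  # exclude the source itself
    return total / pairs, exact


def mean_local_clustering(graph: Graph) -> float:
    """Mean over nodes of (edges among neighbours) / C(degree, 2).

    Nodes of degree < 2 contribute 0.
    """
    if graph.node_count == 0:
        raise ValueError("graph is empty")
    adj = graph.adjacency()
    total = 0.0
    for i in range(graph.node_count):
        nbrs = adj[i]
        k = len(nbrs)
        if k < 2:
            continue
        links = 0
        for u in nbrs:
            # count each neighbour pair once
            links += len(adj[u] & nbrs)
        total += links / (k * (k - 1))
    return total / graph.node_count


def ccdf_slope(
    ccdf: dict[int, float], d_min: int = 3, d_max: int = 100
) -> float:
    """Least-squares slope of log10(ccdf) against log10(degree) over a window.

    For a power-law degree density with exponent -g the CCDF slope is
    1 - g (so linear preferential attachment gives a slope near -2).
    """
    pts = [(d, f) for d, f in ccdf.items() if d_min <= d <= d_max and f > 0]
    if len(pts) < 3:
        raise ValueError("too few degrees in the window for a slope fit")
    x = np.log10([d for d, _ in pts])
    y = np.log10([f for _, f in pts])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def compute_metrics(
    graph: Graph,
    max_exact_n: int = 2000,
    n_sources: int = 1000,
    rng: np.random.Generator | None = None,
) -> NetworkMetrics:
    counts, ccdf = degree_distribution(graph)
    cpl, exact = characteristic_path_length(graph, max_exact_n, n_sources, rng)
    return NetworkMetrics(
        degree_counts=counts,
        ccdf=ccdf,
        char_path_length=cpl,
        mean_clustering=mean_local_clustering(graph),
        path_length_exact=exact,
    )
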