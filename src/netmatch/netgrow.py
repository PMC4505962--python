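"""Degree-softmax choice rule and the growing-network simulator.

A newcomer joining the network values each existing member by their degree
and selects whom to link to with probability proportional to ``degree**L``,
where the real-valued sensitivity ``L`` interpolates between antipreferential
attachment (``L < 0``), value-blind uniform choice (``L = 0``), classical
linear preferential attachment (``L = 1``), and winner-take-all behaviour
(``L >> 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
from scipy.special import logsumexp
from scipy.stats import truncnorm

__all__ = [
    "Graph",
    "AttachmentPolicy",
    "GrowthConfig",
    "choice_probabilities",
    "sample_attachments",
    "grow_network",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "read_graphml",
]


def _canonical_edge(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class Graph:
    """A simple undirected graph with nodes ``0 .. node_count - 1``.

    Node ids follow arrival order: in a grown graph, ids ``0 .. m`` are the
    seed clique and id ``k`` is the ``(k - m)``-th newcomer.
    """

    node_count: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.node_count < 0:
            raise ValueError("node_count must be non-negative")
        canon = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u}")
            if not (0 <= u < self.node_count and 0 <= v < self.node_count):
                raise ValueError(f"edge ({u}, {v}) references a missing node")
            canon.add(_canonical_edge(u, v))
        object.__setattr__(self, "edges", frozenset(canon))

    @classmethod
    def from_edges(cls, node_count: int, edges: Iterable[tuple[int, int]]) -> "Graph":
        return cls(node_count=node_count, edges=frozenset(_canonical_edge(u, v) for u, v in edges))

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.node_count, dtype=np.int64)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.node_count)]
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.node_count))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        nodes = sorted(g.nodes())
        relabel = {n: i for i, n in enumerate(nodes)}
        edges = frozenset(_canonical_edge(relabel[u], relabel[v]) for u, v in g.edges())
        return cls(node_count=len(nodes), edges=edges)


@dataclass(frozen=True)
class AttachmentPolicy:
    """Sensitivity policy for newcomers: a fixed L or a population Gaussian."""

    kind: Literal["fixed", "gaussian"]
    L: float = 0.0
    L_mean: float = 0.0
    L_sd: float = 0.0
    lo: float = -10.0
    hi: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "gaussian"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if not self.lo < self.hi:
            raise ValueError("truncation bounds must satisfy lo < hi")
        if self.L_sd < 0:
            raise ValueError("L_sd must be non-negative")
        if self.kind == "fixed" and not (self.lo <= self.L <= self.hi):
            raise ValueError("fixed L must lie within [lo, hi]")

    @classmethod
    def fixed(cls, L: float, lo: float = -10.0, hi: float = 10.0) -> "AttachmentPolicy":
        return cls(kind="fixed", L=L, lo=lo, hi=hi)

    @classmethod
    def gaussian(
        cls, L_mean: float, L_sd: float, lo: float = -10.0, hi: float = 10.0
    ) -> "AttachmentPolicy":
        return cls(kind="gaussian", L_mean=L_mean, L_sd=L_sd, lo=lo, hi=hi)

    def draw_L(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return self.L
        return draw_truncated_normal(rng, self.L_mean, self.L_sd, self.lo, self.hi)


@dataclass(frozen=True)
class GrowthConfig:
    m: int
    n_final: int
    policy: AttachmentPolicy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be a positive integer")
        if self.n_final < self.m + 1:
            raise ValueError("n_final must be at least m + 1")


def draw_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """One draw from Normal(mean, sd) truncated to [lo, hi], driven by ``rng``."""
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ValueError("degenerate truncated normal with mean outside bounds")
        return float(mean)
    # Rejection is cheap when the bounds cover most of the mass; fall back to
    # the inverse CDF when the acceptance region is narrow.
    for _ in range(64):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.ppf(rng.uniform(), a, b, loc=mean, scale=sd))


def choice_probabilities(
    degrees: Sequence[float] | np.ndarray,
    L: float,
    excluded: Iterable[int] = (),
) -> np.ndarray:
    """Softmax-in-log-degree choice distribution over non-excluded nodes.

    Probability of node ``i`` is ``degrees[i]**L`` normalised over the nodes
    not in ``excluded``; excluded nodes get probability exactly 0.  Computed
    as ``exp(L*log(degree) - max)`` so that large ``|L|`` and large degrees
    neither overflow nor underflow.
    """
    deg = np.asarray(degrees, dtype=float)
    if deg.ndim != 1 or deg.size == 0:
        raise ValueError("degrees must be a non-empty 1-D array")
    if np.any(deg <= 0):
        raise ValueError("all degrees must be positive")
    excluded = set(excluded)
    for i in excluded:
        if not (0 <= i < deg.size):
            raise ValueError(f"excluded id {i} out of range")
    if len(excluded) >= deg.size:
        raise ValueError("excluded must be a strict subset of the nodes")

    logw = L * np.log(deg)
    if excluded:
        mask = np.ones(deg.size, dtype=bool)
        mask[list(excluded)] = False
        logw = np.where(mask, logw, -np.inf)
    logw -= np.max(logw)
    p = np.exp(logw)
    return p / p.sum()


def _sample_from_degrees(
    degrees: np.ndarray, L: float, m: int, rng: np.random.Generator
) -> list[int]:
    """Sequentially draw m distinct node ids; degrees frozen across the draws."""
    n = degrees.size
    chosen: list[int] = []
    for _ in range(m):
        p = choice_probabilities(degrees, L, excluded=chosen)
        chosen.append(int(rng.choice(n, p=p)))
    return chosen


def sample_attachments(
    graph: Graph, L: float, m: int, rng: np.random.Generator
) -> set[int]:
    """Draw the m distinct nodes a newcomer with sensitivity L attaches to.

    Sampling is sequential without replacement: each draw renormalises the
    degree-softmax over the not-yet-chosen nodes, with all degrees taken at
    the newcomer's arrival (not updated between the m draws).
    """
    if m < 1:
        raise ValueError("m must be positive")
    if m > graph.node_count:
        raise ValueError("cannot attach to more nodes than the graph has")
    degrees = graph.degrees()
    if np.any(degrees < 1):
        raise ValueError("all existing nodes must have degree >= 1")
    return set(_sample_from_degrees(degrees.astype(float), L, m, rng))


def grow_network(config: GrowthConfig, rng: np.random.Generator | None = None) -> Graph:
    """Grow a network from a complete seed clique of m+1 nodes to n_final nodes.

    Each newcomer draws its own L from the policy (a fresh draw per newcomer
    for the gaussian kind, immediately before its attachment draws) and links
    to m existing nodes sampled sequentially without replacement from the
    degree-softmax distribution.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m, n_final = config.m, config.n_final

    edges: list[tuple[int, int]] = [
        (u, v) for u in range(m + 1) for v in range(u + 1, m + 1)
    ]
    degrees = np.zeros(n_final, dtype=float)
    degrees[: m + 1] = m

    for newcomer in range(m + 1, n_final):
        L = config.policy.draw_L(rng)
        targets = _sample_from_degrees(degrees[:newcomer], L, m, rng)
        for t in targets:
            edges.append(_canonical_edge(t, newcomer))
            degrees[t] += 1
        degrees[newcomer] = m

    return Graph.from_edges(n_final, edges)


# ---------------------------------------------------------------------------
# I/O: whitespace edge list with a "# nodes=<n>" header, and GraphML.

def write_edgelist(graph: Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# nodes={graph.node_count}\n")
        for u, v in sorted(graph.edges):
            fh.write(f"{u} {v}\n")


def read_edgelist(path) -> Graph:
    edges = []
    node_count = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "nodes=" in line:
                    node_count = int(line.split("nodes=")[1].split()[0])
                continue
            u, v = line.split()[:2]
            edges.append((int(u), int(v)))
    if node_count is None:
        node_count = max((max(u, v) for u, v in edges), default=-1) + 1
    return Graph.from_edges(node_count, edges)


def write_graphml(graph: Graph, path) -> None:
    nx.write_graphml(graph.to_networkx(), path)


def read_graphml(path) -> Graph:
    g = nx.read_graphml(path)
    return Graph.from_networkx(nx.relabel_nodes(g, {n: int(n) for n in g.nodes()}))
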