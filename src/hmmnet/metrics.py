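"""Topology and centrality metrics for the HMM similarity network.

Degree distribution and its log-log quadratic fit, density, connected
components with per-component density/diameter/mean distance, clique and
tree detection, global transitivity, Freeman (unnormalized) betweenness,
per-component normalized closeness, size-density rank correlation, and
top-k centrality tables.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np
from scipy import stats

from .network import HmmNetwork
from .scop import ScopClassification

__all__ = [
    "DegreeHistogram",
    "QuadraticFit",
    "ComponentSummary",
    "CentralityRecord",
    "CorrelationResult",
    "degree_histogram",
    "fit_loglog_quadratic",
    "density",
    "connected_components",
    "component_summary",
    "summarize_components",
    "count_tree_components",
    "betweenness",
    "closeness",
    "mean_distance",
    "diameter",
    "global_transitivity",
    "size_density_correlation",
    "centrality_records",
    "top_k",
]

GraphLike = Union[HmmNetwork, nx.Graph]


def _as_graph(network: GraphLike) -> nx.Graph:
    return network.graph if isinstance(network, HmmNetwork) else network


@dataclass(frozen=True)
class DegreeHistogram:
    """Counts of vertices per degree, with summary statistics."""

    counts: Mapping[int, int]
    min_degree: int
    max_degree: int
    mean_degree: float
    median_degree: float

    @property
    def n_vertices(self) -> int:
        return sum(self.counts.values())


def degree_histogram(network: GraphLike) -> DegreeHistogram:
    graph = _as_graph(network)
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot build a degree histogram of an empty network")
    degrees = [d for _, d in graph.degree()]
    counts: Dict[int, int] = {}
    for d in degrees:
        counts[d] = counts.get(d, 0) + 1
    return DegreeHistogram(
        counts=dict(sorted(counts.items())),
        min_degree=min(degrees),
        max_degree=max(degrees),
        mean_degree=2 * graph.number_of_edges() / graph.number_of_nodes(),
        median_degree=float(statistics.median(degrees)),
    )


@dataclass(frozen=True)
class QuadraticFit:
    """OLS quadratic y = c0 + c1 x + c2 x^2 on the log-log degree distribution.

    x = log2(degree), y = log2(vertex count), one point per observed degree.
    """

    c0: float
    c1: float
    c2: float
    log_base: int = 2
    n_points: int = 0

    def predict(self, x: float) -> float:
        return self.c0 + self.c1 * x + self.c2 * x * x


def fit_loglog_quadratic(hist: DegreeHistogram, use_frequencies: bool = False) -> QuadraticFit:
    """Least-squares quadratic fit to (log2 k, log2 N_k).

    With ``use_frequencies`` the y-axis is log2 of the relative frequency
    N_k / V instead of the raw count.
    """
    points = [(k, n) for k, n in hist.counts.items() if n > 0]
    if len(points) < 3:
        raise ValueError(
            f"quadratic fit needs >= 3 distinct degrees, got {len(points)}"
        )
    total = hist.n_vertices
    x = np.log2([k for k, _ in points])
    y = np.log2([n / total if use_frequencies else n for _, n in points])
    c2, c1, c0 = np.polyfit(x, y, 2)
    return QuadraticFit(c0=float(c0), c1=float(c1), c2=float(c2), n_points=len(points))


def density(vertex_count: int, edge_count: int) -> float:
    """Graph density 2E / (V(V-1)): observed edges over all possible edges."""
    if vertex_count < 2:
        raise ValueError(f"density undefined for fewer than 2 vertices ({vertex_count})")
    return 2.0 * edge_count / (vertex_count * (vertex_count - 1))


@dataclass(frozen=True)
class ComponentSummary:
    """Summary of one connected component (size >= 2)."""

    members: FrozenSet[str]
    size: int
    n_edges: int
    density: float
    diameter: int
    mean_distance: float
    is_clique: bool
    is_tree: bool


def connected_components(network: GraphLike) -> List[FrozenSet[str]]:
    """Vertex partition into connected components, largest first (ties by
    smallest member sid)."""
    graph = _as_graph(network)
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), min(map(str, c))))


def component_summary(network: GraphLike, members: Iterable[str]) -> ComponentSummary:
    graph = _as_graph(network)
    members = frozenset(members)
    sub = graph.subgraph(members)
    n, m = sub.number_of_nodes(), sub.number_of_edges()
    if n < 2 or not nx.is_connected(sub):
        raise ValueError("component_summary requires a connected vertex set of size >= 2")
    diam = nx.diameter(sub)
    return ComponentSummary(
        members=members,
        size=n,
        n_edges=m,
        density=density(n, m),
        diameter=diam,
        mean_distance=nx.average_shortest_path_length(sub),
        is_clique=m == n * (n - 1) // 2,
        is_tree=m == n - 1,
    )


def summarize_components(network: GraphLike) -> List[ComponentSummary]:
    graph = _as_graph(network)
    return [component_summary(graph, c) for c in connected_components(graph)]


def count_tree_components(network: GraphLike) -> int:
    """Number of components with exactly N vertices and N - 1 edges."""
    graph = _as_graph(network)
    count = 0
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if sub.number_of_edges() == sub.number_of_nodes() - 1:
            count += 1
    return count


def betweenness(network: GraphLike) -> Dict[str, float]:
    """Freeman betweenness: for each vertex a, the sum over unordered pairs
    {s, t} (s != t != a) of the fraction of s-t shortest paths through a.
    Unnormalized; vertices of a clique score 0."""
    graph = _as_graph(network)
    return dict(nx.betweenness_centrality(graph, normalized=False))


def closeness(component: GraphLike) -> Dict[str, float]:
    """Normalized closeness (n-1) / sum of shortest-path distances, defined
    only within a single connected component of size >= 2."""
    graph = _as_graph(component)
    if graph.number_of_nodes() < 2:
        raise ValueError("closeness requires a component of size >= 2")
    if not nx.is_connected(graph):
        raise ValueError("closeness is defined per connected component; input is disconnected")
    return {
        node: (graph.number_of_nodes() - 1) / sum(lengths.values())
        for node, lengths in (
            (n, nx.single_source_shortest_path_length(graph, n)) for n in graph.nodes
        )
    }


def _require_connected(component: GraphLike) -> nx.Graph:
    graph = _as_graph(component)
    if graph.number_of_nodes() < 2 or not nx.is_connected(graph):
        raise ValueError("requires a connected component of size >= 2")
    return graph


def mean_distance(component: GraphLike) -> float:
    """Mean shortest-path length over unordered vertex pairs of a component."""
    return nx.average_shortest_path_length(_require_connected(component))


def diameter(component: GraphLike) -> int:
    """Longest shortest path within a connected component."""
    return nx.diameter(_require_connected(component))


def global_transitivity(network: GraphLike) -> float:
    """3 x triangles / connected triples (0 when there are no triples)."""
    graph = _as_graph(network)
    if graph.number_of_nodes() == 0:
        raise ValueError("transitivity of an empty network is undefined")
    return nx.transitivity(graph)


@dataclass(frozen=True)
class CorrelationResult:
    """Kendall tau-b between component size and density (size > 2 only)."""

    tau: float
    p_value: float
    n: int


def size_density_correlation(
    summaries: Sequence[ComponentSummary], min_size: int = 3
) -> CorrelationResult:
    """Kendall rank correlation (tau-b, tie-corrected) of component size vs
    density over components of size > 2; two-sided p-value."""
    used = [s for s in summaries if s.size >= min_size]
    if len(used) < 3:
        raise ValueError(
            f"need >= 3 components of size >= {min_size}, got {len(used)}"
        )
    sizes = [s.size for s in used]
    dens = [s.density for s in used]
    res = stats.kendalltau(sizes, dens, variant="b")
    tau = 0.0 if math.isnan(res.statistic) else float(res.statistic)
    p = 1.0 if math.isnan(res.pvalue) else float(res.pvalue)
    return CorrelationResult(tau=tau, p_value=p, n=len(used))


@dataclass(frozen=True)
class CentralityRecord:
    """Per-vertex centralities; closeness is computed within the vertex's
    component (it has no whole-network definition here)."""

    sid: str
    sccs: Optional[ScopClassification]
    degree: int
    betweenness: float
    closeness: float


def centrality_records(network: GraphLike) -> List[CentralityRecord]:
    graph = _as_graph(network)
    btw = betweenness(graph)
    close: Dict[str, float] = {}
    for comp in nx.connected_components(graph):
        close.update(closeness(graph.subgraph(comp)))
    return [
        CentralityRecord(
            sid=str(n),
            sccs=graph.nodes[n].get("sccs"),
            degree=graph.degree(n),
            betweenness=btw[n],
            closeness=close[n],
        )
        for n in graph.nodes
    ]


def top_k(
    records: Sequence[CentralityRecord], metric: str, k: int = 20
) -> List[CentralityRecord]:
    """Top-k records by *metric* (``degree``, ``betweenness`` or
    ``closeness``), descending, ties broken by sid ascending."""
    if not records:
        raise ValueError("no centrality records to rank")
    if metric not in ("degree", "betweenness", "closeness"):
        raise ValueError(f"unknown centrality metric {metric!r}")
    ranked = sorted(records, key=lambda r: (-getattr(r, metric), r.sid))
    return ranked[:k]
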