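"""Independent brute-force oracles for graph metrics and rank correlation.

These deliberately avoid networkx/scipy algorithms: distances come from a
hand-rolled Floyd-Warshall, betweenness from explicit enumeration of every
shortest path, transitivity from triple counting, and Kendall's tau-b from
O(n^2) concordance counting with tie correction.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Dict, Hashable, List, Sequence

INF = math.inf


def adjacency(graph) -> Dict[Hashable, set]:
    adj = {v: set() for v in graph.nodes}
    for u, v in graph.edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def floyd_warshall(graph) -> Dict[Hashable, Dict[Hashable, float]]:
    nodes = list(graph.nodes)
    dist = {u: {v: (0 if u == v else INF) for v in nodes} for u in nodes}
    for u, v in graph.edges:
        dist[u][v] = dist[v][u] = 1
    for k in nodes:
        for i in nodes:
            dik = dist[i][k]
            if dik is INF:
                continue
            for j in nodes:
                if dik + dist[k][j] < dist[i][j]:
                    dist[i][j] = dik + dist[k][j]
    return dist


def brute_diameter(graph) -> int:
    dist = floyd_warshall(graph)
    return int(max(d for row in dist.values() for d in row.values()))


def brute_mean_distance(graph) -> float:
    dist = floyd_warshall(graph)
    nodes = list(graph.nodes)
    pair_d = [dist[u][v] for u, v in combinations(nodes, 2)]
    return sum(pair_d) / len(pair_d)


def brute_closeness(graph) -> Dict[Hashable, float]:
    dist = floyd_warshall(graph)
    n = len(dist)
    return {
        u: (n - 1) / sum(d for v, d in row.items() if v != u)
        for u, row in dist.items()
    }


def _all_shortest_paths(adj, dist_from, s, t) -> List[tuple]:
    """Every shortest s-t path, by DFS restricted to distance-increasing
    moves that stay on some shortest path."""
    target_len = dist_from[s][t]
    out: List[tuple] = []

    def extend(path):
        u = path[-1]
        if u == t:
            out.append(tuple(path))
            return
        for v in adj[u]:
            if (
                dist_from[s][v] == dist_from[s][u] + 1
                and dist_from[s][v] + dist_from[v][t] == target_len
            ):
                extend(path + [v])

    extend([s])
    return out


def brute_betweenness(graph) -> Dict[Hashable, float]:
    """Freeman betweenness over unordered pairs, endpoints excluded,
    unnormalized, by explicit enumeration of every shortest path."""
    adj = adjacency(graph)
    dist = floyd_warshall(graph)
    btw = {v: 0.0 for v in graph.nodes}
    for s, t in combinations(list(graph.nodes), 2):
        if dist[s][t] is INF:
            continue
        paths = _all_shortest_paths(adj, dist, s, t)
        for a in graph.nodes:
            if a in (s, t):
                continue
            through = sum(1 for p in paths if a in p)
            if through:
                btw[a] += through / len(paths)
    return btw


def brute_transitivity(graph) -> float:
    nodes = list(graph.nodes)
    adj = adjacency(graph)
    triangles = sum(
        1
        for a, b, c in combinations(nodes, 3)
        if b in adj[a] and c in adj[a] and c in adj[b]
    )
    triples = sum(len(adj[v]) * (len(adj[v]) - 1) // 2 for v in nodes)
    return 3.0 * triangles / triples if triples else 0.0


def brute_kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> float:
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i, j in combinations(range(n), 2):
        dx = (x[i] > x[j]) - (x[i] < x[j])
        dy = (y[i] > y[j]) - (y[i] < y[j])
        if dx == 0:
            ties_x += 1
        if dy == 0:
            ties_y += 1
        if dx * dy > 0:
            concordant += 1
        elif dx * dy < 0:
            discordant += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (concordant - discordant) / denom if denom else 0.0
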