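import networkx as nx
import pytest

from hmmnet.network import HmmNetwork, build_network
from hmmnet.similarity import Hit, SimilarityTable


def make_table(pairs, self_hits=()):
    """SimilarityTable from {(a, b): evalue} plus optional self-hit sids."""
    hits = [Hit(query=a, target=b, evalue=e) for (a, b), e in pairs.items()]
    hits += [Hit(query=s, target=s, evalue=1e-60) for s in self_hits]
    return SimilarityTable.from_hits(hits)


def labels_for(table, sccs_by_sid=None, default="a.1.1.1"):
    return {sid: (sccs_by_sid or {}).get(sid, default) for sid in table.universe}


def net_from_graph(graph: nx.Graph) -> HmmNetwork:
    """Wrap a bare graph as a network (for pure graph-metric tests)."""
    return HmmNetwork(graph=graph, cutoff=1.0, inclusive=False)


def random_graph_suite(n_graphs=200, max_n=12, seed=0):
    """Seeded connected-ish random graphs of up to max_n vertices."""
    import numpy as np

    rng = np.random.default_rng(seed)
    graphs = []
    while len(graphs) < n_graphs:
        n = int(rng.integers(4, max_n + 1))
        p = float(rng.uniform(0.15, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        g.remove_nodes_from([v for v, d in list(g.degree()) if d == 0])
        if g.number_of_nodes() >= 2:
            graphs.append(g)
    return graphs
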