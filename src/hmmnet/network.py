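"""Construction of the thresholded, undirected HMM similarity network.

An edge joins two HMMs when their symmetrized pairwise e-value passes the
cutoff (strictly below it by default).  Vertices left without any passing
edge — in particular models whose only hit is themselves — are dropped, so
every vertex of the resulting simple graph has degree at least one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import networkx as nx
import pandas as pd

from .scop import ScopClassification, parse_sccs
from .similarity import SimilarityTable

__all__ = ["HmmNetwork", "SweepResult", "MissingLabelError", "build_network", "threshold_sweep"]

LabelMap = Mapping[str, Union[ScopClassification, str]]


class MissingLabelError(KeyError):
    """A networked sid has no SCOP classification in the label map."""

    def __init__(self, missing: Sequence[str]):
        self.missing = sorted(missing)
        super().__init__(f"no sccs label for sids: {', '.join(self.missing)}")


@dataclass
class HmmNetwork:
    """A thresholded similarity network.

    ``graph`` is an undirected simple :class:`networkx.Graph`; nodes are sid
    strings carrying their ``sccs`` classification as an attribute, edges
    carry the symmetrized pair ``evalue``.  The network is analyzed
    unweighted; the e-value is retained for export only.
    """

    graph: nx.Graph
    cutoff: float
    inclusive: bool = False

    @property
    def vertices(self) -> List[str]:
        return list(self.graph.nodes)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def labels(self) -> Dict[str, ScopClassification]:
        return {n: d["sccs"] for n, d in self.graph.nodes(data=True) if "sccs" in d}


def _coerce_label(value: Union[ScopClassification, str]) -> ScopClassification:
    if isinstance(value, ScopClassification):
        return value
    return parse_sccs(str(value))


def _passes(evalue: float, cutoff: float, inclusive: bool) -> bool:
    return evalue <= cutoff if inclusive else evalue < cutoff


def build_network(
    table: SimilarityTable,
    labels: LabelMap,
    cutoff: float = 1e-3,
    inclusive: bool = False,
) -> HmmNetwork:
    """Threshold the pairwise e-values into an undirected network.

    Parameters
    ----------
    table:
        Symmetrized all-vs-all similarities.
    labels:
        sid -> sccs map; every sid that survives thresholding must be present.
    cutoff:
        E-value threshold (default 1e-3, the conventional profile-profile
        significance cutoff).
    inclusive:
        If true, an e-value exactly equal to the cutoff keeps its edge
        (``<=`` instead of the default strict ``<``).
    """
    if not cutoff > 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    graph = nx.Graph()
    for (a, b), e in table.pair_evalue.items():
        if _passes(e, cutoff, inclusive):
            graph.add_edge(a, b, evalue=e)
    missing = [n for n in graph.nodes if n not in labels]
    if missing:
        raise MissingLabelError(missing)
    for n in graph.nodes:
        graph.nodes[n]["sccs"] = _coerce_label(labels[n])
    return HmmNetwork(graph=graph, cutoff=cutoff, inclusive=inclusive)


@dataclass
class SweepResult:
    """Per-cutoff network statistics from an e-value threshold sweep.

    ``rows`` holds, per cutoff: vertex and edge counts, the number of
    connected components (all of size > 1, since isolated vertices are
    removed), the component-size distribution, and the sizes of the 20
    largest components.
    """

    cutoffs: Tuple[float, ...]
    rows: List[dict]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            records.append(
                {
                    "cutoff": row["cutoff"],
                    "n_vertices": row["n_vertices"],
                    "n_edges": row["n_edges"],
                    "n_components": row["n_components"],
                    "largest_cc": max(row["top_sizes"], default=0),
                    "top_sizes": ",".join(str(s) for s in row["top_sizes"]),
                }
            )
        return pd.DataFrame.from_records(records)


def threshold_sweep(
    table: SimilarityTable,
    labels: LabelMap,
    cutoffs: Sequence[float],
    inclusive: bool = False,
) -> SweepResult:
    """Build the network at each cutoff and record summary statistics.

    Cutoffs must be strictly monotone (ascending or descending).  Edge sets
    are nested across cutoffs: tightening the threshold never adds an edge.
    """
    cutoffs = tuple(cutoffs)
    if not cutoffs:
        raise ValueError("cutoff list is empty")
    if len(cutoffs) > 1:
        ascending = all(a < b for a, b in zip(cutoffs, cutoffs[1:]))
        descending = all(a > b for a, b in zip(cutoffs, cutoffs[1:]))
        if not (ascending or descending):
            raise ValueError("cutoffs must be strictly ascending or descending")
    rows = []
    for cutoff in cutoffs:
        net = build_network(table, labels, cutoff=cutoff, inclusive=inclusive)
        sizes = sorted((len(c) for c in nx.connected_components(net.graph)), reverse=True)
        rows.append(
            {
                "cutoff": cutoff,
                "n_vertices": net.n_vertices,
                "n_edges": net.n_edges,
                "n_components": len(sizes),
                "size_distribution": dict(Counter(sizes)),
                "top_sizes": sizes[:20],
                "network": net,
            }
        )
    return SweepResult(cutoffs=cutoffs, rows=rows)
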