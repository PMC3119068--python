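"""I/O for all-vs-all HMM comparison results and network exports.

The pipeline consumes directed (query, target, e-value) hits — either from a
plain 3-column TSV or from HHsearch ``.hhr`` result files — and symmetrizes
them into a map from unordered sid pairs to a single pairwise e-value.
HHsearch reports a query→target and a target→query e-value that generally
differ; by default the better (smaller) of the two is taken as the pair
similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Dict, FrozenSet, Iterable, List, Mapping, Sequence, Tuple

import networkx as nx

from .scop import ScopClassification, parse_sccs

__all__ = [
    "Hit",
    "SimilarityTable",
    "HitTableError",
    "HhrParseError",
    "read_hit_table",
    "write_hit_table",
    "read_hhr",
    "read_labels",
    "write_labels",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
]

Pair = Tuple[str, str]


class HitTableError(ValueError):
    """Malformed hit-table input; message carries the offending line number."""


class HhrParseError(ValueError):
    """Malformed HHsearch .hhr input."""


@dataclass(frozen=True)
class Hit:
    """One directed HHsearch hit: query model, target model, e-value."""

    query: str
    target: str
    evalue: float

    def __post_init__(self) -> None:
        if not self.query or not self.target:
            raise ValueError("query and target sids must be non-empty")
        if not (self.evalue >= 0.0):
            raise ValueError(f"e-value must be non-negative, got {self.evalue}")


def _pair(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class SimilarityTable:
    """Directed hits plus their symmetrized pairwise best-e-value map.

    ``pair_evalue`` maps each unordered pair of distinct sids to the combined
    e-value over both directions (minimum by default); self-hits appear in
    ``hits`` and ``universe`` but never in ``pair_evalue``.
    """

    hits: Tuple[Hit, ...]
    pair_evalue: Mapping[Pair, float]
    universe: FrozenSet[str]
    combine: str = "min"

    @classmethod
    def from_hits(cls, hits: Iterable[Hit], combine: str = "min") -> "SimilarityTable":
        """Build a table, collapsing duplicate directed hits to the smallest
        e-value and combining the two directions of each pair with *combine*
        (one of ``min``, ``max``, ``mean``)."""
        if combine not in ("min", "max", "mean"):
            raise ValueError(f"unknown direction-combining rule {combine!r}")
        hits = tuple(hits)
        directed: Dict[Tuple[str, str], float] = {}
        universe = set()
        for h in hits:
            universe.add(h.query)
            universe.add(h.target)
            key = (h.query, h.target)
            if key not in directed or h.evalue < directed[key]:
                directed[key] = h.evalue
        by_pair: Dict[Pair, List[float]] = {}
        for (q, t), e in directed.items():
            if q == t:
                continue
            by_pair.setdefault(_pair(q, t), []).append(e)
        reduce = {"min": min, "max": max, "mean": lambda v: sum(v) / len(v)}[combine]
        pair_evalue = {p: reduce(v) for p, v in by_pair.items()}
        return cls(
            hits=hits,
            pair_evalue=pair_evalue,
            universe=frozenset(universe),
            combine=combine,
        )


def read_hit_table(stream: IO[str], combine: str = "min") -> SimilarityTable:
    """Read a TSV hit table ``query<TAB>target<TAB>evalue`` (header required)."""
    hits: List[Hit] = []
    header_seen = False
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # first non-comment line is the header
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise HitTableError(
                f"line {lineno}: expected 3 tab-separated columns, got {len(parts)}"
            )
        query, target, etext = parts
        try:
            evalue = float(etext)
        except ValueError:
            raise HitTableError(
                f"line {lineno}: e-value {etext!r} is not a number"
            ) from None
        if not math.isfinite(evalue) or evalue < 0.0:
            raise HitTableError(f"line {lineno}: e-value {etext!r} is negative or non-finite")
        hits.append(Hit(query=query, target=target, evalue=evalue))
    if not header_seen:
        raise HitTableError("empty hit table (no header line)")
    return SimilarityTable.from_hits(hits, combine=combine)


def write_hit_table(hits: Iterable[Hit], stream: IO[str]) -> None:
    stream.write("query\ttarget\tevalue\n")
    for h in hits:
        stream.write(f"{h.query}\t{h.target}\t{h.evalue:.5e}\n")


def read_hhr(stream: IO[str]) -> List[Hit]:
    """Parse the header and hit-list summary of an HHsearch ``.hhr`` file.

    Only the query name and per-hit e-values are extracted; the pairwise
    alignment blocks that follow the summary table are ignored.
    """
    query = None
    lines = iter(stream)
    in_table = False
    for line in lines:
        if line.startswith("Query"):
            parts = line.split()
            if len(parts) < 2:
                raise HhrParseError("Query header line has no identifier")
            query = parts[1]
        if line.lstrip().startswith("No Hit"):
            in_table = True
            break
    if query is None or not in_table:
        raise HhrParseError("not a .hhr file: missing 'Query' header or hit list")
    hits: List[Hit] = []
    for line in lines:
        if not line.strip():
            break
        tokens = line.split()
        # Hit descriptions may contain spaces, so anchor the numeric columns
        # from the right: ... Prob E-value P-value Score SS Cols Query-HMM
        # Template-HMM (match_len).
        if tokens and tokens[-1].startswith("("):
            tokens = tokens[:-1]
        if len(tokens) < 10:
            raise HhrParseError(f"unparseable hit-list row: {line!r}")
        target = tokens[1]
        etext = tokens[-7]
        try:
            evalue = float(etext)
        except ValueError:
            raise HhrParseError(f"bad E-value field {etext!r} in row: {line!r}") from None
        hits.append(Hit(query=query, target=target, evalue=evalue))
    return hits


def read_labels(stream: IO[str]) -> Dict[str, ScopClassification]:
    """Read a 2-column TSV ``sid<TAB>sccs`` mapping (header required)."""
    labels: Dict[str, ScopClassification] = {}
    header_seen = False
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise HitTableError(
                f"line {lineno}: expected 2 tab-separated columns, got {len(parts)}"
            )
        labels[parts[0]] = parse_sccs(parts[1])
    return labels


def write_labels(labels: Mapping[str, ScopClassification], stream: IO[str]) -> None:
    stream.write("sid\tsccs\n")
    for sid in sorted(labels):
        stream.write(f"{sid}\t{labels[sid]}\n")


def write_edge_list(network, stream: IO[str]) -> None:
    """Write the network's edges as TSV ``sid1<TAB>sid2<TAB>evalue``,
    endpoints in lexicographic order, rows sorted."""
    graph = getattr(network, "graph", network)
    stream.write("sid1\tsid2\tevalue\n")
    rows = sorted(_pair(u, v) for u, v in graph.edges)
    for u, v in rows:
        e = graph.edges[u, v].get("evalue", float("nan"))
        stream.write(f"{u}\t{v}\t{e:.5e}\n")


def read_edge_list(stream: IO[str], combine: str = "min") -> SimilarityTable:
    """Read an edge-list TSV back into a SimilarityTable (same dialect as the
    hit table; edge lists are already symmetric so combining is a no-op)."""
    return read_hit_table(stream, combine=combine)


def write_graphml(network, path_or_handle) -> None:
    """Export the network as GraphML with node attributes ``sid``, ``sccs``,
    ``cls``, ``fold``, ``superfamily``, ``family`` and edge attribute
    ``evalue``.  *path_or_handle* is a filesystem path or a binary handle."""
    graph = getattr(network, "graph", network)
    out = nx.Graph()
    for node, data in graph.nodes(data=True):
        sccs = data.get("sccs")
        attrs = {"sid": str(node)}
        if sccs is not None:
            if not isinstance(sccs, ScopClassification):
                sccs = parse_sccs(str(sccs))
            attrs.update(
                sccs=str(sccs),
                cls=sccs.cls,
                fold=sccs.fold,
                superfamily=sccs.superfamily,
                family=sccs.family,
            )
        out.add_node(str(node), **attrs)
    for u, v, data in graph.edges(data=True):
        out.add_edge(str(u), str(v), evalue=float(data.get("evalue", float("nan"))))
    nx.write_graphml(out, path_or_handle)
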