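"""Network structure versus the SCOP hierarchy.

Three analyses: (i) a conservation census classifying every connected
component by the deepest hierarchy level shared by all its members;
(ii) pairwise ROC curves measuring, per hierarchy level and e-value
cutoff, how well "e-value below cutoff" predicts "same level in SCOP";
(iii) a per-superfamily dispersal index — over how many components the
superfamily's models are scattered, relative to how many models it has.
"""

from __future__ import annotations

import enum
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Collection, Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Union

from .metrics import connected_components
from .network import HmmNetwork, LabelMap, MissingLabelError, _coerce_label
from .scop import HierarchyLevel, ScopClassification, shared_level
from .similarity import SimilarityTable

__all__ = [
    "ConservationCategory",
    "CensusResult",
    "RocPoint",
    "DispersalRecord",
    "conservation_level",
    "conservation_census",
    "pairwise_confusion",
    "roc_curve",
    "dispersal_table",
]


class ConservationCategory(enum.Enum):
    """Deepest SCOP level conserved across all members of a component."""

    FAMILY_CONSERVED = "family_conserved"
    SUPERFAMILY_ONLY = "superfamily_only"
    FOLD_ONLY = "fold_only"
    CLASS_ONLY = "class_only"
    CROSS_CLASS = "cross_class"


_LEVEL_TO_CATEGORY = {
    HierarchyLevel.FAMILY: ConservationCategory.FAMILY_CONSERVED,
    HierarchyLevel.SUPERFAMILY: ConservationCategory.SUPERFAMILY_ONLY,
    HierarchyLevel.FOLD: ConservationCategory.FOLD_ONLY,
    HierarchyLevel.CLASS: ConservationCategory.CLASS_ONLY,
}


def _label_of(labels: Mapping, sid: str) -> ScopClassification:
    try:
        return _coerce_label(labels[sid])
    except KeyError:
        raise MissingLabelError([sid]) from None


def conservation_level(
    cc_members: Iterable[str], labels: LabelMap
) -> ConservationCategory:
    """Classify a component by the deepest level shared by all members.

    Because agreement is prefix-based, the deepest common level of a set
    equals the minimum pairwise shared level against any fixed member.
    """
    members = list(cc_members)
    if not members:
        raise ValueError("empty component")
    first = _label_of(labels, members[0])
    level: Optional[HierarchyLevel] = HierarchyLevel.FAMILY
    for sid in members[1:]:
        pair = shared_level(first, _label_of(labels, sid))
        if pair is None:
            return ConservationCategory.CROSS_CLASS
        if level is None or pair < level:
            level = pair
    return _LEVEL_TO_CATEGORY[level]


@dataclass(frozen=True)
class CensusResult:
    """Component counts per conservation category plus cumulative conserved
    proportions at each level (family; family+superfamily_only; ...)."""

    counts: Mapping[ConservationCategory, int]
    n_components: int

    def proportion_conserved(self, level: HierarchyLevel) -> float:
        """Fraction of components whose members all share *level* (counting
        components conserved at any deeper level too)."""
        if self.n_components == 0:
            raise ValueError("census of an empty network")
        order = [
            ConservationCategory.FAMILY_CONSERVED,
            ConservationCategory.SUPERFAMILY_ONLY,
            ConservationCategory.FOLD_ONLY,
            ConservationCategory.CLASS_ONLY,
        ]
        keep = order[: HierarchyLevel.FAMILY - level + 1]
        return sum(self.counts.get(c, 0) for c in keep) / self.n_components


def conservation_census(
    network: Union[HmmNetwork, Sequence[FrozenSet[str]]],
    labels: Optional[LabelMap] = None,
) -> CensusResult:
    """Census of all components of *network* (or an explicit component list).

    Labels default to the classifications stored on the network's nodes.
    """
    if isinstance(network, HmmNetwork):
        components: Sequence[Iterable[str]] = connected_components(network)
        if labels is None:
            labels = network.labels()
    else:
        components = network
        if labels is None:
            raise ValueError("labels are required when passing raw components")
    counts: Counter = Counter(
        conservation_level(c, labels) for c in components
    )
    return CensusResult(counts=dict(counts), n_components=len(components))


@dataclass(frozen=True)
class RocPoint:
    """Confusion counts for one (cutoff, level) over a fixed pair universe."""

    cutoff: float
    level: HierarchyLevel
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else 0.0


def pairwise_confusion(
    table: SimilarityTable,
    labels: LabelMap,
    cutoff: float,
    level: HierarchyLevel,
    universe: Collection[str],
    inclusive: bool = False,
) -> RocPoint:
    """Classify every unordered pair of *universe* at one cutoff and level.

    A pair is positive when SCOP places both sids in the same group at
    *level*; it is predicted positive when its symmetrized e-value is better
    (lower) than the cutoff.  Pairs with no reported hit count as worse than
    any cutoff.  Counting is done group-wise, never by materializing all
    O(n^2) pairs.
    """
    if not isinstance(level, HierarchyLevel):
        level = HierarchyLevel.from_label(str(level))
    sids = sorted(set(universe))
    n = len(sids)
    if n < 2:
        raise ValueError("pair universe needs at least two sids")
    prefix = {sid: _label_of(labels, sid).prefix(level) for sid in sids}
    total_pairs = n * (n - 1) // 2
    groups = Counter(prefix.values())
    positives = sum(g * (g - 1) // 2 for g in groups.values())

    in_universe = set(sids)
    predicted = tp = 0
    for (a, b), e in table.pair_evalue.items():
        if a not in in_universe or b not in in_universe:
            continue
        if (e <= cutoff) if inclusive else (e < cutoff):
            predicted += 1
            if prefix[a] == prefix[b]:
                tp += 1
    fp = predicted - tp
    fn = positives - tp
    tn = total_pairs - tp - fp - fn
    return RocPoint(cutoff=cutoff, level=level, tp=tp, fp=fp, fn=fn, tn=tn)


DEFAULT_ROC_CUTOFFS = tuple(10.0 ** -k for k in range(20, 2, -1))  # 1e-20 ... 1e-3


def roc_curve(
    table: SimilarityTable,
    labels: LabelMap,
    cutoffs: Sequence[float] = DEFAULT_ROC_CUTOFFS,
    levels: Sequence[HierarchyLevel] = tuple(HierarchyLevel),
    universe: Union[str, Collection[str]] = "networked",
    inclusive: bool = False,
) -> List[RocPoint]:
    """ROC points for each hierarchy level across a ladder of e-value cutoffs.

    The pair universe is fixed across cutoffs: ``"networked"`` (default) uses
    the sids with at least one pair passing the loosest cutoff in the ladder,
    ``"all-matched"`` uses every sid seen in the hit table (self-only models
    included), or pass an explicit sid collection.
    """
    cutoffs = sorted(set(cutoffs))
    if not cutoffs:
        raise ValueError("cutoff list is empty")
    if isinstance(universe, str):
        if universe == "networked":
            loosest = max(cutoffs)
            members = set()
            for (a, b), e in table.pair_evalue.items():
                if (e <= loosest) if inclusive else (e < loosest):
                    members.add(a)
                    members.add(b)
            universe = members
        elif universe == "all-matched":
            universe = set(table.universe)
        else:
            raise ValueError(f"unknown universe spec {universe!r}")
    points = []
    for level in levels:
        if not isinstance(level, HierarchyLevel):
            level = HierarchyLevel.from_label(str(level))
        for cutoff in cutoffs:
            points.append(
                pairwise_confusion(table, labels, cutoff, level, universe, inclusive)
            )
    return points


@dataclass(frozen=True)
class DispersalRecord:
    """How scattered one superfamily's models are across components."""

    superfamily: str
    n_hmms: int
    n_ccs: int

    @property
    def index(self) -> float:
        return self.n_ccs / self.n_hmms


def dispersal_table(
    network: HmmNetwork, labels: Optional[LabelMap] = None
) -> List[DispersalRecord]:
    """Per-superfamily dispersal over the networked models only.

    Sorted by model count descending (ties by superfamily id) to mirror the
    usual presentation; re-sort by ``n_ccs`` for the most-dispersed view.
    """
    if labels is None:
        labels = network.labels()
    components = connected_components(network)
    cc_of: Dict[str, int] = {}
    for i, comp in enumerate(components):
        for sid in comp:
            cc_of[sid] = i
    hmms: Dict[str, int] = defaultdict(int)
    ccs: Dict[str, set] = defaultdict(set)
    for sid in network.vertices:
        sf = _label_of(labels, sid).prefix(HierarchyLevel.SUPERFAMILY)
        hmms[sf] += 1
        ccs[sf].add(cc_of[sid])
    records = [
        DispersalRecord(superfamily=sf, n_hmms=hmms[sf], n_ccs=len(ccs[sf]))
        for sf in hmms
    ]
    return sorted(records, key=lambda r: (-r.n_hmms, r.superfamily))
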