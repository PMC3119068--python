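"""Synthetic HHsearch-like data over a planted SCOP-style hierarchy.

The generator plants a 4-level hierarchy (class / fold / superfamily /
family), then draws tiered all-vs-all e-values: pairs from the same family
score many orders of magnitude better than pairs from the same superfamily,
which score better than same-fold and unrelated pairs.  E-values are drawn
as 10^x with x Gaussian per tier, the two directions of each hit carry
independent log-scale jitter (emulating HHsearch's asymmetric query/target
e-values), every model hits itself, and a configurable fraction of models
hit nothing but themselves — exercising the isolated-model filtering step
of network construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np

from .scop import HierarchyLevel, HmmRecord, ScopClassification, parse_sid, shared_level
from .similarity import Hit, SimilarityTable

__all__ = [
    "UniverseConfig",
    "TierModel",
    "SimilarityConfig",
    "generate_universe",
    "generate_hits",
    "generate_random_graph",
]

CountSpec = Union[int, Tuple[int, int]]

_B36 = "0123456789abcdefghijklmnopqrstuvwxyz"


def _b36(i: int, width: int = 4) -> str:
    out = []
    for _ in range(width):
        out.append(_B36[i % 36])
        i //= 36
    return "".join(reversed(out))


def _draw(spec: CountSpec, rng: np.random.Generator) -> int:
    if isinstance(spec, int):
        n = spec
    else:
        lo, hi = spec
        if lo > hi:
            raise ValueError(f"bad count range {spec}")
        n = int(rng.integers(lo, hi + 1))
    if n < 1:
        raise ValueError(f"count spec must yield a positive number, got {n}")
    return n


@dataclass(frozen=True)
class UniverseConfig:
    """Shape of the planted hierarchy.  Each count may be a fixed integer or
    an inclusive (lo, hi) range drawn per parent for heterogeneity — real
    SCOP classes differ widely in fold and family counts."""

    n_classes: int = 3
    folds_per_class: CountSpec = (2, 4)
    superfamilies_per_fold: CountSpec = (1, 3)
    families_per_superfamily: CountSpec = (1, 3)
    hmms_per_family: CountSpec = (2, 6)
    seed: int = 0


def generate_universe(cfg: UniverseConfig) -> List[HmmRecord]:
    """Deterministically generate labeled models over the planted hierarchy.

    Sids are synthetic but grammatical ("d" + 4 base-36 chars + "a_"), so
    they round-trip through the sid parser like real SCOP identifiers.
    """
    if cfg.n_classes < 1 or cfg.n_classes > 7:
        raise ValueError("n_classes must be in 1..7 (SCOP classes a-g)")
    rng = np.random.default_rng(cfg.seed)
    records: List[HmmRecord] = []
    counter = 0
    for ci in range(cfg.n_classes):
        cls = "abcdefg"[ci]
        for fold in range(1, _draw(cfg.folds_per_class, rng) + 1):
            for sf in range(1, _draw(cfg.superfamilies_per_fold, rng) + 1):
                for fam in range(1, _draw(cfg.families_per_superfamily, rng) + 1):
                    sccs = ScopClassification(cls=cls, fold=fold, superfamily=sf, family=fam)
                    for _ in range(_draw(cfg.hmms_per_family, rng)):
                        sid = parse_sid(f"d{_b36(counter)}a_")
                        records.append(HmmRecord(sid=sid, sccs=sccs))
                        counter += 1
    return records


@dataclass(frozen=True)
class TierModel:
    """Log10 e-value distribution and hit probability for one relatedness tier."""

    mean: float
    sd: float
    hit_probability: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not 0.0 <= self.hit_probability <= 1.0:
            raise ValueError("hit probability must be in [0, 1]")


@dataclass(frozen=True)
class SimilarityConfig:
    """Tiered e-value model for all-vs-all synthetic hits.

    Defaults emulate the regime of profile-profile searches against a SCOP
    library at the conventional 1e-3 significance cutoff: same-family pairs
    are nearly always highly significant, same-superfamily pairs often so,
    same-fold pairs occasionally, unrelated pairs essentially never; about
    one model in eight matches nothing but itself.
    """

    same_family: TierModel = TierModel(mean=-28.0, sd=4.0, hit_probability=0.95)
    same_superfamily: TierModel = TierModel(mean=-10.0, sd=4.0, hit_probability=0.05)
    same_fold: TierModel = TierModel(mean=-2.0, sd=2.0, hit_probability=0.005)
    unrelated: TierModel = TierModel(mean=1.5, sd=1.5, hit_probability=0.002)
    asymmetry_sd: float = 0.3
    self_only_fraction: float = 0.12
    self_evalue: float = 1e-60

    def __post_init__(self) -> None:
        means = (
            self.same_family.mean,
            self.same_superfamily.mean,
            self.same_fold.mean,
            self.unrelated.mean,
        )
        if not all(a < b for a, b in zip(means, means[1:])):
            raise ValueError(
                "tier log10 e-value means must be strictly ordered "
                "same_family < same_superfamily < same_fold < unrelated"
            )
        if not 0.0 <= self.self_only_fraction < 1.0:
            raise ValueError("self_only_fraction must be in [0, 1)")
        if self.asymmetry_sd < 0:
            raise ValueError("asymmetry_sd must be non-negative")

    @classmethod
    def tier_separated(cls) -> "SimilarityConfig":
        """A fully separated regime: same-family pairs always score far below
        1e-3, all other tiers score above it (or never hit).  Every component
        of the resulting 1e-3 network is family-conserved by construction."""
        return cls(
            same_family=TierModel(mean=-10.0, sd=1.0, hit_probability=1.0),
            same_superfamily=TierModel(mean=2.0, sd=0.5, hit_probability=0.5),
            same_fold=TierModel(mean=3.0, sd=0.5, hit_probability=0.2),
            unrelated=TierModel(mean=4.0, sd=0.5, hit_probability=0.0),
            asymmetry_sd=0.1,
            self_only_fraction=0.1,
        )


_TIER_BY_LEVEL = {
    HierarchyLevel.FAMILY: "same_family",
    HierarchyLevel.SUPERFAMILY: "same_superfamily",
    HierarchyLevel.FOLD: "same_fold",
}


def generate_hits(
    universe: Sequence[HmmRecord],
    cfg: SimilarityConfig = SimilarityConfig(),
    seed: int = 0,
) -> SimilarityTable:
    """Draw directed all-vs-all hits over *universe* under the tier model.

    For each unordered pair the tier follows from the planted labels; with
    the tier's hit probability both directed hits are emitted, sharing one
    base log10 e-value plus independent asymmetry jitter.  Designated
    self-only models receive nothing but their self-hit.  Pure function of
    (universe, cfg, seed).
    """
    rng = np.random.default_rng(seed)
    sids = [str(r.sid) for r in universe]
    if len(set(sids)) != len(sids):
        raise ValueError("duplicate sids in universe")
    labels = {str(r.sid): r.sccs for r in universe}
    n_self_only = int(round(cfg.self_only_fraction * len(sids)))
    self_only = set(
        rng.choice(sids, size=n_self_only, replace=False)
    ) if n_self_only else set()

    hits: List[Hit] = [Hit(query=s, target=s, evalue=cfg.self_evalue) for s in sids]
    for i in range(len(sids)):
        a = sids[i]
        for j in range(i + 1, len(sids)):
            b = sids[j]
            if a in self_only or b in self_only:
                continue
            level = shared_level(labels[a], labels[b])
            tier: TierModel = getattr(cfg, _TIER_BY_LEVEL.get(level, "unrelated"))
            if rng.random() >= tier.hit_probability:
                continue
            base = rng.normal(tier.mean, tier.sd)
            e_ab = 10.0 ** (base + rng.normal(0.0, cfg.asymmetry_sd))
            e_ba = 10.0 ** (base + rng.normal(0.0, cfg.asymmetry_sd))
            hits.append(Hit(query=a, target=b, evalue=e_ab))
            hits.append(Hit(query=b, target=a, evalue=e_ba))
    return SimilarityTable.from_hits(hits)


def generate_random_graph(n: int, edge_probability: float, seed: int = 0) -> nx.Graph:
    """Erdos-Renyi G(n, p) fixture with isolated vertices dropped.

    Returned unlabeled, for exercising pure graph metrics against oracles.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= edge_probability <= 1.0:
        raise ValueError("edge probability must be in [0, 1]")
    graph = nx.gnp_random_graph(n, edge_probability, seed=int(seed))
    graph.remove_nodes_from([v for v, d in list(graph.degree()) if d == 0])
    return graph
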