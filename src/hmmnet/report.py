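"""Tabular report builders: each function turns analysis results into a
pandas DataFrame with a fixed column order, shared by the pipeline and the
per-stage CLI commands so that staged and monolithic runs emit identical
tables."""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .hierarchy import (
    CensusResult,
    ConservationCategory,
    DispersalRecord,
    RocPoint,
    conservation_census,
)
from .metrics import (
    CentralityRecord,
    DegreeHistogram,
    centrality_records,
    count_tree_components,
    degree_histogram,
    density,
    fit_loglog_quadratic,
    global_transitivity,
    size_density_correlation,
    summarize_components,
    top_k,
)
from .network import HmmNetwork, LabelMap
from .nullmodel import NullModelSummary
from .scop import HierarchyLevel

__all__ = [
    "degree_histogram_frame",
    "quadratic_fit_frame",
    "components_frame",
    "network_summary_frame",
    "centrality_frame",
    "top_k_frame",
    "census_frame",
    "dispersal_frame",
    "roc_frame",
    "null_summary_frame",
    "null_replicates_frame",
]

log = logging.getLogger("hmmnet")


def degree_histogram_frame(hist: DegreeHistogram) -> pd.DataFrame:
    return pd.DataFrame(
        {"degree": list(hist.counts), "n_vertices": list(hist.counts.values())}
    )


def quadratic_fit_frame(hist: DegreeHistogram) -> Optional[pd.DataFrame]:
    """None when the fit is underdetermined (< 3 distinct degrees)."""
    try:
        fit = fit_loglog_quadratic(hist)
    except ValueError as exc:
        log.warning("log-log quadratic fit skipped: %s", exc)
        return None
    return pd.DataFrame(
        [{"c0": fit.c0, "c1": fit.c1, "c2": fit.c2, "log_base": fit.log_base, "n_points": fit.n_points}]
    )


def components_frame(net: HmmNetwork, labels: Optional[LabelMap] = None) -> pd.DataFrame:
    if labels is None:
        labels = net.labels()
    rows = []
    for rank, s in enumerate(summarize_components(net), start=1):
        census = conservation_census([s.members], labels)
        (category,) = census.counts
        rows.append(
            {
                "rank": rank,
                "size": s.size,
                "n_edges": s.n_edges,
                "density": s.density,
                "diameter": s.diameter,
                "mean_distance": s.mean_distance,
                "is_clique": s.is_clique,
                "is_tree": s.is_tree,
                "category": category.value,
            }
        )
    return pd.DataFrame(rows)


def network_summary_frame(net: HmmNetwork) -> pd.DataFrame:
    summaries = summarize_components(net)
    hist = degree_histogram(net)
    try:
        corr = size_density_correlation(summaries)
        tau, p, n_used = corr.tau, corr.p_value, corr.n
    except ValueError:
        tau, p, n_used = float("nan"), float("nan"), 0
    return pd.DataFrame(
        [
            {
                "n_vertices": net.n_vertices,
                "n_edges": net.n_edges,
                "density": density(net.n_vertices, net.n_edges),
                "transitivity": global_transitivity(net),
                "n_components": len(summaries),
                "n_cliques": sum(1 for s in summaries if s.is_clique),
                "n_trees": count_tree_components(net),
                "mean_degree": hist.mean_degree,
                "median_degree": hist.median_degree,
                "max_degree": hist.max_degree,
                "size_density_tau": tau,
                "size_density_p": p,
                "size_density_n": n_used,
            }
        ]
    )


def centrality_frame(records: Sequence[CentralityRecord]) -> pd.DataFrame:
    return (
        pd.DataFrame(
            {
                "sid": [r.sid for r in records],
                "sccs": [str(r.sccs) for r in records],
                "degree": [r.degree for r in records],
                "betweenness": [r.betweenness for r in records],
                "closeness": [r.closeness for r in records],
            }
        )
        .sort_values("sid")
        .reset_index(drop=True)
    )


def top_k_frame(records: Sequence[CentralityRecord], metric: str, k: int) -> pd.DataFrame:
    top = top_k(records, metric, k)
    return pd.DataFrame(
        {
            "rank": range(1, len(top) + 1),
            "sid": [r.sid for r in top],
            "sccs": [str(r.sccs) for r in top],
            metric: [getattr(r, metric) for r in top],
        }
    )


def census_frame(census: CensusResult) -> pd.DataFrame:
    rows: List[dict] = [
        {"category": cat.value, "value": census.counts.get(cat, 0)}
        for cat in ConservationCategory
    ]
    rows.append({"category": "n_components", "value": census.n_components})
    for level in HierarchyLevel:
        rows.append(
            {
                "category": f"proportion_conserved_{level.label}",
                "value": census.proportion_conserved(level),
            }
        )
    return pd.DataFrame(rows)


def dispersal_frame(records: Sequence[DispersalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "superfamily": [d.superfamily for d in records],
            "n_hmms": [d.n_hmms for d in records],
            "n_ccs": [d.n_ccs for d in records],
            "index": [d.index for d in records],
        }
    )


def roc_frame(points: Sequence[RocPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "level": [p.level.label for p in points],
            "cutoff": [p.cutoff for p in points],
            "TP": [p.tp for p in points],
            "FP": [p.fp for p in points],
            "FN": [p.fn for p in points],
            "TN": [p.tn for p in points],
            "TPR": [p.tpr for p in points],
            "FPR": [p.fpr for p in points],
        }
    )


def null_summary_frame(summary: NullModelSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "level": summary.level.label,
                "scheme": summary.scheme,
                "n_reps": summary.n_reps,
                "observed_proportion": summary.observed_proportion,
                "null_max": summary.null_max,
                "null_mean": summary.null_mean,
                "empirical_p": summary.empirical_p,
                "seed": summary.seed,
            }
        ]
    )


def null_replicates_frame(summary: NullModelSummary) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "replicate": range(1, summary.n_reps + 1),
            "proportion": summary.null_proportions,
        }
    )
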