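"""End-to-end orchestration: from a hit table (or synthetic data) to the
full bundle of network, metric, hierarchy, ROC, dispersal, and null-model
reports, each written as TSV with a provenance header."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from . import report as rpt
from .hierarchy import conservation_census, dispersal_table, roc_curve
from .metrics import centrality_records, degree_histogram
from .network import build_network, threshold_sweep
from .nullmodel import null_distribution
from .scop import HierarchyLevel
from .similarity import (
    SimilarityTable,
    read_hhr,
    read_hit_table,
    read_labels,
    write_edge_list,
    write_graphml,
    write_hit_table,
    write_labels,
)
from .simulate import SimilarityConfig, UniverseConfig, generate_hits, generate_universe

__all__ = ["PipelineConfig", "run_pipeline", "provenance_line", "write_table"]

log = logging.getLogger("hmmnet")

DEFAULT_SWEEP = tuple(10.0 ** -k for k in range(20, 2, -1))  # 1e-20 ... 1e-3


@dataclass
class PipelineConfig:
    """Flat, serializable parameter record for one analysis run.

    Exactly one input source: either ``hits_path``/``hhr_dir`` together with
    ``labels_path``, or ``synthetic=True``.
    """

    hits_path: Optional[str] = None
    hhr_dir: Optional[str] = None
    labels_path: Optional[str] = None
    synthetic: bool = False
    seed: int = 0
    cutoff: float = 1e-3
    inclusive: bool = False
    sweep_cutoffs: Sequence[float] = DEFAULT_SWEEP
    roc_levels: Sequence[str] = ("family", "superfamily", "fold", "class")
    roc_universe: str = "networked"
    null_scheme: str = "label_permutation"
    null_reps: int = 10_000
    null_level: str = "family"
    top_k: int = 20
    outdir: str = "hmmnet_out"

    def __post_init__(self) -> None:
        file_input = self.hits_path is not None or self.hhr_dir is not None
        if file_input == self.synthetic:
            raise ValueError(
                "exactly one input source required: hits_path/hhr_dir or synthetic=True"
            )
        if file_input and self.labels_path is None:
            raise ValueError("file input requires labels_path")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.null_reps < 1:
            raise ValueError("null_reps must be >= 1")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping of flat keys")
        return cls(**data)

    def digest(self) -> str:
        # outdir is excluded: it does not affect the analysis
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self).items()
            if k != "outdir"
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def provenance_line(config_hash: str, seed: int) -> str:
    return f"# hmmnet {__version__} seed={seed} config={config_hash}\n"


def write_table(df: pd.DataFrame, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def _load_inputs(config: PipelineConfig):
    if config.synthetic:
        universe = generate_universe(UniverseConfig(seed=config.seed))
        table = generate_hits(universe, SimilarityConfig(), seed=config.seed + 1)
        labels = {str(r.sid): r.sccs for r in universe}
        return table, labels
    if config.hits_path:
        with open(config.hits_path) as fh:
            table = read_hit_table(fh)
    else:
        hits = []
        hhr_files = sorted(Path(config.hhr_dir).glob("*.hhr"))
        if not hhr_files:
            raise FileNotFoundError(f"no .hhr files under {config.hhr_dir}")
        for f in hhr_files:
            with open(f) as fh:
                hits.extend(read_hhr(fh))
        table = SimilarityTable.from_hits(hits)
    with open(config.labels_path) as fh:
        labels = read_labels(fh)
    return table, labels


class _Stage:
    """Context manager logging stage timing and renaming failures."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            log.error("stage %s: failed: %s", self.name, exc)
            raise RuntimeError(f"stage {self.name} failed: {exc}") from exc
        log.info("stage %s: done in %.2fs", self.name, time.perf_counter() - self.t0)
        return False


def run_pipeline(config: PipelineConfig) -> Dict[str, Path]:
    """Run every analysis stage and write the report bundle to ``outdir``.

    Returns a mapping from artifact name to file path.  Any stage failure
    raises ``RuntimeError`` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = provenance_line(config.digest(), config.seed)
    artifacts: Dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, filename: str) -> None:
        path = outdir / filename
        write_table(df, path, header)
        artifacts[name] = path

    with _Stage("load"):
        table, labels = _load_inputs(config)
        if config.synthetic:
            with open(outdir / "hits.tsv", "w") as fh:
                fh.write(header)
                write_hit_table(table.hits, fh)
            artifacts["hits"] = outdir / "hits.tsv"
            with open(outdir / "labels.tsv", "w") as fh:
                fh.write(header)
                write_labels(labels, fh)
            artifacts["labels"] = outdir / "labels.tsv"

    with _Stage("build"):
        net = build_network(table, labels, cutoff=config.cutoff, inclusive=config.inclusive)

    with _Stage("export"):
        with open(outdir / "edges.tsv", "w") as fh:
            fh.write(header)
            write_edge_list(net, fh)
        artifacts["edges"] = outdir / "edges.tsv"
        write_graphml(net, str(outdir / "network.graphml"))
        artifacts["graphml"] = outdir / "network.graphml"

    with _Stage("metrics"):
        hist = degree_histogram(net)
        emit("degree_histogram", rpt.degree_histogram_frame(hist), "degree_histogram.tsv")
        fit = rpt.quadratic_fit_frame(hist)
        if fit is not None:
            emit("quadratic_fit", fit, "quadratic_fit.tsv")
        emit("components", rpt.components_frame(net, labels), "components.tsv")
        emit("network_summary", rpt.network_summary_frame(net), "network_summary.tsv")
        records = centrality_records(net)
        emit("centrality", rpt.centrality_frame(records), "centrality.tsv")
        for metric in ("degree", "betweenness"):
            emit(
                f"top_{metric}",
                rpt.top_k_frame(records, metric, config.top_k),
                f"top20_{metric}.tsv",
            )

    with _Stage("sweep"):
        sweep = threshold_sweep(table, labels, config.sweep_cutoffs, config.inclusive)
        emit("sweep", sweep.to_frame(), "sweep.tsv")

    with _Stage("hierarchy"):
        census = conservation_census(net, labels)
        emit("census", rpt.census_frame(census), "census.tsv")
        emit("dispersal", rpt.dispersal_frame(dispersal_table(net, labels)), "dispersal.tsv")

    with _Stage("roc"):
        points = roc_curve(
            table,
            labels,
            cutoffs=config.sweep_cutoffs,
            levels=[HierarchyLevel.from_label(l) for l in config.roc_levels],
            universe=config.roc_universe,
            inclusive=config.inclusive,
        )
        emit("roc", rpt.roc_frame(points), "roc.tsv")

    with _Stage("null"):
        summary = null_distribution(
            net,
            labels,
            level=HierarchyLevel.from_label(config.null_level),
            n_reps=config.null_reps,
            seed=config.seed,
            scheme=config.null_scheme,
        )
        emit("null_summary", rpt.null_summary_frame(summary), "null_summary.tsv")
        emit("null_replicates", rpt.null_replicates_frame(summary), "null_replicates.tsv")

    log.info("pipeline complete: %d artifacts in %s", len(artifacts), outdir)
    return artifacts
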