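"""One-call orchestration: simulate (or ingest) -> score -> differential ->
filter -> cluster -> report, with a single master seed and a run manifest.

All outputs are TSV plus one JSON manifest; re-running with the same config
and seed reproduces every output file byte for byte (the manifest carries no
timestamps by design).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import default_library
from .differential import DEFAULT_DEGREE, DEFAULT_SPAN, DifferentialTable, differential_scores
from .hits import (
    ClusterResult,
    Thresholds,
    apply_filters,
    consensus_hits,
    heatmap_matrix,
    hierarchical_cluster,
)
from .io import ScreenDataset, flatten_score_columns, read_screen, write_screen, write_table
from .normalize import ScoreTable, qc_report, score_dataset
from .simulate import SimConfig, SimulationTruth, generate_screen, generate_truth

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one input source (files or simulation)."""

    sim: SimConfig | None = field(default_factory=SimConfig)
    plate_list: str | None = None
    annotation: str | None = None
    n_genes: int = 520
    summarize: str = "mean"
    method: str = "loess_residual"
    span: float = DEFAULT_SPAN
    degree: int = DEFAULT_DEGREE
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_abs_d: float = 0.5
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "complete"
    n_clusters: int = 4
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        from_files = self.plate_list is not None or self.annotation is not None
        if from_files and self.sim is not None:
            raise PipelineConfigError(
                "config names both input files and a simulation; choose one"
            )
        if not from_files and self.sim is None:
            raise PipelineConfigError("config names no input source")
        if from_files and (self.plate_list is None or self.annotation is None):
            raise PipelineConfigError("file input needs both plate_list and annotation")
        self.thresholds.validate()
        if self.sim is not None:
            self.sim.validate()
        return self

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if d.get("sim") is not None:
            sim = dict(d["sim"])
            for key in ("suppressor_effect", "activator_effect", "lethal_effect",
                        "proviability_effect", "screens"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            d["sim"] = SimConfig(**sim)
        if d.get("thresholds") is not None:
            d["thresholds"] = Thresholds(**d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    dataset: ScreenDataset
    truth: SimulationTruth | None
    score_table: ScoreTable
    differential: DifferentialTable
    hit_table: pd.DataFrame
    cluster: ClusterResult
    qc: pd.DataFrame
    manifest: dict[str, Any]


def _child_seeds(master: int, n: int) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(master).generate_state(n)]


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage; optionally write all outputs under ``outdir``."""
    config.validate()
    truth: SimulationTruth | None = None
    if config.sim is not None:
        truth_seed, screen_seed = _child_seeds(config.seed, 2)
        library = default_library(config.n_genes)
        truth = generate_truth(library, config.sim, seed=truth_seed)
        dataset = generate_screen(library, truth, config.sim, seed=screen_seed)
        logger.info("simulated %d wells for %d genes", len(dataset.wells), library.n_genes)
    else:
        dataset = read_screen(config.plate_list, config.annotation)
        logger.info("read %d wells from %s", len(dataset.wells), config.plate_list)

    score_table = score_dataset(dataset, summarize=config.summarize)
    qc = qc_report(score_table)
    logger.info("scored %d genes in %d screen/conditions",
                score_table.scores.shape[0], score_table.scores.shape[1])

    diff = differential_scores(
        score_table, method=config.method, span=config.span, degree=config.degree
    )
    logger.info("differential scores for %d genes x %d screens",
                diff.d.shape[0], diff.d.shape[1])

    ctg_cols = [c for c in score_table.scores.columns if c[1] == "ctg"]
    if not ctg_cols:
        raise PipelineConfigError("no ATP-readout (ctg) screen in the dataset")
    ctg = score_table.scores[ctg_cols[0]]

    hit_table = apply_filters(score_table, diff, ctg, config.thresholds)
    hit_table = consensus_hits(hit_table, diff, min_abs_d=config.min_abs_d)

    cluster = hierarchical_cluster(
        diff.d,
        metric=config.cluster_metric,
        method=config.cluster_linkage,
        n_clusters=config.n_clusters,
    )
    hit_table["cluster_id"] = cluster.labels.reindex(hit_table.index).astype("Int64")

    manifest = {
        "package": "ctlscreen",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_genes": int(score_table.scores.shape[0]),
        "n_wells": int(len(dataset.wells)),
        "n_survivors": int(
            (~hit_table["viability_excluded"]
             & hit_table["effect_pass"]
             & ~hit_table["ctg_excluded"]).sum()
        ),
        "n_classified": int((hit_table["hit_class"] != "none").sum()),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }

    result = PipelineResult(dataset, truth, score_table, diff, hit_table, cluster, qc, manifest)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    st = result.score_table
    write_table(flatten_score_columns(st.scores).rename_axis("gene_id"),
                outdir / "score_table.tsv")
    write_table(flatten_score_columns(st.replicate_scores).rename_axis("gene_id"),
                outdir / "replicate_scores.tsv")
    write_table(st.control_scores, outdir / "control_scores.tsv", index=False)
    write_table(result.qc, outdir / "qc_report.tsv", index=False)

    diff_path = outdir / "differential_scores.tsv"
    with open(diff_path, "w") as fh:
        fh.write(
            f"# method={result.differential.method} "
            f"span={result.differential.span:.6g} degree={result.differential.degree}\n"
        )
        result.differential.d.to_csv(fh, sep="\t", float_format="%.10g")
    write_table(result.hit_table, outdir / "hit_table.tsv")
    write_table(heatmap_matrix(result.differential, result.cluster),
                outdir / "heatmap_matrix.tsv")
    if result.truth is not None:
        result.truth.write(outdir / "truth.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, sort_keys=True, indent=2, default=str)
        fh.write("\n")
    return outdir


def simulate_to_dir(config: PipelineConfig, outdir: str | Path) -> Path:
    """Write a complete on-disk fixture (plates, annotation, truth, config)."""
    config.validate()
    if config.sim is None:
        raise PipelineConfigError("simulate needs a simulation config")
    truth_seed, screen_seed = _child_seeds(config.seed, 2)
    library = default_library(config.n_genes)
    truth = generate_truth(library, config.sim, seed=truth_seed)
    dataset = generate_screen(library, truth, config.sim, seed=screen_seed)
    outdir = Path(outdir)
    write_screen(dataset, outdir)
    truth.write(outdir / "truth.tsv")
    config.to_yaml(outdir / "config.yaml")
    return outdir


# ---------------------------------------------------------------------------
# recovery metrics against simulation truth

def recovery_metrics(hit_table: pd.DataFrame, truth: SimulationTruth) -> dict[str, float]:
    """Sensitivity / false-discovery proportion of consensus classification.

    A planted suppressor counts as recovered when classified
    ``suppressor_candidate`` (symmetrically for activators); every classified
    gene whose planted class does not match is a false discovery.
    """
    cls = truth.table["class_label"].reindex(hit_table.index)
    pred = hit_table["hit_class"]
    tp = (
        ((cls == "suppressor") & (pred == "suppressor_candidate"))
        | ((cls == "activator") & (pred == "activator_candidate"))
    ).sum()
    n_pos = int((cls == "suppressor").sum() + (cls == "activator").sum())
    n_pred = int((pred != "none").sum())
    lethal = cls == "lethal"
    return {
        "sensitivity": float(tp / n_pos) if n_pos else float("nan"),
        "fdp": float((n_pred - tp) / n_pred) if n_pred else 0.0,
        "n_classified": n_pred,
        "lethal_excluded_fraction": float(
            hit_table.loc[lethal, "viability_excluded"].mean()
        ) if int(lethal.sum()) else float("nan"),
    }
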