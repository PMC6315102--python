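"""End-to-end pipeline: simulate -> preprocess -> detect -> rhythm ->
cluster -> network, with a validated config and a deterministic result
bundle.

Every numeric threshold used downstream is carried in the config and
echoed into the run-metadata JSON, so any number in the outputs traces
back to a configuration value.  All randomness derives from the single
config seed; two runs with the same config produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import clustering, crossspecies, detection, periodicity, preprocess, simulate
from .matrixio import Scale, write_matrix, write_probe_map, write_report

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_all",
    "summarize_run",
    "validate_summary",
    "RunBundle",
]

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """All tunable parameters of one pipeline run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_genes: int = 300
    photoperiod: float = 12.0
    periodic_fraction: float = Field(default=0.30, ge=0.0, le=1.0)
    background_fraction: float = Field(default=0.65, ge=0.0, le=1.0)
    probes_per_gene: int = 6
    noise_sd: float = 0.25
    quantile: bool = True
    polish_max_iter: int = 20
    polish_tol: float = 1e-8
    snr_threshold: float = 5.0
    detection_rule: str = "any"
    detection_k: Optional[int] = None
    period_hours: float = 24.0
    n_perm: int = 999
    fdr: float = 0.25
    contrast_alpha: float = 0.05
    k_clusters: int = 4
    network_threshold: float = 0.5
    grid_step: float = 1.0
    phase_shift_hours: float = 12.0
    max_network_genes: int = 80

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunBundle:
    """In-memory results of a full run."""

    config: PipelineConfig
    truth: simulate.SyntheticTruth
    gene_matrix: "Any"
    averaged: "Any"
    detection_result: detection.DetectionResult
    rhythm: pd.DataFrame
    contrast: pd.DataFrame
    assignment: Optional[clustering.ClusterAssignment]
    cluster_table: pd.DataFrame
    network: Optional[crossspecies.DielNetwork]
    ortholog_r: pd.DataFrame
    summary: dict


def _stage(name: str, outdir: Path | None):
    """Context manager: logs wall time, marks failures on disk."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
                return False
            logger.error("stage %s: FAILED after %.2fs (%s)", name, dt, exc)
            if outdir is not None:
                (outdir / f"FAILED_{name}").write_text(f"{type(exc).__name__}: {exc}\n")
            raise PipelineError(name, exc) from exc

    return _Ctx()


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> RunBundle:
    """Execute every stage; optionally write the result bundle to ``outdir``."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    with _stage("simulate", out):
        bundle = simulate.ucyna_preset(
            n_genes=config.n_genes,
            seed=config.seed,
            periodic_fraction=config.periodic_fraction,
            background_fraction=config.background_fraction,
            noise_sd=config.noise_sd,
            period_hours=config.period_hours,
        )
        em_a, em_b, pairs = simulate.simulate_two_organisms(
            bundle.truth, config.phase_shift_hours
        )

    with _stage("preprocess", out):
        genes = preprocess.preprocess_probes(
            bundle.probe_matrix, bundle.probe_map,
            quantile=config.quantile,
            polish_max_iter=config.polish_max_iter,
            polish_tol=config.polish_tol,
        )
        averaged = preprocess.average_replicates(genes)

    with _stage("detect", out):
        rule = detection.DetectionRule(config.detection_rule)
        det = detection.snr_detect(
            preprocess.delog(genes),
            threshold=config.snr_threshold,
            rule=rule,
            k=config.detection_k,
        )

    with _stage("rhythm", out):
        detected = det.detected_ids
        rhythm = periodicity.analyze_rhythms(
            averaged.subset_entities(detected),
            period=config.period_hours,
            n_perm=config.n_perm,
            seed=config.seed,
            fdr_threshold=config.fdr,
        )
        contrast = periodicity.light_dark_contrast(
            genes.subset_entities(detected), alpha=config.contrast_alpha
        )

    with _stage("cluster", out):
        diel_ids = list(rhythm.loc[rhythm["is_diel"], "gene_id"])
        if diel_ids and len(diel_ids) >= 2:
            z, _ = clustering.standardize(averaged.subset_entities(diel_ids))
            dist = clustering.pearson_distance_matrix(z)
            k = min(config.k_clusters, len(z))
            assignment = clustering.hierarchical_cluster(dist, k=k)
            cluster_table, _ = clustering.cluster_summary(assignment, z, averaged.hours)
        else:
            assignment = None
            cluster_table = pd.DataFrame(columns=["cluster", "size", "peak_hour"])

    with _stage("network", out):
        net_ids = diel_ids[: config.max_network_genes]
        if len(net_ids) >= 2:
            grid = crossspecies.common_grid(
                [(em_a.hours.min(), em_a.hours.max()),
                 (em_b.hours.min(), em_b.hours.max())],
                step=config.grid_step,
            )
            on_a = crossspecies.align_to_grid(em_a.subset_entities(net_ids), grid)
            ids_b = [f"orgB_{g}" for g in net_ids]
            on_b = crossspecies.align_to_grid(em_b.subset_entities(ids_b), grid)
            courses = pd.concat([on_a, on_b])
            attrs = pd.DataFrame(
                {"organism": ["orgA"] * len(on_a) + ["orgB"] * len(on_b)},
                index=courses.index,
            )
            network = crossspecies.build_network(
                courses, threshold=config.network_threshold, node_attrs=attrs
            )
            r_pairs = [
                float(network.correlations.at[g, f"orgB_{g}"]) for g in net_ids
            ]
            ortholog_r = pd.DataFrame({"gene_a": net_ids,
                                       "gene_b": ids_b,
                                       "r": r_pairs})
        else:
            network = None
            ortholog_r = pd.DataFrame(columns=["gene_a", "gene_b", "r"])

    summary = summarize_run(
        config, bundle.truth, det, rhythm, contrast, cluster_table, network, ortholog_r
    )
    result = RunBundle(config, bundle.truth, genes, averaged, det, rhythm, contrast,
                       assignment, cluster_table, network, ortholog_r, summary)
    if out is not None:
        _write_bundle(result, bundle, out)
    return result


def summarize_run(
    config: PipelineConfig,
    truth: simulate.SyntheticTruth,
    det: detection.DetectionResult,
    rhythm: pd.DataFrame,
    contrast: pd.DataFrame,
    cluster_table: pd.DataFrame,
    network: Optional[crossspecies.DielNetwork],
    ortholog_r: pd.DataFrame,
) -> dict:
    """Headline counts/fractions of one run (schema-validated JSON object)."""
    n_genes = len(truth.genes)
    n_detected = int(det.calls["detected"].sum())
    n_diel = int(rhythm["is_diel"].sum())
    diel_contrast = contrast.merge(rhythm.loc[rhythm["is_diel"], ["gene_id"]], on="gene_id")
    n_different = int((diel_contrast["direction"] != periodicity.Direction.FLAT.value).sum())
    summary = {
        "seed": config.seed,
        "n_genes": n_genes,
        "detected_count": n_detected,
        "detected_fraction": n_detected / n_genes if n_genes else 0.0,
        "diel_count": n_diel,
        "diel_fraction_of_detected": n_diel / n_detected if n_detected else 0.0,
        "diel_fraction_of_total": n_diel / n_genes if n_genes else 0.0,
        "light_dark_different_fraction": n_different / n_diel if n_diel else 0.0,
        "cluster_sizes": [int(s) for s in cluster_table["size"]],
        "cluster_peak_hours": [float(h) for h in cluster_table["peak_hour"]],
        "network_edge_count": int(network.graph.number_of_edges()) if network else 0,
        "antiphase_ortholog_fraction": (
            float((ortholog_r["r"] < -0.5).mean()) if len(ortholog_r) else 0.0
        ),
        "thresholds": {
            "snr_threshold": config.snr_threshold,
            "fdr": config.fdr,
            "n_perm": config.n_perm,
            "period_hours": config.period_hours,
            "k_clusters": config.k_clusters,
            "network_threshold": config.network_threshold,
            "contrast_alpha": config.contrast_alpha,
            "grid_step": config.grid_step,
            "phase_shift_hours": config.phase_shift_hours,
        },
    }
    validate_summary(summary)
    return summary


def _load_schema() -> dict:
    with resources.files("dieltx.data").joinpath("summary.schema.json").open() as fh:
        return json.load(fh)


def validate_summary(summary: dict, schema: dict | None = None) -> None:
    """Check the summary against the published JSON schema (subset: object
    types, required keys, scalar/array kinds)."""
    schema = schema or _load_schema()

    def check(value, spec, path):
        kind = spec.get("type")
        ok = {
            "object": lambda v: isinstance(v, dict),
            "array": lambda v: isinstance(v, list),
            "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
            "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
            "string": lambda v: isinstance(v, str),
            "boolean": lambda v: isinstance(v, bool),
        }
        if kind and not ok[kind](value):
            raise ValueError(f"summary{path}: expected {kind}, got {type(value).__name__}")
        if kind == "object":
            for key in spec.get("required", []):
                if key not in value:
                    raise ValueError(f"summary{path}: missing required key {key!r}")
            for key, sub in spec.get("properties", {}).items():
                if key in value:
                    check(value[key], sub, f"{path}.{key}")

    check(summary, schema, "")


def _write_bundle(result: RunBundle, sim: simulate.SimulationBundle, out: Path) -> None:
    """Write every artifact plus metadata and a hashed manifest."""
    write_matrix(sim.probe_matrix, out / "probe_matrix.tsv")
    write_probe_map(sim.probe_map, out / "probe_map.tsv")
    truth_table = result.truth.genes.reset_index()
    write_report(truth_table, out / "truth_genes.tsv")
    write_matrix(result.gene_matrix, out / "gene_matrix.tsv")
    write_matrix(result.averaged, out / "gene_matrix_averaged.tsv")
    write_report(result.detection_result.calls, out / "detection.tsv")
    write_report(result.rhythm, out / "rhythm.tsv")
    write_report(result.contrast, out / "light_dark_contrast.tsv")
    if result.assignment is not None:
        assign = result.assignment.labels.rename_axis("gene_id").reset_index()
        write_report(assign, out / "clusters.tsv")
    write_report(result.cluster_table, out / "cluster_summary.tsv")
    if result.network is not None:
        write_report(result.network.edge_table, out / "network_edges.tsv")
        nx.write_graphml(result.network.graph, out / "network.graphml")
    write_report(result.ortholog_r, out / "ortholog_correlations.tsv")
    write_report(result.summary, out / "summary.json")
    metadata = {"config": result.config.model_dump(), "package": "dieltx"}
    write_report(metadata, out / "metadata.json")
    manifest = {}
    for path in sorted(out.iterdir()):
        if path.name == "manifest.json" or path.name.startswith("FAILED"):
            continue
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    write_report({"files": manifest}, out / "manifest.json")
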