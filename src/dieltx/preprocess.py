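"""Probe-to-gene summarization and normalization.

The pipeline follows the robust multichip convention: log2-transform the
linear intensities, quantile-normalize across samples, summarize each
gene's probes to one value per sample by Tukey median polish (gene value =
overall effect + column effect), then average replicate samples.
Normalization precedes summarization; ``preprocess_probes`` exposes a flag
to swap the order for sensitivity checks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrixio import ExpressionMatrix, ProbeMap, Scale

__all__ = [
    "PolishDecomposition",
    "median_polish",
    "quantile_normalize",
    "summarize_genes",
    "average_replicates",
    "log2_transform",
    "delog",
    "preprocess_probes",
]

logger = logging.getLogger(__name__)


@dataclass
class PolishDecomposition:
    """Additive decomposition x[i,j] ~ overall + row[i] + col[j] + residual."""

    overall: float
    row_effects: np.ndarray
    column_effects: np.ndarray
    residuals: np.ndarray
    iterations: int
    converged: bool

    def reconstruct(self) -> np.ndarray:
        return (self.overall
                + self.row_effects[:, None]
                + self.column_effects[None, :]
                + self.residuals)

    @property
    def summarized(self) -> np.ndarray:
        """Per-column (per-sample) summary value: overall + column effect."""
        return self.overall + self.column_effects


def median_polish(x, max_iter: int = 20, tol: float = 1e-8) -> PolishDecomposition:
    """Tukey's median polish by alternating row/column median sweeps.

    Iterates until the sum of absolute residuals stops decreasing by a
    relative ``tol`` or ``max_iter`` sweeps are reached.  The decomposition
    reconstructs the input exactly at every iteration.
    """
    z = np.array(x, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ValueError("median_polish needs a non-empty 2-D matrix")
    if not np.all(np.isfinite(z)):
        raise ValueError("median_polish requires finite input")
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    oldsum = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        delta = float(np.median(col))
        col -= delta
        overall += delta
        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        delta = float(np.median(row))
        row -= delta
        overall += delta
        newsum = float(np.abs(z).sum())
        if newsum == 0.0 or abs(newsum - oldsum) < tol * newsum:
            converged = True
            break
        oldsum = newsum
    return PolishDecomposition(overall, row, col, z, it, converged)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean order-statistic distribution.

    After normalization each sample's sorted values equal the across-sample
    mean of sorted values; within-sample ranks are preserved (ties broken
    by row order, stably), which makes the operation idempotent.
    """
    v = matrix.values.to_numpy(dtype=float)
    if v.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    order = np.argsort(v, axis=0, kind="stable")
    mean_sorted = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        out[order[:, j], j] = mean_sorted
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(values)


def summarize_genes(
    probes: ExpressionMatrix,
    probe_map: ProbeMap,
    max_iter: int = 20,
    tol: float = 1e-8,
) -> ExpressionMatrix:
    """Summarize probe rows to one gene row per sample via median polish.

    Expects log2-scale probes.  Probes absent from the map are excluded
    with a warning carrying the count; single-probe genes pass through.
    """
    if probes.scale is not Scale.LOG2:
        raise ValueError("summarize_genes expects a log2-scale probe matrix")
    mapped = set(probe_map.table["probe_id"])
    present = [p for p in probes.entity_ids if p in mapped]
    n_unmapped = len(probes.entity_ids) - len(present)
    if n_unmapped:
        warnings.warn(f"excluding {n_unmapped} probes missing from the probe map",
                      stacklevel=2)
    missing = mapped - set(probes.entity_ids)
    if missing:
        raise ValueError(f"probe map references probes absent from the matrix: "
                         f"{sorted(missing)[:5]}")
    by_gene = probe_map.table.set_index("probe_id").loc[present, "gene_id"]
    rows = {}
    for gene in probe_map.genes:
        probe_ids = by_gene.index[by_gene == gene]
        block = probes.values.loc[probe_ids]
        if len(block) == 1:
            rows[gene] = block.iloc[0].to_numpy(dtype=float)
        else:
            rows[gene] = median_polish(block.to_numpy(), max_iter, tol).summarized
    values = pd.DataFrame.from_dict(rows, orient="index", columns=probes.sample_ids)
    values.index.name = "gene_id"
    return ExpressionMatrix(values, list(probes.samples), Scale.LOG2)


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Arithmetic mean of replicate columns sharing a time code.

    Produces one column per time point (named by its label); singleton
    time points pass through unchanged.
    """
    labels = [s.time_point.raw_label for s in matrix.samples]
    unique = list(dict.fromkeys(labels))
    cols = {}
    samples = []
    for label in unique:
        idx = [i for i, l in enumerate(labels) if l == label]
        cols[label] = matrix.values.iloc[:, idx].mean(axis=1)
        first = matrix.samples[idx[0]]
        samples.append(
            type(first)(sample_id=label, time_point=first.time_point,
                        replicate_id="mean", organism=first.organism)
        )
    values = pd.DataFrame(cols, index=matrix.values.index)
    return ExpressionMatrix(values, samples, matrix.scale)


def log2_transform(matrix: ExpressionMatrix, floor: float = 1e-6) -> ExpressionMatrix:
    """Linear -> log2; non-positive intensities are floored at ``floor``
    (the count is logged)."""
    if matrix.scale is not Scale.LINEAR:
        raise ValueError("log2_transform expects linear-scale input")
    v = matrix.values.to_numpy(dtype=float)
    n_floored = int((v < floor).sum())
    if n_floored:
        logger.info("floored %d intensities below %g before log2", n_floored, floor)
    values = pd.DataFrame(np.log2(np.maximum(v, floor)),
                          index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(values, Scale.LOG2)


def delog(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Log2 -> linear."""
    if matrix.scale is not Scale.LOG2:
        raise ValueError("delog expects log2-scale input")
    values = 2.0 ** matrix.values
    return matrix.with_values(values, Scale.LINEAR)


def preprocess_probes(
    probes: ExpressionMatrix,
    probe_map: ProbeMap,
    quantile: bool = True,
    normalize_first: bool = True,
    polish_max_iter: int = 20,
    polish_tol: float = 1e-8,
    floor: float = 1e-6,
) -> ExpressionMatrix:
    """Full probe-level pipeline: log2, quantile normalization, median-polish
    summarization.  Returns the per-chip gene-level log2 matrix (replicates
    not yet averaged)."""
    m = log2_transform(probes, floor=floor) if probes.scale is Scale.LINEAR else probes
    if quantile and normalize_first:
        m = quantile_normalize(m)
    genes = summarize_genes(m, probe_map, max_iter=polish_max_iter, tol=polish_tol)
    if quantile and not normalize_first:
        genes = quantile_normalize(genes)
    return genes
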