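"""Synthetic diel expression data with known ground truth.

Gene rhythms follow a single-harmonic cosinor in log2 units:

    x(t) = mesor + amplitude * cos(2*pi*(t - phase_hour)/period) + noise

Probe-level data add a per-probe affinity offset and probe noise, then a
per-sample affine distortion (gain and shift in log2 space) before
exponentiation to linear intensities — enough structure to make quantile
normalization and median-polish summarization non-trivial without
modelling scanner physics.  A configurable fraction of genes is flat
background near a low intensity so detection calls have true negatives.

The default "ucyna" preset mirrors the emulated study design: 8 time
points over 36 h with duplicate samples at four of them, 6 probes per
gene, 30% of genes periodic and 65% at background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrixio import ExpressionMatrix, ProbeMap, Scale
from .timecourse import (
    CYANOTHECE_LABELS,
    SampleDescriptor,
    TimePoint,
    UCYNA_LABELS,
    parse_series,
)

__all__ = [
    "SyntheticTruth",
    "make_truth",
    "simulate_gene_course",
    "simulate_gene_matrix",
    "simulate_probe_matrix",
    "simulate_two_organisms",
    "ucyna_preset",
    "UCYNA_REPLICATED_LABELS",
]

# Duplicate samples existed at four of the eight UCYN-A time points.
UCYNA_REPLICATED_LABELS = ("L6", "L9", "D3", "2L12")


@dataclass
class SyntheticTruth:
    """Planted per-gene rhythm parameters plus generator provenance.

    ``genes`` is indexed by gene id with columns is_periodic, is_background,
    mesor, amplitude, phase_hour, noise_sd (all log2 units / hours).
    Per-sample distortions and per-probe affinities are filled in by
    :func:`simulate_probe_matrix`.
    """

    genes: pd.DataFrame
    seed: int
    period_hours: float = 24.0
    sample_scale: pd.Series | None = None
    sample_shift: pd.Series | None = None
    probe_affinity: pd.Series | None = None

    def __post_init__(self) -> None:
        g = self.genes
        if (g.loc[g["is_periodic"], "amplitude"] <= 0).any():
            raise ValueError("periodic genes must have amplitude > 0")
        if (g["noise_sd"] < 0).any():
            raise ValueError("noise_sd must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes.index)

    @property
    def periodic_ids(self) -> list[str]:
        return list(self.genes.index[self.genes["is_periodic"]])

    @property
    def background_ids(self) -> list[str]:
        return list(self.genes.index[self.genes["is_background"]])


def make_truth(
    n_genes: int = 400,
    periodic_fraction: float = 0.30,
    background_fraction: float = 0.65,
    seed: int = 0,
    amplitude_range: tuple[float, float] = (0.8, 2.0),
    mesor_range: tuple[float, float] = (6.0, 10.0),
    background_mesor: float = 2.5,
    background_mesor_sd: float = 0.3,
    noise_sd: float = 0.25,
    period_hours: float = 24.0,
) -> SyntheticTruth:
    """Draw planted gene parameters; the requested fractions are realized
    exactly (counts are rounded, then fixed by construction)."""
    if periodic_fraction + background_fraction > 1:
        raise ValueError("periodic and background fractions exceed 1")
    rng = np.random.default_rng([seed, 0])
    n_per = round(n_genes * periodic_fraction)
    n_bg = round(n_genes * background_fraction)
    ids = [f"g{i:04d}" for i in range(n_genes)]
    roles = np.array(["periodic"] * n_per + ["background"] * n_bg
                     + ["flat"] * (n_genes - n_per - n_bg))
    rng.shuffle(roles)
    is_per = roles == "periodic"
    is_bg = roles == "background"
    mesor = rng.uniform(*mesor_range, n_genes)
    mesor[is_bg] = rng.normal(background_mesor, background_mesor_sd, int(is_bg.sum()))
    amplitude = np.where(is_per, rng.uniform(*amplitude_range, n_genes), 0.0)
    phase = rng.uniform(0.0, period_hours, n_genes)
    genes = pd.DataFrame(
        {
            "is_periodic": is_per,
            "is_background": is_bg,
            "mesor": mesor,
            "amplitude": amplitude,
            "phase_hour": phase % period_hours,
            "noise_sd": np.full(n_genes, float(noise_sd)),
        },
        index=pd.Index(ids, name="gene_id"),
    )
    return SyntheticTruth(genes=genes, seed=seed, period_hours=period_hours)


def simulate_gene_course(
    mesor: float,
    amplitude: float,
    phase_hour: float,
    noise_sd: float,
    hours: np.ndarray,
    period_hours: float = 24.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One gene's log2 time course under the cosinor model."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    hours = np.asarray(hours, dtype=float)
    x = mesor + amplitude * np.cos(2 * np.pi * (hours - phase_hour) / period_hours)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("an rng is required when noise_sd > 0")
        x = x + rng.normal(0.0, noise_sd, hours.shape)
    return x


def _expand_samples(
    time_points: Sequence[TimePoint],
    replicated_labels: Sequence[str],
    n_replicates: int,
    organism: str,
) -> list[SampleDescriptor]:
    samples: list[SampleDescriptor] = []
    for tp in time_points:
        reps = n_replicates if tp.raw_label in replicated_labels else 1
        for r in range(1, reps + 1):
            sid = f"{tp.raw_label}_{r}" if reps > 1 else tp.raw_label
            samples.append(SampleDescriptor(sid, tp, str(r), organism))
    return samples


def simulate_gene_matrix(
    truth: SyntheticTruth,
    time_points: Sequence[TimePoint],
    replicated_labels: Sequence[str] = (),
    n_replicates: int = 2,
    organism: str = "synthetic",
    stream: int = 1,
) -> ExpressionMatrix:
    """Gene-level log2 matrix (no probe/sample artifacts)."""
    samples = _expand_samples(time_points, replicated_labels, n_replicates, organism)
    hours = np.array([s.time_point.absolute_hour for s in samples])
    rng = np.random.default_rng([truth.seed, stream])
    rows = [
        simulate_gene_course(
            g.mesor, g.amplitude, g.phase_hour, g.noise_sd, hours,
            truth.period_hours, rng,
        )
        for g in truth.genes.itertuples()
    ]
    values = pd.DataFrame(rows, index=truth.genes.index.copy(),
                          columns=[s.sample_id for s in samples])
    return ExpressionMatrix(values, samples, Scale.LOG2)


def simulate_probe_matrix(
    truth: SyntheticTruth,
    time_points: Sequence[TimePoint],
    probes_per_gene: int = 6,
    replicated_labels: Sequence[str] = UCYNA_REPLICATED_LABELS,
    n_replicates: int = 2,
    affinity_sd: float = 0.7,
    probe_noise_sd: float = 0.1,
    sample_scale_sd: float = 0.05,
    sample_shift_sd: float = 0.3,
    organism: str = "synthetic",
) -> tuple[ExpressionMatrix, ProbeMap, SyntheticTruth]:
    """Probe-level linear intensities with affinities and chip distortions.

    Probe log2 value = gene value + affinity offset + probe noise; each
    sample then gets an affine log2 distortion (gain ~ N(1, scale_sd),
    shift ~ N(0, shift_sd)) before exponentiation.
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    samples = _expand_samples(time_points, replicated_labels, n_replicates, organism)
    hours = np.array([s.time_point.absolute_hour for s in samples])
    n_s = len(samples)
    rng = np.random.default_rng([truth.seed, 2])

    gene_ids = truth.gene_ids
    probe_ids = [f"{g}_p{j + 1}" for g in gene_ids for j in range(probes_per_gene)]
    affinity = pd.Series(rng.normal(0.0, affinity_sd, len(probe_ids)),
                         index=probe_ids, name="affinity_offset")
    scale = pd.Series(rng.normal(1.0, sample_scale_sd, n_s),
                      index=[s.sample_id for s in samples], name="scale_distortion")
    shift = pd.Series(rng.normal(0.0, sample_shift_sd, n_s),
                      index=[s.sample_id for s in samples], name="shift_distortion")
    if (scale <= 0).any():
        raise ValueError("sample scale distortion must stay positive; lower sample_scale_sd")

    rows = np.empty((len(probe_ids), n_s))
    for i, g in enumerate(truth.genes.itertuples()):
        course = simulate_gene_course(
            g.mesor, g.amplitude, g.phase_hour, g.noise_sd, hours,
            truth.period_hours, rng,
        )
        block = course[None, :] + affinity.to_numpy()[
            i * probes_per_gene:(i + 1) * probes_per_gene, None
        ]
        if probe_noise_sd > 0:
            block = block + rng.normal(0.0, probe_noise_sd, block.shape)
        rows[i * probes_per_gene:(i + 1) * probes_per_gene] = block
    log2_values = rows * scale.to_numpy()[None, :] + shift.to_numpy()[None, :]
    values = pd.DataFrame(2.0 ** log2_values, index=pd.Index(probe_ids, name="probe_id"),
                          columns=[s.sample_id for s in samples])
    pmap = ProbeMap(pd.DataFrame({
        "probe_id": probe_ids,
        "gene_id": [g for g in gene_ids for _ in range(probes_per_gene)],
    }))
    truth_out = replace(truth, sample_scale=scale, sample_shift=shift, probe_affinity=affinity)
    return ExpressionMatrix(values, samples, Scale.LINEAR), pmap, truth_out


def simulate_two_organisms(
    truth: SyntheticTruth,
    phase_shift_hours: float,
    labels_a: Sequence[str] = UCYNA_LABELS,
    labels_b: Sequence[str] = CYANOTHECE_LABELS,
    organism_a: str = "orgA",
    organism_b: str = "orgB",
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Paired datasets: organism B orthologs reuse organism A's parameters
    with peak phase shifted by ``phase_shift_hours``; grids may differ.

    Returns (matrix_a, matrix_b, ortholog truth table).
    """
    tps_a = parse_series(labels_a)
    tps_b = parse_series(labels_b)
    em_a = simulate_gene_matrix(truth, tps_a, organism=organism_a, stream=3)
    genes_b = truth.genes.copy()
    genes_b["phase_hour"] = (genes_b["phase_hour"] + phase_shift_hours) % truth.period_hours
    genes_b.index = pd.Index(
        [f"{organism_b}_{g}" for g in truth.genes.index], name="gene_id"
    )
    truth_b = SyntheticTruth(genes=genes_b, seed=truth.seed,
                             period_hours=truth.period_hours)
    em_b = simulate_gene_matrix(truth_b, tps_b, organism=organism_b, stream=4)
    pairs = pd.DataFrame({
        "gene_a": list(truth.genes.index),
        "gene_b": list(genes_b.index),
        "planted_shift_hours": phase_shift_hours,
    })
    return em_a, em_b, pairs


@dataclass
class SimulationBundle:
    """Everything one preset run produces."""

    probe_matrix: ExpressionMatrix
    probe_map: ProbeMap
    truth: SyntheticTruth
    time_points: list[TimePoint]


def ucyna_preset(
    n_genes: int = 400,
    seed: int = 0,
    **truth_overrides,
) -> SimulationBundle:
    """The default emulation: 8 points (L6..2L12), duplicates at four of
    them, 6 probes/gene, 30% periodic, 65% background."""
    truth = make_truth(n_genes=n_genes, seed=seed, **truth_overrides)
    tps = parse_series(UCYNA_LABELS)
    probes, pmap, truth = simulate_probe_matrix(truth, tps)
    return SimulationBundle(probes, pmap, truth, tps)
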