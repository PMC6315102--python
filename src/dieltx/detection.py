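"""Detection calls from signal-to-noise ratios, plus the abundance/IQR filter.

A chip's background BG is the mean of its lowest 5% of signals; a gene's
per-chip SNR is (S - BG)/BG and transcription counts as detected when the
SNR reaches a threshold (default 5) under a combination rule across chips
(default: any chip).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .matrixio import ExpressionMatrix, Scale

__all__ = [
    "DetectionRule",
    "DetectionResult",
    "chip_background",
    "snr_matrix",
    "snr_detect",
    "abundance_iqr_filter",
]


class DetectionRule(Enum):
    """How per-chip detection flags combine into one call per gene."""

    ANY = "any"
    ALL = "all"
    K_OF_N = "k_of_n"


@dataclass
class DetectionResult:
    """Per-gene/per-chip SNR values and the combined detection calls."""

    snr: pd.DataFrame              # genes x samples
    background: pd.Series          # per-sample BG
    calls: pd.DataFrame            # gene_id, max_snr, n_above, detected
    threshold: float
    rule: DetectionRule

    @property
    def detected_ids(self) -> list[str]:
        return list(self.calls.loc[self.calls["detected"], "gene_id"])


def chip_background(signals, fraction: float = 0.05) -> float:
    """Mean of the lowest ``ceil(fraction * n)`` signals on a chip."""
    x = np.asarray(signals, dtype=float)
    if x.size == 0:
        raise ValueError("chip_background needs at least one signal")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if x.size * fraction < 1:
        raise ValueError(
            f"need at least {math.ceil(1 / fraction)} signals for fraction={fraction}"
        )
    k = math.ceil(fraction * x.size)
    return float(np.sort(x)[:k].mean())


def snr_matrix(matrix: ExpressionMatrix, fraction: float = 0.05) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene, per-chip SNR = (S - BG)/BG with per-chip background."""
    if matrix.scale is not Scale.LINEAR:
        raise ValueError(
            "SNR detection runs on linear intensities; de-log the matrix first"
        )
    v = matrix.values
    bg = pd.Series({c: chip_background(v[c], fraction) for c in v.columns})
    snr = (v - bg) / bg
    return snr, bg


def snr_detect(
    matrix: ExpressionMatrix,
    threshold: float = 5.0,
    rule: DetectionRule = DetectionRule.ANY,
    k: int | None = None,
    fraction: float = 0.05,
) -> DetectionResult:
    """Call genes transcribed at detectable levels (SNR >= threshold)."""
    snr, bg = snr_matrix(matrix, fraction)
    above = snr >= threshold
    n_above = above.sum(axis=1)
    n_chips = snr.shape[1]
    if rule is DetectionRule.ANY:
        detected = n_above >= 1
    elif rule is DetectionRule.ALL:
        detected = n_above == n_chips
    else:
        if k is None or not 1 <= k <= n_chips:
            raise ValueError("K_OF_N rule needs 1 <= k <= number of chips")
        detected = n_above >= k
    calls = pd.DataFrame({
        "gene_id": snr.index,
        "max_snr": snr.max(axis=1).to_numpy(),
        "n_above": n_above.to_numpy(),
        "detected": detected.to_numpy(),
    })
    return DetectionResult(snr, bg, calls, threshold, rule)


def abundance_iqr_filter(
    matrix: ExpressionMatrix,
    min_value: float,
    min_fraction: float = 0.25,
    min_iqr_log2: float = 0.5,
) -> tuple[list[str], pd.DataFrame]:
    """Keep genes abundant in enough samples AND variable across samples.

    A gene passes when its log2 value exceeds ``min_value`` in at least
    ``min_fraction`` of samples and its interquartile range across all
    samples is at least ``min_iqr_log2``.  ``min_value`` is an explicit
    required parameter (the filter is scale-sensitive).
    """
    if matrix.scale is not Scale.LOG2:
        raise ValueError("abundance_iqr_filter expects a log2-scale matrix")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    v = matrix.values
    frac_above = (v > min_value).mean(axis=1)
    iqr = v.quantile(0.75, axis=1) - v.quantile(0.25, axis=1)
    pass_abundance = frac_above >= min_fraction
    pass_iqr = iqr >= min_iqr_log2
    selected = pass_abundance & pass_iqr
    table = pd.DataFrame({
        "gene_id": v.index,
        "fraction_above": frac_above.to_numpy(),
        "iqr_log2": iqr.to_numpy(),
        "pass_abundance": pass_abundance.to_numpy(),
        "pass_iqr": pass_iqr.to_numpy(),
        "selected": selected.to_numpy(),
    })
    return list(v.index[selected]), table
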