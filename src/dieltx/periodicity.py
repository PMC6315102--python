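"""Fourier-score periodicity testing with a permutation null.

The statistic is the single-frequency periodogram of the standardized
series evaluated at the diel frequency (period 24 h by default):

    F = sqrt( (sum_j x_j cos(w t_j))^2 + (sum_j x_j sin(w t_j))^2 ) / n

with x standardized to mean 0, sd 1 (sample sd).  Sampling grids may be
irregular: sin/cos are evaluated at the true absolute hours, with no
resampling.  Significance comes from permuting the assignment of values to
time points; q-values are Benjamini-Hochberg, and genes with q below the
FDR threshold (0.25 by default) are called diel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrixio import ExpressionMatrix, Scale
from .timecourse import Phase

__all__ = [
    "fourier_score",
    "permutation_test",
    "fdr_adjust",
    "peak_hour",
    "analyze_rhythms",
    "Direction",
    "light_dark_contrast",
]


def _standardize(x: np.ndarray) -> np.ndarray | None:
    """Mean-0, sd-1 (sample sd) copy, or None for a constant series."""
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return None
    return (x - x.mean()) / sd


def _check_series(x, t):
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.shape != t.shape or x.ndim != 1:
        raise ValueError("x and t must be 1-D and of equal length")
    if x.size < 4:
        raise ValueError("periodicity testing needs at least 4 time points")
    return x, t


def fourier_score(x, t, period: float = 24.0) -> float:
    """Single-frequency periodogram score; 0 for a constant series."""
    x, t = _check_series(x, t)
    z = _standardize(x)
    if z is None:
        return 0.0
    w = 2 * np.pi * t / period
    return float(np.hypot(z @ np.cos(w), z @ np.sin(w)) / x.size)


def permutation_test(
    x,
    t,
    n_perm: int = 1999,
    seed: int | np.random.SeedSequence = 0,
    period: float = 24.0,
) -> tuple[float, float]:
    """Permutation p-value for the Fourier score.

    p = (1 + #{permuted score >= observed}) / (n_perm + 1), permuting the
    assignment of values to time points with a seeded generator.
    """
    x, t = _check_series(x, t)
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse p-value resolution",
                      stacklevel=2)
    z = _standardize(x)
    if z is None:
        return 0.0, 1.0
    w = 2 * np.pi * t / period
    c, s = np.cos(w), np.sin(w)
    n = x.size
    observed = float(np.hypot(z @ c, z @ s) / n)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(z, (n_perm, 1)), axis=1)
    scores = np.hypot(perms @ c, perms @ s) / n
    p = (1 + int((scores >= observed).sum())) / (n_perm + 1)
    return observed, p


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def peak_hour(x, t, period: float = 24.0) -> float:
    """Hour in [0, period) at which the fitted diel harmonic peaks.

    Least-squares cosinor fit x ~ a + b cos(wt) + c sin(wt); the peak is the
    phase of the fitted harmonic.  (On a uniform full-period grid this
    equals the phase of the first Fourier component; the regression form
    stays unbiased on irregular grids.)  Constant series have no peak and
    raise ValueError.
    """
    x, t = _check_series(x, t)
    if x.std(ddof=1) == 0:
        raise ValueError("peak hour is undefined for a constant series")
    w = 2 * np.pi * t / period
    design = np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    _, b, c = coef
    return float((np.arctan2(c, b) * period / (2 * np.pi)) % period)


def analyze_rhythms(
    matrix: ExpressionMatrix,
    period: float = 24.0,
    n_perm: int = 1999,
    seed: int = 0,
    fdr_threshold: float = 0.25,
) -> pd.DataFrame:
    """Per-gene periodicity table: score, p, q, diel call, peak hour.

    Each gene gets an independent, reproducible permutation stream spawned
    from ``seed``.  Constant genes score 0 with p = 1 and no peak hour.
    """
    t = matrix.hours
    genes = matrix.entity_ids
    streams = np.random.SeedSequence(seed).spawn(len(genes))
    scores = np.empty(len(genes))
    pvals = np.empty(len(genes))
    peaks = np.full(len(genes), np.nan)
    for i, gene in enumerate(genes):
        x = matrix.values.loc[gene].to_numpy(dtype=float)
        scores[i], pvals[i] = permutation_test(x, t, n_perm, streams[i], period)
        if x.std(ddof=1) > 0:
            peaks[i] = peak_hour(x, t, period)
    qvals = fdr_adjust(pvals)
    return pd.DataFrame({
        "gene_id": genes,
        "fourier_score": scores,
        "p_value": pvals,
        "q_value": qvals,
        "is_diel": qvals < fdr_threshold,
        "peak_hour": peaks,
    })


class Direction(Enum):
    """Sign of a significant light-vs-dark difference."""

    LIGHT_UP = "light_up"
    DARK_UP = "dark_up"
    FLAT = "flat"


def light_dark_contrast(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample test of log2 levels, light vs dark, per gene.

    Requires at least two samples in each phase.  fold_change = 2^|dmean|;
    direction is FLAT unless q < alpha.
    """
    if matrix.scale is not Scale.LOG2:
        raise ValueError("light_dark_contrast expects a log2-scale matrix")
    light_cols = [s.sample_id for s in matrix.samples if s.time_point.phase is Phase.LIGHT]
    dark_cols = [s.sample_id for s in matrix.samples if s.time_point.phase is Phase.DARK]
    if len(light_cols) < 2 or len(dark_cols) < 2:
        raise ValueError("need >= 2 light and >= 2 dark samples")
    light = matrix.values[light_cols].to_numpy(dtype=float)
    dark = matrix.values[dark_cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(light, dark, axis=1, equal_var=False)
    pvals = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    mean_light = light.mean(axis=1)
    mean_dark = dark.mean(axis=1)
    diff = mean_light - mean_dark
    qvals = fdr_adjust(np.clip(pvals, np.finfo(float).tiny, 1.0))
    significant = qvals < alpha
    direction = np.where(
        ~significant, Direction.FLAT.value,
        np.where(diff > 0, Direction.LIGHT_UP.value, Direction.DARK_UP.value),
    )
    return pd.DataFrame({
        "gene_id": matrix.entity_ids,
        "mean_light": mean_light,
        "mean_dark": mean_dark,
        "log2_difference": diff,
        "fold_change": 2.0 ** np.abs(diff),
        "p_value": pvals,
        "q_value": qvals,
        "direction": direction,
    })
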