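"""Cross-organism comparison: common-grid alignment, orthologs, networks.

Organisms in the comparative analysis were sampled on different grids over
36 h, so standardized courses are aligned onto a common hourly grid with
Stineman's monotonicity-preserving rational interpolation before computing
Pearson correlations.  Orthologs are called by reciprocal best hit over a
pairwise similarity table (a built-in k-mer scorer or any user-supplied
scores), and a co-expression network connects genes whose courses
correlate above a threshold (0.5 for the conservative view, 0.2 for the
exploratory one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import standardize
from .matrixio import ExpressionMatrix

__all__ = [
    "stineman_interpolate",
    "common_grid",
    "align_to_grid",
    "kmer_similarity_scores",
    "reciprocal_best_hits",
    "OrthologPair",
    "DielNetwork",
    "build_network",
]

logger = logging.getLogger(__name__)


def _stineman_slopes(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Slope estimates for Stineman interpolation.

    Interior slopes start from the tangents of the circle through a point
    and its two neighbours (the secant for collinear triples); endpoint
    slopes are extrapolated from the first/last secant with the
    sign-preserving rule.  Slopes are then limited to at most three times
    the smaller adjacent secant (zero where the secants change sign), the
    standard monotonicity-consistent restriction: within each interval the
    rational interpolant is monotone whenever both end slopes share the
    secant's sign and stay below ~4x its magnitude.
    """
    dt = np.diff(t)
    dx = np.diff(x)
    m = dx / dt
    n = t.size
    yp = np.empty(n)
    if n == 2:
        yp[:] = m[0]
        return yp
    # circle tangents at interior knots; for collinear triples the formula
    # reduces exactly to the shared secant (denominator is positive since
    # dt > 0)
    chord2 = dt**2 + dx**2
    num = dx[:-1] * chord2[1:] + dx[1:] * chord2[:-1]
    den = dt[:-1] * chord2[1:] + dt[1:] * chord2[:-1]
    yp[1:-1] = num / den

    def endpoint(s: float, yp_next: float) -> float:
        if (s >= 0 and s >= yp_next) or (s <= 0 and s <= yp_next):
            return 2.0 * s - yp_next
        denom = abs(s) + abs(s - yp_next)
        return s + abs(s) * (s - yp_next) / denom if denom else s

    yp[0] = endpoint(m[0], yp[1])
    yp[-1] = endpoint(m[-1], yp[-2])
    # monotonicity-consistent limiting
    for i in range(n):
        left = m[i - 1] if i > 0 else m[0]
        right = m[i] if i < n - 1 else m[-1]
        if left * right < 0:
            yp[i] = 0.0
        else:
            cap = 3.0 * min(abs(left), abs(right))
            yp[i] = float(np.clip(yp[i], -cap, cap))
            if left + right != 0 and yp[i] * (left + right) < 0:
                yp[i] = 0.0
    return yp


def stineman_interpolate(t_known, x_known, t_query) -> np.ndarray:
    """Stineman (1980) rational interpolation through all knots.

    Reproduces exactly linear data exactly, passes through every knot, and
    never overshoots: monotone knots yield a monotone interpolant.
    Queries outside the knot span raise (no extrapolation).
    """
    t = np.asarray(t_known, dtype=float)
    x = np.asarray(x_known, dtype=float)
    q = np.atleast_1d(np.asarray(t_query, dtype=float))
    if t.ndim != 1 or t.size < 2 or t.shape != x.shape:
        raise ValueError("need >= 2 knots with matching value vector")
    if (np.diff(t) <= 0).any():
        raise ValueError("knot hours must be strictly increasing")
    if (q < t[0]).any() or (q > t[-1]).any():
        raise ValueError(
            f"query outside knot span [{t[0]:g}, {t[-1]:g}]; extrapolation refused"
        )
    yp = _stineman_slopes(t, x)
    idx = np.clip(np.searchsorted(t, q, side="right") - 1, 0, t.size - 2)
    t0, t1 = t[idx], t[idx + 1]
    x0, x1 = x[idx], x[idx + 1]
    s = (x1 - x0) / (t1 - t0)
    base = x0 + s * (q - t0)          # secant (linear) part
    d0 = (yp[idx] - s) * (q - t0)      # tangent-line deviations at both ends
    d1 = (yp[idx + 1] - s) * (q - t1)
    prod = d0 * d1
    out = base.copy()
    pos = prod > 0
    neg = prod < 0
    out[pos] += prod[pos] / (d0 + d1)[pos]
    if neg.any():
        out[neg] += prod[neg] * (2 * q[neg] - t0[neg] - t1[neg]) / (
            (d0 - d1)[neg] * (t1 - t0)[neg]
        )
    return out


def common_grid(spans: list[tuple[float, float]], stop: float = 36.0, step: float = 1.0) -> np.ndarray:
    """Hourly (by default) grid from the latest series start to the
    earliest series end, capped at ``stop``.  No cyclic extension is
    performed, so the grid never leaves any organism's observed span."""
    start = max(s for s, _ in spans)
    end = min(min(e for _, e in spans), stop)
    if end <= start:
        raise ValueError("organism series do not overlap in time")
    n = int(np.floor((end - start) / step + 1e-9))
    return start + step * np.arange(n + 1)


def align_to_grid(
    matrix: ExpressionMatrix,
    grid: np.ndarray,
    min_points: int = 4,
) -> pd.DataFrame:
    """Standardized gene courses evaluated on a common grid.

    Genes observed at fewer than ``min_points`` time points (or constant)
    are excluded with a logged count.  The grid must lie inside the
    organism's observed span.
    """
    hours = matrix.hours
    grid = np.asarray(grid, dtype=float)
    if grid.min() < hours.min() or grid.max() > hours.max():
        raise ValueError("grid extends outside this organism's observed hours")
    if len(hours) < min_points:
        raise ValueError(f"series has fewer than {min_points} time points")
    z, excluded = standardize(matrix)
    if excluded:
        logger.info("align_to_grid excluded %d constant genes", len(excluded))
    order = np.argsort(hours)
    t_sorted = hours[order]
    rows = {
        gene: stineman_interpolate(t_sorted, z.loc[gene].to_numpy()[order], grid)
        for gene in z.index
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=[f"h{h:g}" for h in grid])


def kmer_similarity_scores(
    seqs_a: dict[str, str],
    seqs_b: dict[str, str],
    k: int = 11,
) -> pd.DataFrame:
    """Shared k-mer count normalized by the shorter sequence's k-mer count.

    A desk-scale similarity for reciprocal-best-hit ortholog calling,
    swappable for any user-supplied score table.
    """
    def kmers(s: str) -> set[str]:
        s = s.upper()
        return {s[i:i + k] for i in range(len(s) - k + 1)}

    ka = {g: kmers(s) for g, s in seqs_a.items()}
    kb = {g: kmers(s) for g, s in seqs_b.items()}
    scores = pd.DataFrame(0.0, index=list(seqs_a), columns=list(seqs_b))
    for ga, sa in ka.items():
        for gb, sb in kb.items():
            denom = min(len(sa), len(sb))
            scores.at[ga, gb] = len(sa & sb) / denom if denom else 0.0
    return scores


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal best hit between two genomes."""

    gene_a: str
    gene_b: str
    score_ab: float
    score_ba: float


def reciprocal_best_hits(
    scores_ab: pd.DataFrame,
    scores_ba: pd.DataFrame,
) -> list[OrthologPair]:
    """Pairs where each gene is the other's unique best hit.

    ``scores_ab`` scores A genes (rows) against B genes (columns) and
    ``scores_ba`` the reverse.  Tied best hits yield no pair (logged).
    """
    if set(scores_ab.index) != set(scores_ba.columns) or set(scores_ab.columns) != set(scores_ba.index):
        raise ValueError("score matrices do not cover the same gene sets")
    pairs: list[OrthologPair] = []
    n_ties = 0
    for ga in scores_ab.index:
        row = scores_ab.loc[ga]
        best = row.max()
        hits = row.index[row == best]
        if len(hits) != 1:
            n_ties += 1
            continue
        gb = hits[0]
        back = scores_ba.loc[gb]
        best_back = back.max()
        back_hits = back.index[back == best_back]
        if len(back_hits) != 1:
            n_ties += 1
            continue
        if back_hits[0] == ga:
            pairs.append(OrthologPair(str(ga), str(gb), float(best), float(best_back)))
    if n_ties:
        logger.info("reciprocal_best_hits skipped %d genes with tied best hits", n_ties)
    return pairs


@dataclass
class DielNetwork:
    """Correlation-thresholded co-expression graph on the common grid."""

    graph: nx.Graph
    threshold: float
    correlations: pd.DataFrame  # full pairwise r, nodes x nodes

    @property
    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "r": d["r"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "r"])

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)

    def degrees(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree()), name="degree")


def build_network(
    courses: pd.DataFrame,
    threshold: float = 0.5,
    include_anticorrelated: bool = False,
    node_attrs: pd.DataFrame | None = None,
) -> DielNetwork:
    """Connect genes whose grid courses correlate above ``threshold``.

    Only positive co-expression makes edges unless
    ``include_anticorrelated``, which switches the criterion to |r|.
    ``node_attrs`` (indexed like ``courses``) adds node attributes such as
    organism or annotation tags.
    """
    if len(courses) < 2:
        raise ValueError("need >= 2 courses to build a network")
    arr = courses.to_numpy(dtype=float)
    if (arr.std(axis=1) == 0).any():
        raise ValueError("zero-variance course in network input")
    r = np.corrcoef(arr)
    corr = pd.DataFrame(r, index=courses.index, columns=courses.index)
    g = nx.Graph(threshold=threshold)
    for node in courses.index:
        attrs = node_attrs.loc[node].to_dict() if node_attrs is not None else {}
        g.add_node(node, **attrs)
    nodes = list(courses.index)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            rij = float(r[i, j])
            strength = abs(rij) if include_anticorrelated else rij
            if strength > threshold:
                g.add_edge(nodes[i], nodes[j], r=rij)
    return DielNetwork(g, threshold, corr)
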