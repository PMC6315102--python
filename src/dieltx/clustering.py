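"""Peak-phase clustering of standardized diel courses.

Each gene's course is standardized across time points (mean 0, sd 1), the
pairwise distance is 1 - Pearson r, and genes are grouped by
complete-linkage hierarchical clustering cut into k groups (the emulated
analysis used k = 4 phase clades).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .matrixio import ExpressionMatrix

__all__ = [
    "standardize",
    "pearson_distance_matrix",
    "hierarchical_cluster",
    "cluster_summary",
    "ClusterAssignment",
]

logger = logging.getLogger(__name__)


def standardize(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-scores across time points (sample sd, denominator n-1).

    Returns (z table, excluded constant-gene ids).  Constant genes cannot
    be standardized and are dropped with a logged count.
    """
    v = matrix.values
    if v.shape[1] < 2:
        raise ValueError("standardization needs >= 2 time points")
    sd = v.std(axis=1, ddof=1)
    constant = list(v.index[sd == 0])
    if constant:
        logger.info("excluding %d constant genes from standardization", len(constant))
    keep = v.index[sd > 0]
    z = v.loc[keep].sub(v.loc[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)
    return z, constant


def pearson_distance_matrix(courses: pd.DataFrame) -> pd.DataFrame:
    """d_ij = 1 - Pearson r between gene courses; d in [0, 2]."""
    if len(courses) < 2:
        raise ValueError("need >= 2 courses for a distance matrix")
    arr = courses.to_numpy(dtype=float)
    if (arr.std(axis=1) == 0).any():
        raise ValueError("zero-variance course; standardize/exclude first")
    d = 1.0 - np.corrcoef(arr)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=courses.index, columns=courses.index)


@dataclass
class ClusterAssignment:
    """Gene -> cluster labels (contiguous 1..k)."""

    labels: pd.Series  # index gene_id, values 1..k
    k: int

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def hierarchical_cluster(distance: pd.DataFrame, k: int = 4) -> ClusterAssignment:
    """Complete-linkage agglomeration of a distance matrix, cut into k groups.

    Labels are renumbered 1..k by order of first appearance so the output
    is deterministic for a given input ordering.
    """
    n = len(distance)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    condensed = squareform(distance.to_numpy(dtype=float), checks=False)
    tree = linkage(condensed, method="complete")
    raw = fcluster(tree, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels.append(remap[lab])
    return ClusterAssignment(pd.Series(labels, index=distance.index, name="cluster"), k)


def cluster_summary(
    assignment: ClusterAssignment,
    courses: pd.DataFrame,
    hours: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean standardized course and peak hour per cluster.

    The cluster's peak is the grid hour (mod 24) where its mean course is
    highest.  Returns (summary table, mean-course matrix clusters x hours).
    """
    hours = np.asarray(hours, dtype=float)
    mean_courses = {}
    records = []
    for cluster in sorted(assignment.labels.unique()):
        members = assignment.members(cluster)
        mean_course = courses.loc[members].mean(axis=0).to_numpy()
        mean_courses[cluster] = mean_course
        peak = float(hours[int(np.argmax(mean_course))] % 24.0)
        records.append({"cluster": cluster, "size": len(members), "peak_hour": peak})
    summary = pd.DataFrame.from_records(records)
    mean_df = pd.DataFrame.from_dict(mean_courses, orient="index", columns=list(courses.columns))
    mean_df.index.name = "cluster"
    return summary, mean_df
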