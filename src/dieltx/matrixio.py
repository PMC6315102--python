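"""Expression matrices, probe maps, and tab-separated I/O.

The on-disk format is a plain UTF-8 TSV: first column entity (probe or
gene) identifiers, header row sample labels of the form ``<timecode>_<rep>``
(``L6_1``) or a bare time code when there is a single replicate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .timecourse import (
    SampleDescriptor,
    TimePoint,
    parse_series,
)

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "ProbeMap",
    "read_matrix",
    "write_matrix",
    "matrix_from_frame",
    "read_probe_map",
    "write_probe_map",
    "write_report",
    "read_report",
]


class Scale(Enum):
    """Whether intensity values are raw (linear) or log2-transformed."""

    LINEAR = "linear"
    LOG2 = "log2"


@dataclass
class ExpressionMatrix:
    """An entities x samples intensity table with an explicit scale.

    ``values`` is a DataFrame indexed by entity id with one column per
    sample id; ``samples`` carries the parsed time point and replicate for
    each column, in column order.
    """

    values: pd.DataFrame
    samples: list[SampleDescriptor]
    scale: Scale

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate entity ids: {dups}")
        if list(v.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("sample descriptors do not match matrix columns")
        arr = v.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.scale is Scale.LINEAR and (arr < 0).any():
            raise ValueError("linear-scale intensities must be >= 0")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def time_points(self) -> list[TimePoint]:
        return [s.time_point for s in self.samples]

    @property
    def hours(self) -> np.ndarray:
        return np.array([s.time_point.absolute_hour for s in self.samples])

    def subset_entities(self, ids: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(ids)])

    def with_values(self, values: pd.DataFrame, scale: Scale | None = None) -> "ExpressionMatrix":
        """New matrix with the same sample structure and new values."""
        return ExpressionMatrix(values, list(self.samples), scale or self.scale)


@dataclass
class ProbeMap:
    """Probe -> gene assignment (each probe maps to exactly one gene)."""

    table: pd.DataFrame  # columns: probe_id, gene_id

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns) != ["probe_id", "gene_id"]:
            raise ValueError("probe map needs columns probe_id, gene_id")
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValueError(f"probes mapped more than once: {dup}")

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.table["gene_id"]))

    def probes_for(self, gene_id: str) -> list[str]:
        t = self.table
        return t.loc[t["gene_id"] == gene_id, "probe_id"].tolist()

    def gene_of(self, probe_id: str) -> str:
        t = self.table.set_index("probe_id")
        return str(t.loc[probe_id, "gene_id"])


def _parse_header(
    columns: Sequence[str],
    photoperiod_hours: float,
    dark_first: bool,
    organism: str,
) -> list[SampleDescriptor]:
    labels: list[str] = []
    reps: list[str] = []
    for col in columns:
        label, _, rep = col.rpartition("_")
        if not label:
            label, rep = col, "1"
        labels.append(label)
        reps.append(rep)
    # Resolve unique time codes in order of first appearance so replicate
    # columns share one TimePoint.
    unique = list(dict.fromkeys(labels))
    tps = dict(zip(unique, parse_series(unique, photoperiod_hours, dark_first)))
    return [
        SampleDescriptor(sample_id=col, time_point=tps[label], replicate_id=rep, organism=organism)
        for col, label, rep in zip(columns, labels, reps)
    ]


def read_matrix(
    path: str | Path,
    scale: Scale,
    photoperiod_hours: float = 12.0,
    dark_first: bool = False,
    organism: str = "",
) -> ExpressionMatrix:
    """Read a TSV intensity matrix, parsing sample time codes from the header.

    Non-numeric cells, ragged rows and duplicate entity ids are rejected
    with messages naming the offending location.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate entity ids in {path}: {dups}")
    numeric = raw.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    bad = numeric.isna()
    if bad.to_numpy().any():
        cells = [
            f"({row}, {col})={raw.at[row, col]!r}"
            for row in raw.index
            for col in raw.columns
            if bad.at[row, col]
        ]
        raise ValueError(f"non-numeric cells in {path}: " + ", ".join(cells[:10]))
    samples = _parse_header(list(numeric.columns), photoperiod_hours, dark_first, organism)
    return ExpressionMatrix(numeric.astype(float), samples, scale)


def matrix_from_frame(
    values: pd.DataFrame,
    scale: Scale,
    photoperiod_hours: float = 12.0,
    dark_first: bool = False,
    organism: str = "",
) -> ExpressionMatrix:
    """Build a matrix from a DataFrame whose columns are sample labels
    (``L6_1`` style), parsing time codes exactly like :func:`read_matrix`."""
    samples = _parse_header(list(values.columns), photoperiod_hours, dark_first, organism)
    return ExpressionMatrix(values.astype(float), samples, scale)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = out.index.name or "id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_probe_map(path: str | Path) -> ProbeMap:
    t = pd.read_csv(path, sep="\t", dtype=str)
    return ProbeMap(t[["probe_id", "gene_id"]])


def write_probe_map(pmap: ProbeMap, path: str | Path) -> None:
    pmap.table.to_csv(path, sep="\t", index=False)


def write_report(result, path: str | Path) -> None:
    """Write a pipeline result: DataFrames as TSV, mappings as sorted JSON."""
    path = Path(path)
    if isinstance(result, pd.DataFrame):
        result.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif isinstance(result, dict):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise TypeError(f"cannot serialize result of type {type(result).__name__}")


def read_report(path: str | Path):
    path = Path(path)
    if path.suffix == ".json":
        with open(path, encoding="utf-8") as fh:
            return json.load(fh)
    return pd.read_csv(path, sep="\t")
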