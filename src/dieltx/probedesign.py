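"""Oligonucleotide probe selection for a custom expression array.

Candidate 60-mers are tiled evenly along each gene, then pass a cascade:

1. cross-hybridization: drop probes with a full-length gapless match at
   >= 95% identity anywhere in an off-target sequence database (both
   strands; hybridization tolerates ~5% mismatch over the whole probe),
2. redundancy: greedy clustering at 95% identity keeps one representative
   per cluster,
3. strain specificity: drop probes matching the sister strain's genes at
   >= 95% identity, except probes of whitelisted conserved genes (the
   nitrogenase-gene scenario), which are retained with a recorded note.

The scan is an exhaustive gapless sliding window (identity =
matches/length over 100% of the probe), which captures the full-length
identity criterion at desk scale without gapped alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "ProbeStatus",
    "ProbeCandidate",
    "tile_candidates",
    "cross_hyb_filter",
    "redundancy_cluster",
    "strain_specificity_filter",
    "run_cascade",
    "CascadeReport",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


class ProbeStatus(Enum):
    """Filter outcome; transitions only ever leave KEPT."""

    KEPT = "kept"
    CROSS_HYB = "cross_hyb"
    REDUNDANT = "redundant"
    STRAIN_SHARED = "strain_shared"


@dataclass(frozen=True)
class ProbeCandidate:
    """A candidate oligo: 0-based plus-strand window on its gene."""

    probe_id: str
    gene_id: str
    sequence: str
    start: int
    status: ProbeStatus = ProbeStatus.KEPT
    evidence: str = ""


def _check_sequence(name: str, seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"sequence {name!r} contains non-ACGT characters: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def tile_candidates(
    gene_id: str,
    sequence: str,
    n_probes: int = 6,
    length: int = 60,
) -> list[ProbeCandidate]:
    """Evenly spaced, deduplicated probe windows along a gene.

    Short genes yield fewer probes; genes shorter than the probe length
    yield none.
    """
    seq = _check_sequence(gene_id, sequence)
    span = len(seq) - length
    if span < 0:
        return []
    n = min(n_probes, span + 1)
    offsets = sorted({int(round(o)) for o in np.linspace(0, span, n)})
    return [
        ProbeCandidate(f"{gene_id}_p{i + 1}", gene_id, seq[o:o + length], o)
        for i, o in enumerate(offsets)
    ]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _best_window_identity(probe: np.ndarray, target: np.ndarray) -> float:
    """Best gapless identity of any equal-length window of ``target``."""
    L = probe.size
    if target.size < L:
        return 0.0
    windows = np.lib.stride_tricks.sliding_window_view(target, L)
    matches = (windows == probe).sum(axis=1)
    return float(matches.max()) / L


def _best_hit(
    probe_seq: str,
    targets: dict[str, str],
    exclude: str | None = None,
) -> tuple[float, str, str]:
    """Best identity over both strands of every target; (identity, id, strand)."""
    probe = _encode(probe_seq)
    best = (0.0, "", "+")
    for tid, tseq in targets.items():
        if tid == exclude:
            continue
        fwd = _best_window_identity(probe, _encode(tseq))
        if fwd > best[0]:
            best = (fwd, tid, "+")
        rev = _best_window_identity(probe, _encode(reverse_complement(tseq)))
        if rev > best[0]:
            best = (rev, tid, "-")
    return best


def cross_hyb_filter(
    probes: list[ProbeCandidate],
    off_target_db: dict[str, str],
    min_identity: float = 0.95,
) -> list[ProbeCandidate]:
    """Mark probes with a full-length off-target match >= min_identity."""
    db = {tid: _check_sequence(tid, s) for tid, s in off_target_db.items()}
    out = []
    for p in probes:
        if p.status is not ProbeStatus.KEPT:
            out.append(p)
            continue
        ident, tid, strand = _best_hit(p.sequence, db, exclude=p.gene_id)
        if ident >= min_identity:
            out.append(replace(p, status=ProbeStatus.CROSS_HYB,
                               evidence=f"{tid}({strand}):{ident:.3f}"))
        else:
            out.append(p)
    return out


def _identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("redundancy identity compares equal-length probes")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def redundancy_cluster(
    probes: list[ProbeCandidate],
    threshold: float = 0.95,
) -> list[ProbeCandidate]:
    """Greedy clustering in input order at ``threshold`` identity.

    A probe joins the first cluster whose representative it matches and is
    marked REDUNDANT; otherwise it founds a new cluster and stays KEPT.
    """
    representatives: list[ProbeCandidate] = []
    out = []
    for p in probes:
        if p.status is not ProbeStatus.KEPT:
            out.append(p)
            continue
        rep = next(
            (r for r in representatives if _identity(p.sequence, r.sequence) >= threshold),
            None,
        )
        if rep is None:
            representatives.append(p)
            out.append(p)
        else:
            out.append(replace(p, status=ProbeStatus.REDUNDANT,
                               evidence=f"cluster:{rep.probe_id}"))
    return out


def strain_specificity_filter(
    probes: list[ProbeCandidate],
    other_strain_genes: dict[str, str],
    threshold: float = 0.95,
    whitelist: frozenset[str] | set[str] = frozenset(),
) -> list[ProbeCandidate]:
    """Drop probes matching the other strain unless their gene is whitelisted.

    Whitelisted conserved genes keep their probes with the cross-strain
    evidence recorded.
    """
    db = {tid: _check_sequence(tid, s) for tid, s in other_strain_genes.items()}
    out = []
    for p in probes:
        if p.status is not ProbeStatus.KEPT:
            out.append(p)
            continue
        ident, tid, strand = _best_hit(p.sequence, db)
        if ident >= threshold:
            if p.gene_id in whitelist:
                out.append(replace(p, evidence=f"retained_conserved:{tid}({strand}):{ident:.3f}"))
            else:
                out.append(replace(p, status=ProbeStatus.STRAIN_SHARED,
                                   evidence=f"{tid}({strand}):{ident:.3f}"))
        else:
            out.append(p)
    return out


@dataclass
class CascadeReport:
    """Per-stage attrition; removals sum to candidates - kept."""

    n_candidates: int
    n_cross_hyb: int
    n_redundant: int
    n_strain_shared: int

    @property
    def n_kept(self) -> int:
        return self.n_candidates - self.n_cross_hyb - self.n_redundant - self.n_strain_shared

    def as_dict(self) -> dict[str, int]:
        return {
            "candidates": self.n_candidates,
            "removed_cross_hyb": self.n_cross_hyb,
            "removed_redundant": self.n_redundant,
            "removed_strain_shared": self.n_strain_shared,
            "kept": self.n_kept,
        }


def run_cascade(
    genes: dict[str, str],
    off_target_db: dict[str, str],
    other_strain_genes: dict[str, str],
    whitelist: frozenset[str] | set[str] = frozenset(),
    n_probes: int = 6,
    length: int = 60,
    min_identity: float = 0.95,
) -> tuple[list[ProbeCandidate], CascadeReport]:
    """Tile + cross-hyb + redundancy + strain specificity, in that order."""
    probes: list[ProbeCandidate] = []
    for gid, seq in genes.items():
        probes.extend(tile_candidates(gid, seq, n_probes, length))
    probes = cross_hyb_filter(probes, off_target_db, min_identity)
    probes = redundancy_cluster(probes, min_identity)
    probes = strain_specificity_filter(probes, other_strain_genes, min_identity, whitelist)
    counts = {status: sum(p.status is status for p in probes) for status in ProbeStatus}
    report = CascadeReport(
        n_candidates=len(probes),
        n_cross_hyb=counts[ProbeStatus.CROSS_HYB],
        n_redundant=counts[ProbeStatus.REDUNDANT],
        n_strain_shared=counts[ProbeStatus.STRAIN_SHARED],
    )
    return probes, report
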