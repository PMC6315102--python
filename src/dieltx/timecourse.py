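"""Diel time labels and sample descriptors.

Samples in light/dark time-course experiments are labelled with codes such
as ``L6`` (6 h into the light period), ``D3`` (3 h into the dark period) or
``2L12`` (12 h into the light period of the second light/dark cycle).  This
module parses those labels onto a continuous hour axis whose origin is the
first sunrise (light onset) of cycle 1 — or the first sunset for dark-first
experiments.

Two parsing entry points exist:

``parse_time_label``
    Context-free parsing with a fixed convention (see below).
``parse_series``
    Sequence-aware parsing: each label receives the smallest admissible
    absolute hour greater than its predecessor's.  Published series
    sometimes leave the cycle prefix implicit (a ``D1`` sampled in the
    second night), which only the ordering of the series disambiguates.

Convention for the context-free parser: the phase that closes a 24-h day
(dark for light-first regimes) may be labelled with its full phase length to
denote the day boundary itself, so under 12 h/12 h light-first ``D12`` is
hour 0 and ``2D12`` is hour 24.  Every other label maps to
``24*(cycle-1) + phase_start + hour_in_phase``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Phase",
    "TimePoint",
    "SampleDescriptor",
    "LabelParseError",
    "parse_time_label",
    "parse_series",
    "format_time_label",
    "UCYNA_LABELS",
    "TRICHODESMIUM_LABELS",
    "CYANOTHECE_LABELS",
    "CROCOSPHAERA_LABELS",
    "PROCHLOROCOCCUS_LABELS",
]


class Phase(Enum):
    """Photoperiod phase of a diel sample."""

    LIGHT = "L"
    DARK = "D"


class LabelParseError(ValueError):
    """Raised for malformed or inconsistent diel time labels."""


_LABEL_RE = re.compile(r"^(2)?([LD])([0-9]+)$")

# Published sampling grids (one per organism in the comparative analysis).
UCYNA_LABELS = ("L6", "L9", "D3", "D6", "2D12", "2L3", "2L9", "2L12")
TRICHODESMIUM_LABELS = ("D12", "L3", "L6", "L9", "L12", "D3", "D6", "D9", "2D12")
CYANOTHECE_LABELS = ("L2", "L6", "L10", "D2", "D6", "D10")
CROCOSPHAERA_LABELS = ("D11", "L1", "L6", "L11", "D1", "D6", "2D11", "2L1")
PROCHLOROCOCCUS_LABELS = (
    "D12", "L2", "L4", "L6", "L8", "L10", "L12",
    "D2", "D4", "D6", "D8", "D10", "2D12",
    "2L2", "2L4", "2L6", "2L8", "2L10", "2L12",
)


@dataclass(frozen=True)
class TimePoint:
    """A parsed diel time label.

    Attributes
    ----------
    raw_label : str
        The label as written, e.g. ``"2L12"``.
    cycle_index : int
        Light/dark cycle number (1 unless the label is prefixed ``2``, or
        inferred from sequence context by :func:`parse_series`).
    phase : Phase
        Light or dark.
    hour_in_phase : int
        Hours since entry into the phase (1-based, <= phase length).
    absolute_hour : float
        Hours since the experiment's reference sunrise (sunset if
        dark-first).
    """

    raw_label: str
    cycle_index: int
    phase: Phase
    hour_in_phase: int
    absolute_hour: float

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.raw_label}@{self.absolute_hour}h"


@dataclass(frozen=True)
class SampleDescriptor:
    """One array/sample column: identity, time point, replicate, organism."""

    sample_id: str
    time_point: TimePoint
    replicate_id: str = "1"
    organism: str = ""


def _split_label(label: str) -> tuple[int, Phase, int]:
    m = _LABEL_RE.match(label)
    if m is None:
        raise LabelParseError(f"malformed diel time label: {label!r}")
    cycle = 2 if m.group(1) else 1
    phase = Phase(m.group(2))
    hour = int(m.group(3))
    if hour < 1:
        raise LabelParseError(f"hour in label {label!r} must be >= 1")
    return cycle, phase, hour


def _phase_lengths(photoperiod_hours: float) -> tuple[float, float]:
    if not 0 < photoperiod_hours < 24:
        raise ValueError("photoperiod_hours must be in (0, 24)")
    return photoperiod_hours, 24.0 - photoperiod_hours


def _absolute_hour(
    cycle: int,
    phase: Phase,
    hour: int,
    photoperiod_hours: float,
    dark_first: bool,
) -> float:
    light_len, dark_len = _phase_lengths(photoperiod_hours)
    if dark_first:
        first, first_len = Phase.DARK, dark_len
        second_len = light_len
    else:
        first, first_len = Phase.LIGHT, light_len
        second_len = dark_len
    if phase is first:
        phase_start, phase_len = 0.0, first_len
        terminal = False
    else:
        phase_start, phase_len = first_len, second_len
        terminal = True  # this phase closes the 24-h day
    if hour > phase_len:
        raise LabelParseError(
            f"hour {hour} exceeds the {phase.name.lower()} phase length "
            f"({phase_len:g} h)"
        )
    if terminal and hour == phase_len:
        # Full-length terminal-phase label denotes the day boundary itself:
        # under 12/12 light-first, D12 == hour 0 and 2D12 == hour 24.
        return 24.0 * (cycle - 1)
    return 24.0 * (cycle - 1) + phase_start + hour


def parse_time_label(
    label: str,
    photoperiod_hours: float = 12.0,
    dark_first: bool = False,
) -> TimePoint:
    """Parse a single diel time label with the fixed convention.

    Raises
    ------
    LabelParseError
        If the label is malformed or its hour exceeds the phase length.
    """
    cycle, phase, hour = _split_label(label)
    absolute = _absolute_hour(cycle, phase, hour, photoperiod_hours, dark_first)
    return TimePoint(label, cycle, phase, hour, absolute)


def parse_series(
    labels: Sequence[str],
    photoperiod_hours: float = 12.0,
    dark_first: bool = False,
    max_cycles: int = 4,
) -> list[TimePoint]:
    """Parse an ordered label sequence onto strictly increasing hours.

    Each label is assigned the smallest absolute hour consistent with its
    phase and hour-in-phase that is strictly greater than the previous
    label's hour (the first label takes the smallest hour >= 0).  Labels
    carrying an explicit cycle prefix keep that cycle; unprefixed labels may
    be promoted to a later cycle when the ordering requires it, which is how
    published series denote, e.g., a second-night ``D6``.
    """
    out: list[TimePoint] = []
    previous = -1.0
    for label in labels:
        cycle, phase, hour = _split_label(label)
        cycles = [cycle] if cycle > 1 else list(range(1, max_cycles + 1))
        candidates: list[tuple[float, int]] = []
        for c in cycles:
            try:
                candidates.append(
                    (_absolute_hour(c, phase, hour, photoperiod_hours, dark_first), c)
                )
            except LabelParseError:
                raise
        # A prefixed terminal full-length label (2D12) maps to the day
        # boundary; its plain reading (cycle 2 dark, hour 12 -> h 48) is
        # also admissible if the boundary reading would break the ordering.
        light_len, dark_len = _phase_lengths(photoperiod_hours)
        terminal_phase = Phase.LIGHT if dark_first else Phase.DARK
        terminal_len = light_len if dark_first else dark_len
        if phase is terminal_phase and hour == terminal_len:
            first_len = dark_len if dark_first else light_len
            for c in cycles:
                candidates.append((24.0 * (c - 1) + first_len + hour, c))
        admissible = sorted(
            (h, c) for h, c in candidates if (h > previous or (not out and h >= 0))
        )
        if not admissible:
            raise LabelParseError(
                f"label {label!r} cannot continue a strictly increasing series "
                f"after hour {previous:g}"
            )
        absolute, resolved_cycle = admissible[0]
        out.append(TimePoint(label, resolved_cycle, phase, hour, absolute))
        previous = absolute
    return out


def format_time_label(tp: TimePoint) -> str:
    """Inverse of :func:`parse_time_label`: rebuild the label text."""
    prefix = "2" if tp.cycle_index == 2 else ""
    if tp.cycle_index > 2:
        raise ValueError("labels only encode cycles 1 and 2")
    return f"{prefix}{tp.phase.value}{tp.hour_in_phase}"


def absolute_hours(samples: Iterable[SampleDescriptor]) -> list[float]:
    """Absolute hours of a sample collection, in order."""
    return [s.time_point.absolute_hour for s in samples]
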