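"""Segmentation of germination-mode traces into resting and oscillation phases.

A germinating wild-type pollen grain shows a stereotyped anatomy: a first
resting phase (RePh1), a train of small-amplitude oscillations (CaOscS), a
second resting phase (RePh2), a train of large-amplitude oscillations
(CaOscL) that culminates in tube protrusion, and a final resting phase
(RePh3).  When germination does not occur, CaOscS -> RePh2 -> CaOscL -> RePh3
modules recur; repeats are labelled with an ``_r<k>`` suffix so a single
left-to-right pass yields an unambiguous grammar.

Segmentation is greedy over the classified event list: an event-free gap of
at least ``rest_min_gap`` seconds opens a resting segment; runs of events
with shorter gaps form oscillation segments; a run that contains a large
event is split at the first large event's onset, promoting the remainder to
CaOscL (large trains are the later, propagating component).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .spikes import SpikeEvent

#: Minimum event count before an oscillation phase is considered well-populated.
SPARSE_PHASE_EVENTS = 3


@dataclass(frozen=True)
class SegmentationConfig:
    """``rest_min_gap_s``: minimum event-free interval opening a resting phase."""

    rest_min_gap_s: float = 600.0

    def __post_init__(self) -> None:
        if self.rest_min_gap_s <= 0:
            raise InvalidInputError("rest_min_gap_s must be positive")


@dataclass(frozen=True)
class PhaseSegment:
    label: str  # RePh1 | CaOscS | RePh2 | CaOscL | RePh3 (+ _r<k> for repeats)
    start_time: float
    end_time: float
    n_events: int
    sparse: bool = False  # oscillation phase with fewer than SPARSE_PHASE_EVENTS

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def base_label(self) -> str:
        return self.label.split("_r")[0]

    @property
    def is_resting(self) -> bool:
        return self.base_label.startswith("RePh")


def _runs(events: list[SpikeEvent], gap: float) -> list[list[SpikeEvent]]:
    runs: list[list[SpikeEvent]] = [[events[0]]]
    for prev, ev in zip(events, events[1:]):
        if ev.onset_time - prev.offset_time >= gap:
            runs.append([ev])
        else:
            runs[-1].append(ev)
    return runs


def segment_phases(
    events: list[SpikeEvent],
    span_s: float,
    cfg: SegmentationConfig | None = None,
) -> list[PhaseSegment]:
    """Tile [0, span_s] with labelled resting/oscillation segments.

    An all-quiet trace yields a single RePh1 segment — the signature of a
    strongly impaired grain.  Oscillation segments span first event onset to
    last event offset; resting segments fill the gaps regardless of length so
    the tiling is exact (the ``rest_min_gap`` criterion governs where trains
    are split, not whether the filler is emitted).
    """
    cfg = cfg or SegmentationConfig()
    if span_s <= 0:
        raise InvalidInputError("span must be positive")
    if not events:
        return [PhaseSegment("RePh1", 0.0, span_s, 0)]
    events = sorted(events, key=lambda e: e.peak_time)

    # oscillation intervals: (class, start, end, events)
    osc: list[tuple[str, float, float, list[SpikeEvent]]] = []
    for run in _runs(events, cfg.rest_min_gap_s):
        large_idx = next((i for i, e in enumerate(run) if e.spike_class == "large"), None)
        if large_idx is None:
            osc.append(("S", run[0].onset_time, run[-1].offset_time, run))
        else:
            if large_idx > 0:
                split = run[large_idx].onset_time
                osc.append(("S", run[0].onset_time, split, run[:large_idx]))
                osc.append(("L", split, run[-1].offset_time, run[large_idx:]))
            else:
                osc.append(("L", run[0].onset_time, run[-1].offset_time, run))

    segments: list[PhaseSegment] = []
    module = 0
    last_osc: str | None = None

    def suffix(m: int) -> str:
        return "" if m <= 1 else f"_r{m}"

    cursor = 0.0
    for kind, start, end, run in osc:
        if start > cursor:  # rest filler belongs to the module just finished
            if last_osc is None:
                rest_label = "RePh1"
            elif last_osc == "S":
                rest_label = "RePh2" + suffix(module)
            else:
                rest_label = "RePh3" + suffix(module)
            segments.append(PhaseSegment(rest_label, cursor, start, 0))
        if kind == "S":
            module += 1
        elif module == 0:
            module = 1
        label = ("CaOscS" if kind == "S" else "CaOscL") + suffix(module)
        segments.append(PhaseSegment(label, start, end, len(run), sparse=len(run) < SPARSE_PHASE_EVENTS))
        cursor = end
        last_osc = kind
    if cursor < span_s:
        rest_label = ("RePh2" if last_osc == "S" else "RePh3") + suffix(module)
        segments.append(PhaseSegment(rest_label, cursor, span_s, 0))
    return segments


def count_modules(segments: list[PhaseSegment]) -> int:
    """Number of completed CaOscS -> (rest) -> CaOscL modules.

    Resting segments between the trains are optional (they are absent when
    gaps are short); a CaOscL train with no preceding small train, or a small
    train never followed by a large one, does not complete a module.
    """
    count = 0
    pending_small = False
    for seg in segments:
        base = seg.base_label
        if base == "CaOscS":
            pending_small = True
        elif base == "CaOscL":
            if pending_small:
                count += 1
            pending_small = False
    return count


def resting_duration(segments: list[PhaseSegment], label: str = "RePh1") -> float:
    """Total duration of resting segments with the given base label."""
    return float(sum(s.duration for s in segments if s.base_label == label))


def module_completion(segments: list[PhaseSegment]) -> bool:
    """Whether at least one full small->large module completed."""
    return count_modules(segments) >= 1


def segments_to_array(segments: list[PhaseSegment]) -> np.ndarray:
    """(n, 2) array of [start, end] for quick numeric checks."""
    return np.array([[s.start_time, s.end_time] for s in segments])
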