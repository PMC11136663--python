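"""Calcium-transient detection and small/large classification on dF/F0 traces.

Events are local maxima of the (optionally smoothed) dF/F0 exceeding a
detection floor, separated by a minimum gap.  The class boundary follows the
fluorescence-fold criteria used for pollen recordings: small oscillation
events (CaOsc^S) reach roughly 2-3x the baseline fluorescence and large
events (CaOsc^L) 5x or more, i.e. in dF/F0 units the detection floor defaults
to 1.0 (F/F0 = 2) and the large-class boundary to 4.0 (F/F0 = 5).  Events in
between are classed small: "5x or more" is the only sharp criterion, so it is
the sole class boundary.

Detection semantics (kept deliberately explicit so an exhaustive brute-force
scan can reproduce them frame by frame):

1. smooth with a centred moving average of ``smoothing_width`` frames
   (reflect padding; width 1 = no smoothing);
2. candidate indices are interior local maxima of the smoothed series, with
   plateaus attributed to their first frame;
3. each candidate is refined to the raw-trace maximum within half the
   smoothing window, and the *raw* refined value must reach the detection
   floor (smoothing localizes, it does not measure);
4. candidates are accepted greedily by descending raw peak height, rejecting
   any peak closer than ``min_gap_s`` to an accepted one;
5. onset/offset are the nearest frames at or below ``onset_fraction`` of the
   peak on either side, with offsets clipped to the next event's onset so
   events never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .preprocess import DffTrace


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable thresholds for transient detection (dF/F0 units, seconds)."""

    detect_min_dff: float = 1.0
    large_min_dff: float = 4.0
    onset_fraction: float = 0.2
    min_gap_s: float | None = None  # None -> 2 frame intervals
    smoothing_width: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.detect_min_dff < self.large_min_dff):
            raise InvalidInputError("need 0 < detect_min_dff < large_min_dff")
        if not (0 < self.onset_fraction < 1):
            raise InvalidInputError("onset_fraction must be in (0, 1)")
        if self.smoothing_width < 1 or self.smoothing_width % 2 == 0:
            raise InvalidInputError("smoothing_width must be an odd positive frame count")
        if self.min_gap_s is not None and self.min_gap_s <= 0:
            raise InvalidInputError("min_gap_s must be positive")

    def resolved_min_gap(self, dt: float) -> float:
        return self.min_gap_s if self.min_gap_s is not None else 2.0 * dt


@dataclass(frozen=True)
class SpikeEvent:
    """One detected calcium transient."""

    peak_time: float
    peak_dff: float
    trough_dff: float
    onset_time: float
    offset_time: float
    spike_class: str  # "small" | "large"

    @property
    def duration(self) -> float:
        return self.offset_time - self.onset_time

    @property
    def prominence(self) -> float:
        """Peak minus following trough (the P - T measure)."""
        return self.peak_dff - self.trough_dff


def classify_spike(peak_dff: float | SpikeEvent, cfg: DetectionConfig | None = None) -> str:
    """Class label from the amplitude criterion: large iff peak >= large_min_dff."""
    cfg = cfg or DetectionConfig()
    v = peak_dff.peak_dff if isinstance(peak_dff, SpikeEvent) else float(peak_dff)
    return "large" if v >= cfg.large_min_dff else "small"


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average with reflect padding (width 1 returns a copy)."""
    if width == 1:
        return np.asarray(x, dtype=float).copy()
    h = width // 2
    padded = np.pad(np.asarray(x, dtype=float), h, mode="reflect")
    kernel = np.full(width, 1.0 / width)
    return np.convolve(padded, kernel, mode="valid")


def detect_spikes(dff: DffTrace, cfg: DetectionConfig | None = None) -> list[SpikeEvent]:
    """Detect and classify transients on a dF/F0 trace; empty list if none."""
    cfg = cfg or DetectionConfig()
    x = np.asarray(dff.dff, dtype=float)
    times = np.asarray(dff.times, dtype=float)
    n = len(x)
    if n < 3:
        return []
    dt = dff.dt
    min_gap = cfg.resolved_min_gap(dt)
    s = moving_average(x, cfg.smoothing_width)
    half = cfg.smoothing_width // 2

    # interior local maxima of the smoothed series; plateau -> first frame
    candidates = [i for i in range(1, n - 1) if s[i] > s[i - 1] and s[i] >= s[i + 1]]

    # refine to the raw maximum within the smoothing half-window
    refined: dict[int, float] = {}
    for i in candidates:
        lo, hi = max(0, i - half), min(n - 1, i + half)
        j = lo + int(np.argmax(x[lo : hi + 1]))
        if 0 < j < n - 1 and x[j] >= cfg.detect_min_dff:
            refined[j] = x[j]

    # greedy acceptance by descending raw height, enforcing the minimum gap
    order = sorted(refined, key=lambda j: (-refined[j], times[j]))
    kept: list[int] = []
    for j in order:
        if all(abs(times[j] - times[k]) >= min_gap for k in kept):
            kept.append(j)
    kept.sort()

    events: list[SpikeEvent] = []
    frac = cfg.onset_fraction
    for idx, j in enumerate(kept):
        thr = frac * x[j]
        k = j - 1
        while k > 0 and x[k] > thr:
            k -= 1
        onset = times[k]
        k = j + 1
        while k < n - 1 and x[k] > thr:
            k += 1
        offset = times[k]
        nxt = kept[idx + 1] if idx + 1 < len(kept) else None
        trough_hi = nxt if nxt is not None else n
        trough = float(np.min(x[j + 1 : trough_hi])) if j + 1 < trough_hi else float(x[min(j + 1, n - 1)])
        events.append(
            SpikeEvent(
                peak_time=float(times[j]),
                peak_dff=float(x[j]),
                trough_dff=trough,
                onset_time=float(onset),
                offset_time=float(offset),
                spike_class=classify_spike(float(x[j]), cfg),
            )
        )

    # enforce non-overlap: clip offsets to the next onset, onsets to the
    # previous offset (keeping onset < peak < offset)
    for i in range(len(events) - 1):
        a, b = events[i], events[i + 1]
        if a.offset_time > b.onset_time:
            new_off = max(b.onset_time, a.peak_time + dt / 2)
            events[i] = SpikeEvent(a.peak_time, a.peak_dff, a.trough_dff, a.onset_time, new_off, a.spike_class)
    for i in range(1, len(events)):
        a, b = events[i - 1], events[i]
        if b.onset_time < a.offset_time:
            new_on = min(a.offset_time, b.peak_time - dt / 2)
            events[i] = SpikeEvent(b.peak_time, b.peak_dff, b.trough_dff, new_on, b.offset_time, b.spike_class)
    return events


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class oscillation statistics; None marks undefined quantities."""

    count: int
    amplitude_mean: float | None = None
    amplitude_sd: float | None = None
    prominence_mean: float | None = None
    duration_mean: float | None = None
    duration_sd: float | None = None
    period_mean: float | None = None
    period_sd: float | None = None
    frequency_per_min: float = 0.0
    first_event_time: float | None = None


@dataclass(frozen=True)
class OscillationMetrics:
    small: ClassMetrics
    large: ClassMetrics

    def for_class(self, label: str) -> ClassMetrics:
        return self.small if label == "small" else self.large


def _class_metrics(events: list[SpikeEvent]) -> ClassMetrics:
    n = len(events)
    if n == 0:
        return ClassMetrics(count=0)
    amps = np.array([e.peak_dff for e in events])
    proms = np.array([e.prominence for e in events])
    durs = np.array([e.duration for e in events])
    peaks = np.array([e.peak_time for e in events])
    periods = np.diff(peaks)
    sd = lambda a: float(a.std(ddof=1)) if len(a) >= 2 else None
    freq = float((n - 1) / ((peaks[-1] - peaks[0]) / 60.0)) if n >= 2 else 0.0
    return ClassMetrics(
        count=n,
        amplitude_mean=float(amps.mean()),
        amplitude_sd=sd(amps),
        prominence_mean=float(proms.mean()),
        duration_mean=float(durs.mean()),
        duration_sd=sd(durs),
        period_mean=float(periods.mean()) if n >= 2 else None,
        period_sd=sd(periods),
        frequency_per_min=freq,
        first_event_time=float(peaks[0]),
    )


def spike_metrics(events: list[SpikeEvent], trace_span_s: float | None = None) -> OscillationMetrics:
    """Amplitude/duration/period/frequency summaries per amplitude class.

    Period is the mean interval between successive same-class peaks (defined
    for counts >= 2); frequency is (count - 1) over the class's active span,
    in events/min, and 0 for counts < 2.
    """
    events = sorted(events, key=lambda e: e.peak_time)
    return OscillationMetrics(
        small=_class_metrics([e for e in events if e.spike_class == "small"]),
        large=_class_metrics([e for e in events if e.spike_class == "large"]),
    )
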