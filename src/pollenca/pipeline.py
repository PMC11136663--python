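"""Per-trace analysis driver: raw trace -> dF/F0 -> events -> metrics -> phases.

This is the glue the CLI, the cohort summaries and the validation scripts
share, so that every trace in a cohort is guaranteed to run through the same
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .phases import PhaseSegment, SegmentationConfig, count_modules, segment_phases
from .preprocess import DffTrace, preprocess_trace
from .spikes import DetectionConfig, OscillationMetrics, SpikeEvent, detect_spikes, spike_metrics
from .trace_io import RawTrace


@dataclass
class TraceResult:
    """Everything computed for one trace."""

    roi_id: str
    genotype: str | None
    osmolarity_mosm: float | None
    dff: DffTrace
    events: list[SpikeEvent]
    metrics: OscillationMetrics
    segments: list[PhaseSegment]
    detection_cfg: DetectionConfig = field(default_factory=DetectionConfig)
    segmentation_cfg: SegmentationConfig = field(default_factory=SegmentationConfig)
    germinated: bool | None = None

    @property
    def module_count(self) -> int:
        return count_modules(self.segments)


def analyze_trace(
    trace: RawTrace,
    correct_bleach: bool = True,
    detection_cfg: DetectionConfig | None = None,
    segmentation_cfg: SegmentationConfig | None = None,
) -> TraceResult:
    """Run the full germination-mode analysis on one raw trace."""
    detection_cfg = detection_cfg or DetectionConfig()
    segmentation_cfg = segmentation_cfg or SegmentationConfig()
    dff = preprocess_trace(trace, correct_bleach=correct_bleach)
    events = detect_spikes(dff, detection_cfg)
    metrics = spike_metrics(events, dff.span_s)
    segments = segment_phases(events, dff.span_s, segmentation_cfg)
    return TraceResult(
        roi_id=trace.roi_id,
        genotype=trace.meta.genotype,
        osmolarity_mosm=trace.meta.osmolarity_mosm,
        dff=dff,
        events=events,
        metrics=metrics,
        segments=segments,
        detection_cfg=detection_cfg,
        segmentation_cfg=segmentation_cfg,
    )


def analyze_cohort(
    records: Sequence,
    correct_bleach: bool = True,
    detection_cfg: DetectionConfig | None = None,
    segmentation_cfg: SegmentationConfig | None = None,
) -> list[TraceResult]:
    """Analyze a synthetic cohort (sequence of records carrying ``.trace``).

    When a record carries ground truth with a germination label, the label is
    copied onto the result so germination fractions can be summarized.
    """
    detection_cfg = detection_cfg or DetectionConfig()
    segmentation_cfg = segmentation_cfg or SegmentationConfig()
    results = []
    for rec in records:
        trace = rec.trace if hasattr(rec, "trace") else rec
        res = analyze_trace(
            trace,
            correct_bleach=correct_bleach,
            detection_cfg=detection_cfg,
            segmentation_cfg=segmentation_cfg,
        )
        truth = getattr(rec, "truth", None)
        if truth is not None:
            res.germinated = truth.germination_time_s is not None
        results.append(res)
    return results
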