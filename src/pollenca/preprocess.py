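"""Raw traces -> bleach-corrected dF/F0 series.

The normalized trace is dF/F0 = (F - F0)/F0, where F0 is the baseline
fluorescence averaged over the first run of ten *stable* frames (coefficient
of variation <= 0.05 by default; the stability criterion is a tunable because
manual analyses rarely state one).  Photobleaching over long recordings is
modelled as a multiplicative mono-exponential B*exp(-lambda*t) fitted to
resting (non-event) frames; the trace is divided by the fitted curve and
rescaled so the baseline-window mean is preserved.  When no event mask is
supplied, an iterative scheme is used: fit on all frames, detect events on
the provisional dF/F0, mask them, refit once.  dF/F0 is computed after the
correction, with F0 taken from the corrected trace.

Ratiometric (e.g. 340/380 nm) inputs are turned into a single ratio trace
that downstream analysis treats exactly like a raw trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    AlignmentError,
    BleachFitError,
    InvalidBaselineError,
    InvalidInputError,
    NoStableBaselineError,
)
from .trace_io import RawTrace, TraceMeta

DEFAULT_BASELINE_WINDOW = 10
DEFAULT_CV_MAX = 0.05
MIN_FIT_FRAMES = 20


@dataclass(frozen=True)
class BleachModel:
    """Fitted photobleaching model.

    ``kind`` is ``"none"``, ``"exponential"`` or ``"linear"``; ``rate`` is the
    exponential decay rate lambda (1/s) or the linear slope fraction (1/s);
    ``n_fit_frames`` counts the resting frames used.
    """

    kind: str = "none"
    rate: float = 0.0
    n_fit_frames: int = 0


@dataclass
class DffTrace:
    """Normalized dF/F0 series with its baseline and bleaching provenance."""

    times: np.ndarray
    dff: np.ndarray
    f0: float
    baseline_frames: tuple[int, int]
    bleach_model: BleachModel = field(default_factory=BleachModel)
    roi_id: str = ""
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if not np.all(np.isfinite(self.dff)):
            raise InvalidInputError("dF/F0 values must be finite")
        if np.any(self.dff < -1.0 - 1e-9):
            raise InvalidInputError("dF/F0 cannot fall below -1 (intensity cannot be negative)")
        if self.f0 <= 0:
            raise InvalidBaselineError(f"F0 must be positive, got {self.f0}")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    @property
    def span_s(self) -> float:
        return float(self.times[-1] - self.times[0])


def find_stable_baseline(
    trace: RawTrace,
    window: int = DEFAULT_BASELINE_WINDOW,
    cv_max: float = DEFAULT_CV_MAX,
) -> tuple[int, int]:
    """Earliest run of ``window`` consecutive frames with CV <= ``cv_max``.

    Returns the half-open index range (start, stop).  Raises
    :class:`NoStableBaselineError` when no window qualifies.
    """
    v = trace.values
    if window < 2:
        raise InvalidInputError("baseline window must span at least 2 frames")
    if len(v) < window:
        raise InvalidInputError(f"trace shorter than baseline window ({len(v)} < {window})")
    for start in range(len(v) - window + 1):
        seg = v[start : start + window]
        m = seg.mean()
        if m <= 0:
            continue
        if seg.std(ddof=0) / m <= cv_max:
            return (start, start + window)
    raise NoStableBaselineError(f"no {window}-frame window with CV <= {cv_max}")


def compute_dff(trace: RawTrace, baseline: tuple[int, int], bleach_model: BleachModel | None = None) -> DffTrace:
    """dF/F0 with F0 = mean fluorescence over the ``baseline`` index range."""
    start, stop = baseline
    if not (0 <= start < stop <= len(trace.values)):
        raise InvalidBaselineError(f"baseline range {baseline} outside trace of length {len(trace.values)}")
    f0 = float(trace.values[start:stop].mean())
    if f0 <= 0:
        raise InvalidBaselineError(f"baseline mean must be positive, got {f0}")
    dff = (trace.values - f0) / f0
    return DffTrace(
        times=trace.times.copy(),
        dff=dff,
        f0=f0,
        baseline_frames=(start, stop),
        bleach_model=bleach_model or BleachModel(),
        roi_id=trace.roi_id,
        meta=trace.meta,
    )


def _fit_exponential(t: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Least squares for v = B*exp(-lam*t) in linear space; returns (B, lam).

    A log-linear fit on the strictly positive frames supplies the starting
    point; the refinement in linear space keeps near-zero noisy tail frames
    from biasing the rate.
    """
    from scipy.optimize import OptimizeWarning, curve_fit

    pos = v > 0
    if int(pos.sum()) < MIN_FIT_FRAMES:
        raise BleachFitError("too few positive values for an exponential bleach fit")
    slope, intercept = np.polyfit(t[pos], np.log(v[pos]), 1)
    try:
        with warnings.catch_warnings():
            # a perfectly clean trace fits exactly; the singular covariance
            # warning carries no information here
            warnings.simplefilter("ignore", category=OptimizeWarning)
            popt, _ = curve_fit(
                lambda tt, b, lam: b * np.exp(-lam * tt),
                t,
                v,
                p0=(float(np.exp(intercept)), float(-slope)),
                maxfev=10000,
            )
    except (RuntimeError, ValueError) as exc:
        raise BleachFitError(f"exponential bleach fit did not converge: {exc}") from exc
    return float(popt[0]), float(popt[1])


def _event_mask_from_detection(dff: DffTrace) -> np.ndarray:
    """Frames influenced by detected events, with a decay-scaled margin."""
    from .spikes import DetectionConfig, detect_spikes  # local import: spikes depends on this module

    events = detect_spikes(dff, DetectionConfig())
    mask = np.zeros(len(dff.times), dtype=bool)
    dt = dff.dt
    for ev in events:
        # extend past the offset by twice the fall time so slow tails do not
        # bias the resting-frame fit
        tail = 2.0 * max(ev.offset_time - ev.peak_time, dt)
        lo = ev.onset_time - dt
        hi = ev.offset_time + tail
        mask |= (dff.times >= lo) & (dff.times <= hi)
    return mask


def correct_bleaching(
    trace: RawTrace,
    event_mask: np.ndarray | None = None,
    rate_tolerance: float | None = None,
) -> tuple[RawTrace, BleachModel]:
    """Divide out a fitted photobleaching curve, preserving the baseline mean.

    ``event_mask`` marks frames to exclude from the fit (True = event).  When
    omitted, events are detected on a provisional dF/F0 and the fit is redone
    once with those frames masked.  A mono-exponential fit is tried first; a
    clearly negative rate (fluorescence growing beyond ``rate_tolerance``)
    falls back to a linear trend, and failure of both raises
    :class:`BleachFitError`.
    """
    t = trace.times - trace.times[0]
    v = trace.values
    span = max(float(t[-1]), 1e-12)
    if rate_tolerance is None:
        rate_tolerance = 0.01 / span  # <1% apparent growth over the recording

    if event_mask is None:
        flat, model = _apply_fit(trace, t, v, np.zeros(len(v), dtype=bool), rate_tolerance)
        try:
            base = find_stable_baseline(flat)
        except NoStableBaselineError:
            base = (0, min(DEFAULT_BASELINE_WINDOW, len(v)))
        provisional = compute_dff(flat, base, model)
        event_mask = _event_mask_from_detection(provisional)

    event_mask = np.asarray(event_mask, dtype=bool)
    if event_mask.shape != v.shape:
        raise InvalidInputError("event mask length must match the trace")
    if int((~event_mask).sum()) < MIN_FIT_FRAMES:
        raise BleachFitError(f"fewer than {MIN_FIT_FRAMES} resting frames available for the bleach fit")
    return _apply_fit(trace, t, v, event_mask, rate_tolerance)


def _apply_fit(
    trace: RawTrace, t: np.ndarray, v: np.ndarray, event_mask: np.ndarray, rate_tolerance: float
) -> tuple[RawTrace, BleachModel]:
    rest = ~event_mask
    tr, vr = t[rest], v[rest]
    curve = None
    model = None
    try:
        b, lam = _fit_exponential(tr, vr)
        if lam >= -rate_tolerance:
            curve = b * np.exp(-max(lam, 0.0) * t)
            model = BleachModel("exponential", max(lam, 0.0), int(rest.sum()))
    except BleachFitError:
        pass
    if curve is None:  # linear fallback
        slope, intercept = np.polyfit(tr, vr, 1)
        curve = intercept + slope * t
        if intercept <= 0 or np.any(curve <= 0) or slope > rate_tolerance * intercept:
            raise BleachFitError("neither exponential nor linear bleach model fits this trace")
        model = BleachModel("linear", float(-slope / intercept), int(rest.sum()))

    corrected = v / curve
    # preserve the scale of the original baseline window
    stop = min(DEFAULT_BASELINE_WINDOW, len(v))
    scale = v[:stop].mean() / corrected[:stop].mean()
    corrected = corrected * scale
    return replace(trace, values=corrected), model


def ratiometric_trace(ch_num: RawTrace, ch_den: RawTrace) -> RawTrace:
    """Value-wise ratio of two channels sharing a time grid (e.g. F340/F380)."""
    if len(ch_num.times) != len(ch_den.times) or np.any(
        np.abs(ch_num.times - ch_den.times) > 1e-6 * max(ch_num.dt, 1e-12)
    ):
        raise AlignmentError("channel time grids do not match")
    if np.any(ch_den.values <= 0):
        raise InvalidInputError("denominator channel must be strictly positive")
    return RawTrace(
        times=ch_num.times.copy(),
        values=ch_num.values / ch_den.values,
        roi_id=ch_num.roi_id,
        meta=ch_num.meta,
    )


def preprocess_trace(
    trace: RawTrace,
    correct_bleach: bool = True,
    baseline_window: int = DEFAULT_BASELINE_WINDOW,
    cv_max: float = DEFAULT_CV_MAX,
    fallback_to_first_frames: bool = True,
) -> DffTrace:
    """Full raw -> dF/F0 pipeline for one trace.

    Bleach correction is on by default (germination-length recordings); turn
    it off for short shock recordings.  If no stable baseline window exists
    and ``fallback_to_first_frames`` is set, the first ``baseline_window``
    frames are used with a warning.
    """
    model = BleachModel()
    work = trace
    if correct_bleach:
        work, model = correct_bleaching(trace)
    try:
        base = find_stable_baseline(work, baseline_window, cv_max)
    except NoStableBaselineError:
        if not fallback_to_first_frames:
            raise
        warnings.warn(
            f"trace {trace.roi_id!r}: no stable baseline window; falling back to the first "
            f"{baseline_window} frames",
            stacklevel=2,
        )
        base = (0, min(baseline_window, len(work.values)))
    return compute_dff(work, base, model)
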