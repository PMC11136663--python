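"""Reading/writing fluorescence trace tables and image stacks.

Trace tables are delimited text in long format, one row per (time, ROI):

    time_s, roi_id, F              (single channel)
    time_s, roi_id, F_ch1, F_ch2   (two-channel ratiometric input)

A wide table (``time_s`` plus one column per ROI) is also accepted on read;
long format is always written.  Acquisition metadata (genotype, medium
osmolarity, frame interval, shock time) travels in a JSON sidecar next to the
table, keyed by roi_id, with ``"_default"`` applying to all ROIs.

Image stacks are multi-page grayscale TIFF (read/written with tifffile);
ROI tables are CSV with columns ``roi_id, x, y, radius_px``.  ROI discs are
fixed over time: per-frame trace values are plain means over the disc, and
changes in fluorescent area are deliberately not tracked.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, InvalidInputError, InvalidRoiError

#: Relative tolerance on frame-interval uniformity.
GRID_RTOL = 1e-3

MIN_TRACE_LENGTH = 20


@dataclass(frozen=True)
class TraceMeta:
    """Acquisition metadata attached to a trace."""

    genotype: str | None = None
    osmolarity_mosm: float | None = None
    frame_interval_s: float | None = None
    shock_time_s: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "TraceMeta":
        known = {k: d[k] for k in ("genotype", "osmolarity_mosm", "frame_interval_s", "shock_time_s") if k in d}
        return cls(**known)


@dataclass
class RawTrace:
    """Raw fluorescence time series for one region of interest.

    ``times`` must be a strictly increasing uniform grid (seconds); ``values``
    are arbitrary fluorescence units, finite and non-negative.  A ratiometric
    trace produced from two channels is carried in the same container.
    """

    times: np.ndarray
    values: np.ndarray
    roi_id: str
    meta: TraceMeta = field(default_factory=TraceMeta)
    channel: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise InvalidInputError("times and values must be 1-D arrays of equal length")
        if len(self.times) < MIN_TRACE_LENGTH:
            raise InvalidInputError(f"trace must have >= {MIN_TRACE_LENGTH} frames, got {len(self.times)}")
        dts = np.diff(self.times)
        if np.any(dts <= 0):
            raise InvalidInputError("times must be strictly increasing")
        dt = float(np.median(dts))
        if np.any(np.abs(dts - dt) > GRID_RTOL * dt):
            raise FormatError("time grid is not uniform within tolerance")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InvalidInputError("values must be finite and >= 0")

    @property
    def dt(self) -> float:
        """Frame interval in seconds (median of the grid)."""
        return float(np.median(np.diff(self.times)))

    @property
    def span_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    def shifted(self, offset_s: float) -> "RawTrace":
        """Same trace with a constant time offset added to the stamps."""
        return replace(self, times=self.times + offset_s)


@dataclass(frozen=True)
class RoiDef:
    """A circular region of interest in pixel coordinates (0-based, y down)."""

    roi_id: str
    x: float
    y: float
    radius: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.radius) or self.radius <= 0:
            raise InvalidInputError(f"ROI radius must be > 0, got {self.radius}")


# ---------------------------------------------------------------------------
# trace tables


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _load_meta(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        return {}
    return json.loads(sidecar.read_text())


def _meta_for(meta_map: dict, roi_id: str) -> TraceMeta:
    d = dict(meta_map.get("_default", {}))
    d.update(meta_map.get(roi_id, {}))
    return TraceMeta.from_dict(d)


def read_traces(path: str | Path) -> list[RawTrace]:
    """Read a trace table (long or wide, one or two channels) into RawTraces.

    Rows may appear in any order; traces are sorted by time on read.  For
    two-channel tables, two RawTraces per ROI are returned with ``channel``
    set to ``"ch1"`` / ``"ch2"``.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta_map = _load_meta(path)
    cols = list(df.columns)
    if "time_s" not in cols:
        raise FormatError("trace table must have a 'time_s' column")

    traces: list[RawTrace] = []
    if "roi_id" in cols:  # long format
        value_cols = [c for c in ("F", "F_ch1", "F_ch2") if c in cols]
        if not value_cols:
            raise FormatError("long-format table needs an 'F' (or 'F_ch1'/'F_ch2') column")
        if df.duplicated(subset=["time_s", "roi_id"]).any():
            raise FormatError("duplicated (time_s, roi_id) rows")
        for roi_id, sub in df.groupby("roi_id", sort=True):
            sub = sub.sort_values("time_s")
            meta = _meta_for(meta_map, str(roi_id))
            if "F" in value_cols:
                traces.append(RawTrace(sub["time_s"].to_numpy(), sub["F"].to_numpy(), str(roi_id), meta))
            else:
                for ch, col in (("ch1", "F_ch1"), ("ch2", "F_ch2")):
                    if col in value_cols:
                        traces.append(
                            RawTrace(sub["time_s"].to_numpy(), sub[col].to_numpy(), str(roi_id), meta, channel=ch)
                        )
    else:  # wide format: every non-time column is one ROI
        if df.duplicated(subset=["time_s"]).any():
            raise FormatError("duplicated time_s rows in wide table")
        df = df.sort_values("time_s")
        for col in cols:
            if col == "time_s":
                continue
            traces.append(RawTrace(df["time_s"].to_numpy(), df[col].to_numpy(), str(col), _meta_for(meta_map, str(col))))
    if not traces:
        raise FormatError("no ROI columns found")
    return traces


def write_traces(traces: Sequence[RawTrace], path: str | Path) -> None:
    """Write traces as a long-format CSV plus a JSON metadata sidecar."""
    path = Path(path)
    frames = []
    meta_map: dict[str, dict] = {}
    two_channel = any(t.channel for t in traces)
    if two_channel:
        by_roi: dict[str, dict[str, RawTrace]] = {}
        for t in traces:
            by_roi.setdefault(t.roi_id, {})[t.channel or "ch1"] = t
        for roi_id, chans in by_roi.items():
            ch1 = chans.get("ch1")
            ch2 = chans.get("ch2")
            if ch1 is None or ch2 is None:
                raise InvalidInputError(f"two-channel write needs both channels for ROI {roi_id!r}")
            frames.append(
                pd.DataFrame(
                    {"time_s": ch1.times, "roi_id": roi_id, "F_ch1": ch1.values, "F_ch2": ch2.values}
                )
            )
            meta_map[roi_id] = ch1.meta.to_dict()
    else:
        for t in traces:
            frames.append(pd.DataFrame({"time_s": t.times, "roi_id": t.roi_id, "F": t.values}))
            meta_map[t.roi_id] = t.meta.to_dict()
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    _sidecar_path(path).write_text(json.dumps(meta_map, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# ROI tables and image stacks


def read_rois(path: str | Path) -> list[RoiDef]:
    df = pd.read_csv(path)
    needed = {"roi_id", "x", "y", "radius_px"}
    if not needed.issubset(df.columns):
        raise FormatError(f"ROI table must have columns {sorted(needed)}")
    return [RoiDef(str(r.roi_id), float(r.x), float(r.y), float(r.radius_px)) for r in df.itertuples()]


def write_rois(rois: Sequence[RoiDef], path: str | Path) -> None:
    pd.DataFrame(
        {"roi_id": [r.roi_id for r in rois], "x": [r.x for r in rois], "y": [r.y for r in rois],
         "radius_px": [r.radius for r in rois]}
    ).to_csv(path, index=False)


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page grayscale TIFF as a (frames, height, width) array."""
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None, :, :]
    if stack.ndim != 3:
        raise FormatError(f"expected a grayscale stack, got shape {stack.shape}")
    return stack


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(stack))


def disc_mask(shape: tuple[int, int], roi: RoiDef) -> np.ndarray:
    """Boolean membership mask: pixel centres within ``radius`` of the ROI centre."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - roi.x) ** 2 + (yy - roi.y) ** 2 <= roi.radius**2


def extract_roi_traces(
    stack: np.ndarray,
    rois: Sequence[RoiDef],
    frame_interval_s: float = 1.0,
    meta: TraceMeta | None = None,
) -> list[RawTrace]:
    """Mean disc intensity per frame for each ROI (fixed discs).

    Raises :class:`InvalidRoiError` if a disc extends beyond the frame bounds.
    Returns an empty list for an empty ROI list.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise InvalidInputError("stack must be (frames, height, width)")
    n, h, w = stack.shape
    if frame_interval_s <= 0:
        raise InvalidInputError("frame interval must be > 0")
    base_meta = meta or TraceMeta()
    times = np.arange(n) * float(frame_interval_s)
    out = []
    for roi in rois:
        if roi.x - roi.radius < -0.5 or roi.x + roi.radius > w - 0.5 or roi.y - roi.radius < -0.5 or roi.y + roi.radius > h - 0.5:
            raise InvalidRoiError(f"ROI {roi.roi_id!r} extends outside the {h}x{w} frame")
        mask = disc_mask((h, w), roi)
        if not mask.any():
            raise InvalidRoiError(f"ROI {roi.roi_id!r} covers no pixels")
        values = stack[:, mask].mean(axis=1).astype(float)
        out.append(
            RawTrace(times, values, roi.roi_id, replace(base_meta, frame_interval_s=float(frame_interval_s)))
        )
    return out
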