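"""Quantification of hypo-osmotic-shock calcium transients (HOSCA).

A grain pre-incubated at high osmolarity and perfused with a low-osmolarity
solution responds with a single [Ca2+]i transient: the response is summarized
by its peak dF/F0 within a window after the shock, the time to that peak, and
a mono-exponential decay constant fitted from the peak onward with a floating
plateau term (traces need not return to baseline).  Repeated challenges probe
desensitization (ratios of successive peaks to the first), and grouping peak
responses by pre-incubation osmolarity yields the dose-response relation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import InvalidInputError, UndefinedIndexError
from .preprocess import DffTrace

DEFAULT_WINDOW_S = 300.0


@dataclass(frozen=True)
class ShockResponse:
    shock_time: float
    peak_dff: float
    time_to_peak: float
    decay_tau: float | None  # None when the decay fit failed / was skipped
    fit_quality: float | None  # fraction of variance explained by the decay fit
    pre_osmolarity_mosm: float | None = None

    @property
    def decay_fitted(self) -> bool:
        return self.decay_tau is not None


@dataclass(frozen=True)
class DoseResponsePoint:
    pre_osmolarity_mosm: float
    mean_peak_dff: float
    sd_peak_dff: float
    n: int


def _fit_decay(t: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Least-squares fit of y = A*exp(-t/tau) + C; returns (tau, R^2) or None."""
    if len(t) < 4 or float(np.ptp(y)) < 1e-12:
        return None
    a0 = max(y[0] - y[-1], 1e-6)
    tau0 = max((t[-1] - t[0]) / 3.0, 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
            t - t[0],
            y,
            p0=(a0, tau0, float(y[-1])),
            bounds=([0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return None
    a, tau, c = popt
    resid = y - (a * np.exp(-(t - t[0]) / tau) + c)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return float(tau), r2


def quantify_shock(
    dff: DffTrace,
    shock_time: float,
    window_s: float = DEFAULT_WINDOW_S,
    pre_osmolarity_mosm: float | None = None,
) -> ShockResponse:
    """Peak response and decay kinetics in [shock_time, shock_time + window].

    The peak is the maximum dF/F0 in the window (ties broken toward the
    earlier frame); the decay constant comes from a mono-exponential fit from
    the peak to the end of the window.  A flat or unfittable decay yields
    ``decay_tau=None`` rather than an error.
    """
    t = dff.times
    if not (t[0] <= shock_time <= t[-1]):
        raise InvalidInputError(f"shock time {shock_time} outside trace [{t[0]}, {t[-1]}]")
    sel = (t >= shock_time) & (t <= shock_time + window_s)
    if int(sel.sum()) < 2:
        raise InvalidInputError("response window contains fewer than 2 frames")
    tw, yw = t[sel], dff.dff[sel]
    pk = int(np.argmax(yw))  # argmax returns the first of equal maxima
    peak = float(yw[pk])
    fit = None
    if peak > 0:
        fit = _fit_decay(tw[pk:], yw[pk:])
    return ShockResponse(
        shock_time=float(shock_time),
        peak_dff=peak,
        time_to_peak=float(tw[pk] - shock_time),
        decay_tau=fit[0] if fit else None,
        fit_quality=fit[1] if fit else None,
        pre_osmolarity_mosm=pre_osmolarity_mosm,
    )


def desensitization_index(responses: Sequence[ShockResponse]) -> list[float]:
    """Ratios peak_k / peak_1 for successive challenges ordered by shock time."""
    if len(responses) < 2:
        raise InvalidInputError("need at least 2 shock responses")
    ordered = sorted(responses, key=lambda r: r.shock_time)
    first = ordered[0].peak_dff
    if first <= 0:
        raise UndefinedIndexError("first peak is zero; desensitization index undefined")
    return [r.peak_dff / first for r in ordered]


def dose_response(
    groups: Mapping[float, Sequence[ShockResponse]],
) -> tuple[list[DoseResponsePoint], float]:
    """Per-osmolarity mean/sd/n of peak dF/F0, plus a monotone-trend summary.

    Returns points sorted by pre-incubation osmolarity and the Spearman rank
    correlation between osmolarity and mean peak (NaN with fewer than 2
    groups).
    """
    if not groups:
        raise InvalidInputError("need at least one osmolarity group")
    points = []
    for osm in sorted(groups):
        peaks = np.array([r.peak_dff for r in groups[osm]], dtype=float)
        if len(peaks) == 0:
            raise InvalidInputError(f"empty group at {osm} mOsm")
        sd = float(peaks.std(ddof=1)) if len(peaks) >= 2 else 0.0
        points.append(DoseResponsePoint(float(osm), float(peaks.mean()), sd, len(peaks)))
    if len(points) >= 2:
        rho = float(stats.spearmanr([p.pre_osmolarity_mosm for p in points], [p.mean_peak_dff for p in points])[0])
    else:
        rho = float("nan")
    return points, rho
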