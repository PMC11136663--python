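"""Cohort-level summaries: spike counts and oscillation metrics grouped by
(genotype, osmolarity), germination percentages, and relative growth-rate
normalization for the bacterial expression screen.

Hypothesis testing (ANOVA, t-tests) is deliberately not reimplemented here;
the summaries are tidy tables ready for external statistical tools.
Dispersion is reported as both s.d. and s.e.m.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigMismatchError, InvalidInputError, NormalizationError
from .phases import count_modules, resting_duration
from .pipeline import TraceResult

DEFAULT_CONTROL_CONDITION = "-IPTG"

_METRIC_FIELDS = (
    ("small", "period_mean", "small_period_s"),
    ("small", "amplitude_mean", "small_amplitude_dff"),
    ("small", "duration_mean", "small_duration_s"),
    ("small", "frequency_per_min", "small_frequency_per_min"),
    ("large", "period_mean", "large_period_s"),
    ("large", "amplitude_mean", "large_amplitude_dff"),
    ("large", "duration_mean", "large_duration_s"),
    ("large", "frequency_per_min", "large_frequency_per_min"),
)


def _trace_row(res: TraceResult) -> dict:
    row = {
        "genotype": res.genotype,
        "osmolarity_mosm": res.osmolarity_mosm,
        "roi_id": res.roi_id,
        "n_small": res.metrics.small.count,
        "n_large": res.metrics.large.count,
        "n_total": res.metrics.small.count + res.metrics.large.count,
        "reph1_duration_s": resting_duration(res.segments, "RePh1"),
        "module_count": count_modules(res.segments),
        "germinated": res.germinated,
    }
    for cls, field, name in _METRIC_FIELDS:
        row[name] = getattr(res.metrics.for_class(cls), field)
    return row


def cohort_table(results: Sequence[TraceResult]) -> pd.DataFrame:
    """One tidy row per analyzed trace (the unit for external statistics)."""
    if not results:
        raise InvalidInputError("no trace results")
    cfg0 = (results[0].detection_cfg, results[0].segmentation_cfg)
    for r in results[1:]:
        if (r.detection_cfg, r.segmentation_cfg) != cfg0:
            raise ConfigMismatchError("cohort members were analyzed with different configurations")
    return pd.DataFrame([_trace_row(r) for r in results])


def summarize_cohort(results: Sequence[TraceResult]) -> tuple[pd.DataFrame, dict]:
    """Grouped summaries keyed by (genotype, osmolarity), plus trend signs.

    The summary holds per-key trace counts, summed spike counts, and
    mean/s.d./s.e.m. of the per-trace metrics.  The trend report gives, per
    genotype, the sign of the Spearman association between osmolarity and
    total spikes, large-event period, and large-event amplitude.
    """
    table = cohort_table(results)
    keys = ["genotype", "osmolarity_mosm"]
    rows = []
    for (geno, osm), sub in table.groupby(keys, sort=True, dropna=False):
        row = {
            "genotype": geno,
            "osmolarity_mosm": osm,
            "n_traces": len(sub),
            "n_small": int(sub["n_small"].sum()),
            "n_large": int(sub["n_large"].sum()),
            "n_total": int(sub["n_total"].sum()),
        }
        for col in [c for _, _, c in _METRIC_FIELDS] + ["reph1_duration_s", "module_count"]:
            vals = sub[col].dropna().astype(float)
            n = len(vals)
            row[f"{col}_mean"] = float(vals.mean()) if n else None
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if n >= 2 else None
            row[f"{col}_sem"] = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else None
        germ = sub["germinated"].dropna()
        row["germination_fraction"] = float(germ.mean()) if len(germ) else None
        rows.append(row)
    summary = pd.DataFrame(rows)

    trends: dict[str, dict[str, float]] = {}
    for geno, sub in summary.groupby("genotype"):
        if len(sub) < 2:
            continue
        osm = sub["osmolarity_mosm"].to_numpy(dtype=float)
        t = {}
        for name, col in (
            ("total_spikes", "n_total"),
            ("large_period", "large_period_s_mean"),
            ("large_amplitude", "large_amplitude_dff_mean"),
        ):
            y = sub[col].to_numpy(dtype=float)
            ok = np.isfinite(y)
            rho = float(stats.spearmanr(osm[ok], y[ok])[0]) if ok.sum() >= 2 else float("nan")
            t[name] = {"rho": rho, "sign": int(np.sign(rho)) if np.isfinite(rho) else 0}
        trends[str(geno)] = t
    return summary, trends


def germination_rate(n_germinated: int, n_total: int) -> float:
    """Germination rate as a percentage: 100 * germinated / total."""
    if n_total <= 0:
        raise InvalidInputError("n_total must be positive")
    if not (0 <= n_germinated <= n_total):
        raise InvalidInputError("need 0 <= n_germinated <= n_total")
    return 100.0 * n_germinated / n_total


def normalize_growth(
    records: pd.DataFrame,
    control_condition: str = DEFAULT_CONTROL_CONDITION,
    value_col: str = "raw",
) -> pd.DataFrame:
    """Relative growth rates: each construct scaled so its matched
    no-induction control equals exactly 1.

    ``records`` needs columns ``construct``, ``condition`` and ``value_col``.
    Returns a copy with a ``relative_rate`` column.  Applying the function to
    its own output (feeding ``relative_rate`` back as the value column) is a
    no-op.
    """
    needed = {"construct", "condition", value_col}
    if not needed.issubset(records.columns):
        raise InvalidInputError(f"growth table must have columns {sorted(needed)}")
    out = records.copy()
    out["relative_rate"] = np.nan
    for construct, sub in records.groupby("construct"):
        ctrl = sub.loc[sub["condition"] == control_condition, value_col]
        if ctrl.empty:
            raise NormalizationError(f"construct {construct!r} has no {control_condition!r} control")
        ctrl_val = float(ctrl.mean())
        if not np.isfinite(ctrl_val) or ctrl_val <= 0:
            raise NormalizationError(f"construct {construct!r} control measure must be positive")
        out.loc[sub.index, "relative_rate"] = sub[value_col].astype(float) / ctrl_val
    return out
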