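"""Synthetic GCaMP6-like pollen traces with ground truth.

No public recording of these experiments exists, so every downstream stage is
validated against generated data whose event times, classes, amplitudes and
phase boundaries are known exactly.  The generative model is

    F(t) = F0 * exp(-bleach_rate * t) * (1 + sum_events s_e(t)) + noise,

with additive Gaussian noise on the raw intensity and each event shaped as a
linear rise over ``rise_time`` followed by an exponential decay with time
constant ``decay_tau`` (no kinetics are published for these grains; this is
the simplest shape with distinct rise and fall).  Event onsets are snapped to
the frame grid so noise-free sampled traces attain true peaks exactly.

Germination-mode traces follow the five-phase anatomy (RePh1, CaOscS, RePh2,
CaOscL, RePh3), sampled at 30 s for 300 min; shock mode produces step
transients sampled at 1 s.  ``osmolarity_to_params`` encodes the study
conditions: lowering medium osmolarity raises spike rates and amplitudes and
shortens inter-spike periods, strictly monotonically, while the
osca2.1/osca2.2 double-mutant signature is a much longer first resting phase,
shortened oscillation trains, an abolished second resting phase, and smaller,
sparser spikes at every osmolarity.

Within an oscillation train, inter-event intervals are drawn uniformly from
[0.85, 1.15] times the train's mean period: irregular, but bounded so that
within-train gaps never masquerade as resting phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, InvalidLayoutError
from .trace_io import RawTrace, RoiDef, TraceMeta

WT = "WT"
MUTANT = "osca2.1/2.2"
GENOTYPES = (WT, MUTANT)

OSM_MIN, OSM_MAX = 100.0, 1000.0

#: Germination-mode acquisition: one frame per 30 s for 300 min.
GERMINATION_DT_S = 30.0
GERMINATION_N_FRAMES = 600
#: Shock-mode acquisition: one frame per second for 350 s.
SHOCK_DT_S = 1.0
SHOCK_N_FRAMES = 350

DEFAULT_F0 = 100.0
DEFAULT_BLEACH_RATE = 1e-4  # 1/s; ~17% decay over a 300-min recording
DEFAULT_SNR = 50.0  # baseline_F0 / noise_sd

GERMINATION_RISE_S = 60.0
GERMINATION_DECAY_TAU_S = 25.0
SHOCK_RISE_S = 5.0
SHOCK_DECAY_TAU_S = 40.0

#: Large events complete germination when a CaOscL train has at least this many.
GERMINATION_MIN_LARGE = 3

#: Relative jitter of inter-event intervals around the train period.
PERIOD_JITTER = 0.15


@dataclass(frozen=True)
class SpikeShapeParams:
    """Kinetic template for a single transient."""

    rise_time_s: float
    decay_tau_s: float
    peak_dff: float

    def __post_init__(self) -> None:
        if self.rise_time_s <= 0 or self.decay_tau_s <= 0 or self.peak_dff <= 0:
            raise InvalidInputError("rise time, decay tau and peak must all be positive")


@dataclass(frozen=True)
class PhaseBlock:
    """One planned phase: a resting interval or an oscillation train.

    For oscillation blocks, ``period_s`` is the mean inter-event interval and
    ``amp_lo``/``amp_hi`` bound the sampled peak dF/F0 (log-uniform when
    ``log_uniform`` is set, as large-event amplitudes are right-skewed).
    """

    label: str  # RePh1 | CaOscS | RePh2 | CaOscL | RePh3
    duration_s: float
    amp_class: str = "none"  # none | small | large
    period_s: float | None = None
    amp_lo: float = 0.0
    amp_hi: float = 0.0
    log_uniform: bool = False

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise InvalidInputError("block duration must be >= 0")
        if self.amp_class not in ("none", "small", "large"):
            raise InvalidInputError(f"unknown amplitude class {self.amp_class!r}")
        if self.amp_class == "none" and self.period_s is not None:
            raise InvalidInputError("resting blocks cannot carry a spike period")
        if self.amp_class != "none":
            if self.period_s is None or self.period_s <= 0:
                raise InvalidInputError("oscillation blocks need a positive period")
            if not (0 < self.amp_lo <= self.amp_hi):
                raise InvalidInputError("oscillation blocks need 0 < amp_lo <= amp_hi")

    @property
    def spike_rate_per_min(self) -> float:
        return 0.0 if self.period_s is None else 60.0 / self.period_s


@dataclass(frozen=True)
class PhasePlan:
    blocks: tuple[PhaseBlock, ...]
    module_repeats: int = 1

    def __post_init__(self) -> None:
        if self.module_repeats < 1:
            raise InvalidInputError("module_repeats must be >= 1")

    @property
    def total_duration_s(self) -> float:
        return float(sum(b.duration_s for b in self.blocks))


@dataclass(frozen=True)
class ShockParams:
    shock_times_s: tuple[float, ...]
    peak_dff: float
    decay_tau_s: float = SHOCK_DECAY_TAU_S
    rise_time_s: float = SHOCK_RISE_S
    desensitization_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.shock_times_s:
            raise InvalidInputError("need at least one shock time")
        if self.peak_dff <= 0 or self.decay_tau_s <= 0 or self.rise_time_s <= 0:
            raise InvalidInputError("shock peak, decay tau and rise time must be positive")
        if not (0 < self.desensitization_factor <= 1):
            raise InvalidInputError("desensitization factor must be in (0, 1]")


@dataclass(frozen=True)
class GenerativeParams:
    """Full specification of one synthetic trace."""

    frame_interval_s: float = GERMINATION_DT_S
    n_frames: int = GERMINATION_N_FRAMES
    baseline_f0: float = DEFAULT_F0
    bleach_rate: float = DEFAULT_BLEACH_RATE
    noise_sd: float = DEFAULT_F0 / DEFAULT_SNR
    phase_plan: PhasePlan | None = None
    shock: ShockParams | None = None
    seed: int = 0
    spike_rise_s: float = GERMINATION_RISE_S
    spike_decay_tau_s: float = GERMINATION_DECAY_TAU_S
    genotype: str = WT
    osmolarity_mosm: float | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 20:
            raise InvalidInputError("n_frames must be >= 20 (baseline rule needs 10 stable frames)")
        if self.frame_interval_s <= 0 or self.baseline_f0 <= 0:
            raise InvalidInputError("frame interval and baseline F0 must be positive")
        if self.noise_sd < 0 or self.bleach_rate < 0:
            raise InvalidInputError("noise sd and bleach rate must be >= 0")

    @property
    def span_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s


@dataclass
class GroundTruth:
    """Everything the generator knows about a trace."""

    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    spike_classes: list[str] = field(default_factory=list)
    spike_peaks: np.ndarray = field(default_factory=lambda: np.empty(0))
    phases: list[tuple[str, float, float]] = field(default_factory=list)
    shock_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    shock_peaks: np.ndarray = field(default_factory=lambda: np.empty(0))
    germination_time_s: float | None = None
    module_repeats: int = 0

    @property
    def n_events(self) -> int:
        return len(self.spike_times)

    def class_periods(self, label: str) -> np.ndarray:
        """Inter-peak intervals of the events of one class."""
        t = self.spike_times[np.array([c == label for c in self.spike_classes], dtype=bool)]
        return np.diff(t)


# ---------------------------------------------------------------------------
# osmolarity -> dynamics mapping


def _check_osmolarity(osmolarity_mosm: float) -> float:
    if not (OSM_MIN <= osmolarity_mosm <= OSM_MAX):
        raise InvalidInputError(
            f"osmolarity {osmolarity_mosm} mOsm outside the modelled range [{OSM_MIN}, {OSM_MAX}]"
        )
    return float(osmolarity_mosm)


def _check_genotype(genotype: str) -> str:
    if genotype not in GENOTYPES:
        raise InvalidInputError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    return genotype


def _u(osmolarity: float) -> float:
    """Normalized position of the osmolarity in the modelled range [0, 1]."""
    return (osmolarity - OSM_MIN) / (OSM_MAX - OSM_MIN)


def germination_dynamics(osmolarity_mosm: float, genotype: str = WT) -> dict:
    """Deterministic osmolarity->dynamics mapping for germination mode.

    All rate/amplitude/period entries are strictly monotone in osmolarity for
    both genotypes; the mutant is slower, sparser and weaker than wild type
    at every osmolarity, with a much longer RePh1 and no RePh2.
    """
    osm = _check_osmolarity(osmolarity_mosm)
    geno = _check_genotype(genotype)
    u = _u(osm)

    d = {
        "reph1_s": 600.0 + 1200.0 * u,
        "reph2_s": 900.0,
        "inter_module_rest_s": 900.0,
        "small_period_s": 180.0 + 180.0 * u,
        "small_duration_s": 5400.0 - 4400.0 * u,
        "large_period_s": 200.0 + 200.0 * u,
        "large_duration_s": 4200.0 - 3600.0 * u,
        # small-event dF/F0 uniform on [lo, lo+0.25] (inside the 2-3x F/F0 band)
        "small_amp_lo": 1.75 - 0.60 * u,
        "small_amp_width": 0.25,
        # large-event dF/F0 log-uniform on c*[1/1.05, 1.05] (inside the >=5x band)
        "large_amp_center": 6.3 * (4.35 / 6.3) ** u,
        "large_amp_spread": 1.05,
    }
    if geno == MUTANT:
        d["reph1_s"] += 3600.0  # largely extended first resting phase
        d["reph2_s"] = 0.0  # abolished second resting phase
        d["small_duration_s"] *= 0.55  # shortened small train
        # the large train is diminished overall and collapses toward zero as
        # osmolarity rises (spiking nearly abolished under hyper-osmotic media)
        d["large_duration_s"] *= 0.60 * (1.0 - u) ** 0.8
        d["small_period_s"] *= 1.20  # longer periods, lower rates
        d["large_period_s"] *= 1.20
        d["small_amp_lo"] = 1.15 + 0.5 * (d["small_amp_lo"] - 1.15)  # weaker flashes
        d["large_amp_center"] = 4.35 + 0.6 * (d["large_amp_center"] - 4.35)
    return d


def shock_dynamics(pre_osmolarity_mosm: float, genotype: str = WT) -> dict:
    """Pre-incubation osmolarity -> shock transient parameters.

    Higher pre-incubation osmolarity intensifies the transient; the mutant
    response is strongly attenuated at every osmolarity.
    """
    osm = _check_osmolarity(pre_osmolarity_mosm)
    geno = _check_genotype(genotype)
    peak = 0.8 + 2.2 * _u(osm)
    if geno == MUTANT:
        peak *= 0.25
    return {"peak_dff": peak, "decay_tau_s": SHOCK_DECAY_TAU_S, "rise_time_s": SHOCK_RISE_S}


def _build_phase_plan(dyn: dict, module_repeats: int) -> PhasePlan:
    def small_block() -> PhaseBlock:
        return PhaseBlock(
            "CaOscS", dyn["small_duration_s"], "small", dyn["small_period_s"],
            amp_lo=dyn["small_amp_lo"], amp_hi=dyn["small_amp_lo"] + dyn["small_amp_width"],
        )

    def large_block() -> PhaseBlock:
        c, s = dyn["large_amp_center"], dyn["large_amp_spread"]
        return PhaseBlock("CaOscL", dyn["large_duration_s"], "large", dyn["large_period_s"],
                          amp_lo=c / s, amp_hi=c * s, log_uniform=True)

    blocks: list[PhaseBlock] = [PhaseBlock("RePh1", dyn["reph1_s"])]
    for k in range(module_repeats):
        blocks.append(small_block())
        if dyn["reph2_s"] > 0:
            blocks.append(PhaseBlock("RePh2", dyn["reph2_s"]))
        blocks.append(large_block())
        blocks.append(PhaseBlock("RePh3", dyn["inter_module_rest_s"]))
    return PhasePlan(tuple(blocks), module_repeats)


def osmolarity_to_params(
    osmolarity_mosm: float,
    genotype: str = WT,
    mode: str = "germination",
    seed: int = 0,
    module_repeats: int = 1,
    noise_sd: float | None = None,
    bleach_rate: float | None = None,
    shock_time_s: float = 30.0,
    n_shocks: int = 1,
    desensitization_factor: float = 0.5,
    shock_interval_s: float = 300.0,
) -> GenerativeParams:
    """Full generator parameter set for a (osmolarity, genotype) condition.

    In germination mode the returned plan encodes the five-phase anatomy with
    osmolarity-dependent periods, durations and amplitudes; the trace length
    grows with ``module_repeats`` so repeated modules always fit.  In shock
    mode ``osmolarity_mosm`` is the *pre-incubation* osmolarity and sets the
    transient peak.  Identical inputs yield identical parameter sets.
    """
    if mode == "germination":
        dyn = germination_dynamics(osmolarity_mosm, genotype)
        plan = _build_phase_plan(dyn, module_repeats)
        needed = plan.total_duration_s + 600.0
        n_frames = max(GERMINATION_N_FRAMES, int(math.ceil(needed / GERMINATION_DT_S)) + 1)
        return GenerativeParams(
            frame_interval_s=GERMINATION_DT_S,
            n_frames=n_frames,
            bleach_rate=DEFAULT_BLEACH_RATE if bleach_rate is None else bleach_rate,
            noise_sd=DEFAULT_F0 / DEFAULT_SNR if noise_sd is None else noise_sd,
            phase_plan=plan,
            seed=seed,
            genotype=genotype,
            osmolarity_mosm=float(osmolarity_mosm),
        )
    if mode == "shock":
        dyn = shock_dynamics(osmolarity_mosm, genotype)
        times = tuple(shock_time_s + k * shock_interval_s for k in range(n_shocks))
        n_frames = max(SHOCK_N_FRAMES, int(math.ceil((times[-1] + 320.0) / SHOCK_DT_S)) + 1)
        return GenerativeParams(
            frame_interval_s=SHOCK_DT_S,
            n_frames=n_frames,
            bleach_rate=0.0 if bleach_rate is None else bleach_rate,  # shock recordings are short
            noise_sd=DEFAULT_F0 / DEFAULT_SNR if noise_sd is None else noise_sd,
            shock=ShockParams(times, dyn["peak_dff"], dyn["decay_tau_s"], dyn["rise_time_s"],
                              desensitization_factor),
            spike_rise_s=dyn["rise_time_s"],
            spike_decay_tau_s=dyn["decay_tau_s"],
            seed=seed,
            genotype=genotype,
            osmolarity_mosm=float(osmolarity_mosm),
        )
    raise InvalidInputError(f"unknown mode {mode!r}; expected 'germination' or 'shock'")


# ---------------------------------------------------------------------------
# trace generation


def _spike_waveform(t: np.ndarray, onset: float, peak: float, rise: float, tau: float) -> np.ndarray:
    """Linear rise to ``peak`` over ``rise`` seconds, then exponential decay."""
    rel = t - onset
    out = np.zeros_like(t)
    rising = (rel >= 0) & (rel < rise)
    out[rising] = peak * rel[rising] / rise
    falling = rel >= rise
    out[falling] = peak * np.exp(-(rel[falling] - rise) / tau)
    return out


def _snap(t: float, dt: float) -> float:
    return round(t / dt) * dt


def _sample_block_events(
    rng: np.random.Generator, block: PhaseBlock, start: float, dt: float,
    rise: float, tau: float,
) -> list[tuple[float, float]]:
    """(onset, peak) pairs for one oscillation block, onsets on the frame grid."""
    width = rise + 3.0 * tau  # footprint an event needs inside its block
    end = start + block.duration_s
    events: list[tuple[float, float]] = []
    t = _snap(start + rng.uniform(0.0, 2.0 * dt), dt)
    while t + width <= end:
        if block.log_uniform:
            peak = float(np.exp(rng.uniform(np.log(block.amp_lo), np.log(block.amp_hi))))
        else:
            peak = float(rng.uniform(block.amp_lo, block.amp_hi))
        events.append((t, peak))
        gap = block.period_s * rng.uniform(1.0 - PERIOD_JITTER, 1.0 + PERIOD_JITTER)
        t = _snap(t + gap, dt)
    return events


def generate_trace(params: GenerativeParams, roi_id: str = "sim-0") -> tuple[RawTrace, GroundTruth]:
    """Germination-mode trace plus its ground truth.

    Resting blocks are event-free; oscillation blocks carry a quasi-periodic
    event train whose first event starts within two frames of the block
    boundary.  Ground-truth phase boundaries are the *realized* ones (first
    event onset to last event offset for oscillation phases, resting phases
    filling the gaps), which is what any event-based segmentation can aim for.
    """
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval_s
    times = np.arange(params.n_frames) * dt
    rise, tau = params.spike_rise_s, params.spike_decay_tau_s

    all_events: list[tuple[float, float, str]] = []  # (onset, peak, class)
    realized_phases: list[tuple[str, float, float]] = []
    germination_time: float | None = None

    blocks = params.phase_plan.blocks if params.phase_plan else ()
    cursor = 0.0
    osc_spans: list[tuple[str, float, float]] = []
    for block in blocks:
        if block.amp_class == "none":
            cursor += block.duration_s
            continue
        evs = _sample_block_events(rng, block, cursor, dt, rise, tau)
        for onset, peak in evs:
            all_events.append((onset, peak, block.amp_class))
        if evs:
            span_start = evs[0][0]
            span_end = evs[-1][0] + rise + tau * math.log(5.0)  # decay to 20% of peak
            osc_spans.append((block.label, span_start, span_end))
            if (
                block.amp_class == "large"
                and len(evs) >= GERMINATION_MIN_LARGE
                and germination_time is None
            ):
                germination_time = span_end
        cursor += block.duration_s

    span_s = params.span_s
    prev_end = 0.0
    rest_iter = iter([b.label for b in blocks if b.amp_class == "none"])
    for label, s, e in osc_spans:
        if s > prev_end:
            realized_phases.append((next(rest_iter, "RePh"), prev_end, s))
        realized_phases.append((label, s, e))
        prev_end = e
    if prev_end < span_s:
        realized_phases.append((next(rest_iter, "RePh3"), prev_end, span_s))

    dff = np.zeros_like(times)
    for onset, peak, _cls in all_events:
        dff += _spike_waveform(times, onset, peak, rise, tau)
    raw = params.baseline_f0 * np.exp(-params.bleach_rate * times) * (1.0 + dff)
    if params.noise_sd > 0:
        raw = raw + rng.normal(0.0, params.noise_sd, size=len(times))
    raw = np.clip(raw, 0.0, None)

    truth = GroundTruth(
        spike_times=np.array([o + rise for o, _, _ in all_events]),
        spike_classes=[c for _, _, c in all_events],
        spike_peaks=np.array([p for _, p, _ in all_events]),
        phases=realized_phases,
        germination_time_s=germination_time,
        module_repeats=params.phase_plan.module_repeats if params.phase_plan else 0,
    )
    meta = TraceMeta(
        genotype=params.genotype,
        osmolarity_mosm=params.osmolarity_mosm,
        frame_interval_s=dt,
    )
    return RawTrace(times, raw, roi_id, meta), truth


def generate_shock_trace(params: GenerativeParams, roi_id: str = "shock-0") -> tuple[RawTrace, GroundTruth]:
    """Shock-mode trace: flat baseline, then one transient per challenge.

    The k-th challenge rises linearly to ``peak_dff * d^k`` (d the
    desensitization factor) and decays mono-exponentially.
    """
    if params.shock is None:
        raise InvalidInputError("shock parameters are required for shock traces")
    sp = params.shock
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval_s
    times = np.arange(params.n_frames) * dt

    dff = np.zeros_like(times)
    peaks = []
    for k, s in enumerate(sp.shock_times_s):
        if not (0 <= s <= times[-1]):
            raise InvalidInputError(f"shock time {s} outside the recording")
        peak = sp.peak_dff * sp.desensitization_factor**k
        peaks.append(peak)
        dff += _spike_waveform(times, _snap(s, dt), peak, sp.rise_time_s, sp.decay_tau_s)
    raw = params.baseline_f0 * np.exp(-params.bleach_rate * times) * (1.0 + dff)
    if params.noise_sd > 0:
        raw = raw + rng.normal(0.0, params.noise_sd, size=len(times))
    raw = np.clip(raw, 0.0, None)

    truth = GroundTruth(
        shock_times=np.array(sp.shock_times_s, dtype=float),
        shock_peaks=np.array(peaks),
    )
    meta = TraceMeta(
        genotype=params.genotype,
        osmolarity_mosm=params.osmolarity_mosm,
        frame_interval_s=dt,
        shock_time_s=float(sp.shock_times_s[0]),
    )
    return RawTrace(times, raw, roi_id, meta), truth


# ---------------------------------------------------------------------------
# image stacks and cohorts


def generate_image_stack(
    params: GenerativeParams | Sequence[GenerativeParams],
    grain_layout: Sequence[tuple[float, float, float]],
    image_shape: tuple[int, int] = (64, 64),
    background: float = 20.0,
) -> tuple[np.ndarray, list[RoiDef], list[tuple[RawTrace, GroundTruth]]]:
    """Render traces as discs in a 16-bit image stack.

    ``grain_layout`` lists (x, y, radius) per grain; discs must not overlap
    and must lie within the frame.  One ``params`` may be shared (each grain
    then gets a seed offset) or one may be given per grain.  Returns the
    stack, the matching ROI table, and each grain's (trace, truth).
    """
    h, w = image_shape
    layout = [(float(x), float(y), float(r)) for x, y, r in grain_layout]
    for i, (x, y, r) in enumerate(layout):
        if x - r < 0 or x + r > w - 1 or y - r < 0 or y + r > h - 1:
            raise InvalidLayoutError(f"grain {i} extends outside the {h}x{w} frame")
        for j, (x2, y2, r2) in enumerate(layout[:i]):
            if math.hypot(x - x2, y - y2) < r + r2:
                raise InvalidLayoutError(f"grains {j} and {i} overlap")

    if isinstance(params, GenerativeParams):
        params_list = [replace(params, seed=params.seed + i) for i in range(len(layout))]
    else:
        params_list = list(params)
        if len(params_list) != len(layout):
            raise InvalidInputError("need one parameter set per grain")

    truths: list[tuple[RawTrace, GroundTruth]] = []
    rois: list[RoiDef] = []
    n_frames = params_list[0].n_frames if params_list else GERMINATION_N_FRAMES
    stack = np.full((n_frames, h, w), background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for i, ((x, y, r), p) in enumerate(zip(layout, params_list)):
        if p.n_frames != n_frames:
            raise InvalidInputError("all grains must share the same number of frames")
        roi = RoiDef(f"grain-{i}", x, y, r)
        rois.append(roi)
        trace, truth = (generate_shock_trace if p.shock else generate_trace)(p, roi.roi_id)
        truths.append((trace, truth))
        mask = (xx - x) ** 2 + (yy - y) ** 2 <= r**2
        stack[:, mask] = trace.values[:, None]
    return np.clip(np.round(stack), 0, 65535).astype(np.uint16), rois, truths


@dataclass(frozen=True)
class CohortRecord:
    genotype: str
    osmolarity_mosm: float
    replicate: int
    params: GenerativeParams
    trace: RawTrace
    truth: GroundTruth


def _derived_seed(master_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    genotypes: Sequence[str],
    osmolarities: Sequence[float],
    n_per_condition: int,
    seed: int,
    mode: str = "germination",
    noise_sd: float | None = None,
    **param_kwargs,
) -> list[CohortRecord]:
    """Reproducible dataset keyed by (genotype, osmolarity, replicate).

    Per-replicate seeds are derived deterministically from the master seed,
    so the same call always produces byte-identical traces.
    """
    if n_per_condition < 1:
        raise InvalidInputError("n_per_condition must be >= 1")
    records = []
    for gi, geno in enumerate(genotypes):
        for oi, osm in enumerate(osmolarities):
            for rep in range(n_per_condition):
                s = _derived_seed(seed, gi, oi, rep)
                p = osmolarity_to_params(osm, geno, mode=mode, seed=s, noise_sd=noise_sd, **param_kwargs)
                roi_id = f"{geno}:{osm:g}:{rep}"
                trace, truth = (generate_shock_trace if mode == "shock" else generate_trace)(p, roi_id)
                records.append(CohortRecord(geno, float(osm), rep, p, trace, truth))
    return records
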