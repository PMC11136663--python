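# Methods

## Scope and units

All spike analysis operates on ΔF/F₀ = (F − F₀)/F₀, dimensionless.  The
fluorescence-fold criteria that define the event classes translate as
F/F₀ = k ⇔ ΔF/F₀ = k − 1: the detection floor of "about 2× baseline" is
ΔF/F₀ = 1.0 and the large-event criterion of "5× or more" is ΔF/F₀ = 4.0.
Times are seconds, osmolarities mOsm, potentials MPa.

## Baseline and ΔF/F₀

F₀ is the mean fluorescence over the earliest run of ten consecutive frames
whose coefficient of variation is ≤ 0.05.  The CV criterion operationalizes
"stable"; manual analyses rarely state one, and 5% comfortably accepts
shot-noise-level variation at typical SNR while rejecting frames that carry
event transients.  If no window qualifies, the pipeline can fall back to the
first ten frames with a warning (off by default in library calls, on in the
high-level driver).  ΔF/F₀ is computed after bleach correction, with F₀
taken from the corrected trace.

## Photobleaching correction

Long (300 min) GCaMP recordings bleach appreciably.  Bleaching is modelled
as multiplicative: the trace is divided by a fitted B·exp(−λt) and rescaled
so the mean over the baseline window is preserved.  The fit uses only
resting frames.  When no event mask is supplied, an iterative scheme runs
once: fit on all frames → provisional ΔF/F₀ → detect events → mask each
event from one frame before onset to the offset plus twice the fall time
(slow tails bias the rate) → refit.  The exponential is fitted by linear-
space least squares seeded from a log-linear fit on positive frames; pure
log-fitting is biased when the bleached tail approaches the noise floor.  A
fitted rate more negative than a 1%-growth-over-recording tolerance falls
back to a linear trend; failure of both raises an error.  Short shock
recordings (≤ ~6 min) are not corrected by default.

On noise-free synthetic traces the fitted λ matches the generated value to
better than 1%, and every ground-truth event peak is recovered within 2%
after correction; the test suite asserts 5% over λ ∈ [5×10⁻⁵, 2×10⁻⁴] /s at
the default SNR of 50.

## Spike detection and classification

Candidate peaks are interior local maxima of a centred moving average
(default 3 frames in germination mode; plateaus attribute to their first
frame).  Each candidate is refined to the raw-trace maximum within half the
smoothing window, and the detection threshold and the small/large decision
use that refined **raw** value: at 30 s frames a 3-frame average attenuates
a spike peak by roughly 40%, so thresholding smoothed values would
misclassify against the fold-change criteria.  Candidates are accepted
greedily by descending height subject to a minimum peak-to-peak gap
(default two frames).  Onset and offset are the nearest frames at or below
20% of the peak on either side, with offsets clipped to the next onset so
events never overlap.  Events with peak ΔF/F₀ ≥ 4 are "large", all others
"small"; the band between 3× and 5× baseline has no published class, and
"5× or more" is the only sharp criterion, so it is the sole boundary.

Both the peak amplitude P and the peak-minus-trough prominence P − T are
reported, since figures annotate peaks and troughs separately.  Per class,
metrics are: count, amplitude mean/s.d., duration mean/s.d., period (mean
interval between successive same-class peaks, defined for count ≥ 2), and
frequency ((count − 1)/active span, events/min).

The detector's exact semantics are part of the contract: an exhaustive
frame-by-frame brute-force scan in the test suite reproduces its output on
every trace up to 1,000 frames, including noisy ones.

## Phase segmentation

Classified events are grouped into runs: a gap (offset to next onset) of at
least `rest_min_gap` (default 600 s) splits runs.  The default is chosen
between the two natural timescales — within-train periods are a few minutes
while resting phases span tens of minutes.  A run containing a large event
is split at the first large event's onset and the remainder promoted to
CaOscL (large trains are the later, aperture-propagating component); a lone
large train with no preceding smalls is labelled CaOscL directly.
Oscillation segments span first onset to last offset; resting segments fill
all remaining time so the tiling of [0, span] is exact, labelled RePh1
before the first train, RePh2 after a small train, RePh3 after a large one,
with `_r<k>` suffixes for repeat modules.  An event-free trace is a single
RePh1 — the signature of a strongly impaired grain.  A completed module is
a CaOscS train followed (resting segments optional) by a CaOscL train.
Oscillation phases with fewer than 3 events are flagged `sparse` rather
than suppressed.

## Shock (HOSCA) analysis

The response to a hypo-osmotic challenge is quantified in a window (default
300 s, the length of the 1 s-interval shock acquisitions) after the shock:
peak ΔF/F₀ (ties broken toward the earlier frame), time to peak, and a decay
constant from least-squares fitting of A·exp(−t/τ) + C from the peak to the
window end.  The floating offset C absorbs incomplete return to baseline;
the reported metric operationalizes "decay of the peak" as the fitted τ.  A
flat or unfittable segment yields `decay_tau=None` with a flag rather than
an error.  Desensitization is the vector of peak ratios to the first
challenge; the dose–response summary reports per-pre-incubation-osmolarity
mean/s.d./n and a Spearman rank correlation as the monotone-trend statistic.

## Water-potential arithmetic

Ψs = −iCRT with R = 0.008314 L MPa mol⁻¹ K⁻¹, osmolarity accepted in mOsm
and divided by 1000, i defaulting to 1 (an osmolarity already counts
dissociated particles) and T defaulting to 298.15 K, which reproduces the
−4.5 / −0.03 MPa bounds of the 12–1,800 mOsm range discussed for land
plants.  At 298.15 K the mammalian 270–330 mOsm band evaluates to −0.67 to
−0.82 MPa; the commonly quoted −0.66 lower bound corresponds to a slightly
different temperature and is not forced.

## Synthetic data

The generator exists because the recordings themselves are not deposited;
it emulates their documented structure, not their pixel statistics.

Model: F(t) = F₀·exp(−λt)·(1 + Σ events) + ε, ε ~ N(0, σ²) additive on raw
intensity, with defaults F₀ = 100 a.u., λ = 10⁻⁴ /s, SNR = F₀/σ = 50.
Events rise linearly over 60 s and decay exponentially with τ = 25 s
(germination mode; 5 s/40 s in shock mode).  No kinetics are published for
grain spikes; these choices make a spike span a few 30 s frames, as the
videos show.  Onsets snap to the frame grid so noise-free sampled traces
attain true peaks exactly — the property that lets recovery tests assert
equality rather than approximation.

Event timing within a train is a renewal process with intervals uniform on
[0.85, 1.15]×P.  A heavier-tailed (e.g. Poisson) process would place
substantial mass on within-train gaps longer than the 600 s resting
criterion at the longer reported periods (4–10 min), making a single train
indistinguishable from two for *any* event-based segmentation; bounded
jitter keeps trains irregular but coherent.

The osmolarity→dynamics mapping (domain 100–1,000 mOsm, u the normalized
position) encodes the study conditions:

| quantity | wild type | osca2.1/2.2 |
| --- | --- | --- |
| RePh1 duration | 600 + 1200·u s | + 3600 s |
| RePh2 duration | 900 s | 0 (abolished) |
| CaOsc^S period | 180 + 180·u s | ×1.2 |
| CaOsc^L period | 200 + 200·u s | ×1.2 |
| CaOsc^S train length | 5400 − 4400·u s | ×0.55 |
| CaOsc^L train length | 4200 − 3600·u s | ×0.6·(1−u)^0.8 |
| small peak ΔF/F₀ | U[a, a+0.25], a = 1.75 − 0.6·u | a shrunk halfway to 1.15 |
| large peak ΔF/F₀ | log-U around c = 6.3·(4.35/6.3)^u, ±5% | c shrunk 40% toward 4.35 |

Rates, periods and amplitudes are strictly monotone in osmolarity for both
genotypes; the mutant's large train collapses toward zero as osmolarity
rises, matching the near-abolition of spiking observed at 680 mOsm.
Amplitude bands sit strictly inside the class bands (small ΔF/F₀ ∈ [1.15,
2.0], large ∈ [4.14, 6.6]) so ground-truth classes are recoverable by
thresholding and no default event falls in the unclassified 3–5× band;
boundary behaviour is tested with dedicated fixtures instead.  Germination
is labelled when a large train completes with ≥ 3 events.

Shock mode: flat baseline, then per challenge a rise to peak·d^k (d the
desensitization factor, default presets 0.5 "robust" and 0.9 "mild") and
exponential decay with τ = 40 s; the transient peak grows linearly with
pre-incubation osmolarity (0.8 → 3.0 over the domain), and the mutant
response is scaled to 25%.  Challenges are spaced 300 s apart so
transients do not overlap within the response window.

Image stacks render each grain as a disc whose pixel values follow its
trace, quantized to 16-bit; ROI extraction therefore recovers traces within
±0.5 a.u.  Cohorts derive per-replicate seeds from the master seed via
`numpy.random.SeedSequence([seed, genotype, osmolarity, replicate])`, so a
cohort is byte-identical across runs and machines.

What the generator does **not** emulate: spatial propagation of CaOsc^L
toward the germination aperture, area growth of the fluorescent footprint
(excluded from the quantitative analysis by design), movement artifacts,
indicator saturation, and cell-to-cell expression variability beyond the
seeded amplitude draws.  Passing the round-trip tests therefore shows the
pipeline is correct under the documented trace model, not that it is robust
to every artifact of real microscopy.

## Problem sizes and numerical choices

Validation suites use cohorts of 6 replicates across {350, 420, 535, 680}
mOsm, 100-trace batteries for detection precision/recall (noise-free and
SNR 20) and 100 seeds for shock-decay recovery; traces are 600 frames
(300 min at 30 s) in germination mode and ~350 frames in shock mode.  These
sizes put the Monte-Carlo standard errors well below the tested margins.
Ties at equal-height plateaus resolve to the first frame; equal shock
maxima to the earlier frame; the uniform-grid tolerance on read is 0.1% of
the frame interval; the bleach-rate negativity tolerance corresponds to 1%
apparent growth over the recording.

## Known limitations

- The detector reports frame-resolution peak times; no sub-frame
  interpolation is attempted (30 s frames dominate any interpolation gain).
- Bleach correction assumes a mono-exponential (or linear) profile;
  two-component bleaching would leave a residual trend.
- The phase grammar is event-based: oscillations below the detection floor
  are invisible to it, and a train whose true gaps exceed `rest_min_gap`
  will be split — with real high-osmolarity data the gap parameter may need
  raising.
- Cohort statistics stop at tidy summaries; inferential statistics are left
  to external tools by design.
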