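# pollenca

Quantification of calcium-imaging time series from *Arabidopsis* pollen
grains — the recordings that link extracellular water status, the
OSCA2.1/OSCA2.2 hypo-osmosensing Ca²⁺ channels, and the Ca²⁺ spiking that
gates pollen germination.

A rehydrating pollen grain expressing GCaMP6 shows a stereotyped [Ca²⁺]ᵢ
program: a first resting phase (RePh1), a train of small-amplitude
oscillations (CaOsc^S, ≈2–3× baseline fluorescence), a second resting phase
(RePh2), a train of large-amplitude oscillations (CaOsc^L, ≥5× baseline)
that culminates in tube protrusion, and a final resting phase (RePh3).
Lowering medium osmolarity increases spike numbers and amplitudes and
shortens periods; the *osca2.1/osca2.2* double mutant is slower, sparser and
weaker at every osmolarity.  This package turns raw fluorescence traces into
those quantities automatically and reproducibly:

- **trace I/O** — long/wide CSV trace tables, multi-page TIFF stacks with
  fixed circular ROIs, Fura-2-style two-channel ratio traces;
- **preprocessing** — ΔF/F₀ = (F − F₀)/F₀ with F₀ averaged over the first
  ten stable frames, and multiplicative mono-exponential photobleaching
  correction fitted to resting frames;
- **spike detection** — local-maximum detection with a ΔF/F₀ ≥ 1 floor
  (F/F₀ ≥ 2) and classification at ΔF/F₀ ≥ 4 (F/F₀ ≥ 5) into small/large
  events, plus per-class amplitude, duration, period and frequency metrics;
- **phase segmentation** — greedy grammar over the classified event list
  recovering the RePh1 → CaOsc^S → RePh2 → CaOsc^L → RePh3 anatomy and
  counting recurring modules;
- **shock analysis** — hypo-osmotic-shock transients (HOSCA): peak ΔF/F₀,
  time to peak, mono-exponential decay constant, desensitization across
  repeated challenges, and dose–response versus pre-incubation osmolarity;
- **aggregation** — cohort summaries keyed by (genotype, osmolarity),
  germination percentages, and relative growth-rate normalization for the
  *E. coli* expression screen (no-IPTG controls ≡ 1);
- **water-potential arithmetic** — Ψw = Ψs + Ψp + Ψm with the van't Hoff
  solute term Ψs = −iCRT (R = 0.008314 L MPa mol⁻¹ K⁻¹);
- **synthetic data** — a generator with exact ground truth (event times,
  classes, amplitudes, phase boundaries, shock kinetics) emulating wild-type
  and mutant recordings, since no raw recordings are publicly deposited.

## Worked example

```python
import pollenca as pc

params = pc.osmolarity_to_params(535.0, "WT", seed=7)   # standard medium
trace, truth = pc.generate_trace(params)                # 300 min at 30 s/frame
result = pc.analyze_trace(trace)                        # dF/F0 -> events -> phases

print(f"F0 = {result.dff.f0:.1f} a.u., bleach rate = {result.dff.bleach_model.rate:.2e} /s")
m = result.metrics
print(f"small events: {m.small.count} (mean peak dF/F0 {m.small.amplitude_mean:.2f}, period {m.small.period_mean:.0f} s)")
print(f"large events: {m.large.count} (mean peak dF/F0 {m.large.amplitude_mean:.2f}, period {m.large.period_mean:.0f} s)")
for s in result.segments:
    print(f"  {s.label:8s} {s.start_time:7.0f}-{s.end_time:7.0f} s  ({s.n_events} events)")
print(f"completed modules: {result.module_count}")
```

prints

```
F0 = 99.0 a.u., bleach rate = 1.01e-04 /s
small events: 12 (mean peak dF/F0 1.57, period 265 s)
large events: 9 (mean peak dF/F0 5.28, period 285 s)
  RePh1          0-   1230 s  (0 events)
  CaOscS      1230-   4260 s  (12 events)
  RePh2       4260-   5370 s  (0 events)
  CaOscL      5370-   7770 s  (9 events)
  RePh3       7770-  17970 s  (0 events)
completed modules: 1
```

The trace starts quiet for ~20 min, fires a dozen small flashes every ~4.4
min, rests again, then fires nine large spikes every ~4.8 min — one complete
oscillation module, ending in germination.  The fitted bleach rate recovers
the simulated 1.0 × 10⁻⁴ /s within 1%, and the per-event peaks match the
generator's ground truth, which is how the detector is validated.

The same stages are available from the shell:

```bash
pollenca simulate --mode germination --osmolarity 420 --seed 3 --out-dir sim/
pollenca preprocess sim/traces.csv --out dff.csv --report report.json
pollenca detect dff.csv --out events.csv --metrics-out metrics.json
pollenca segment events.csv --span 17970 --out segments.csv
pollenca osmo --mosm 1800 --precision 2     # -> -4.46 (MPa)
```

## Layout

```
src/pollenca/
  osmo.py        water-potential / osmolarity arithmetic
  trace_io.py    trace tables, TIFF stacks, ROI extraction
  preprocess.py  baselines, dF/F0, photobleaching correction, ratios
  spikes.py      transient detection, classification, metrics
  phases.py      resting/oscillation phase grammar
  shock.py       HOSCA transients, desensitization, dose-response
  aggregate.py   cohort summaries, germination %, growth normalization
  simulate.py    synthetic traces, stacks and cohorts with ground truth
  pipeline.py    per-trace analysis driver
  cli.py         click command-line interface
docs/methods.md  model and design notes
```
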