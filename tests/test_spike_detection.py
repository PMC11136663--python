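"""Transient detection, amplitude classification and oscillation metrics."""

import numpy as np
import pytest

from pollenca import (
    DetectionConfig,
    DffTrace,
    SpikeEvent,
    classify_spike,
    detect_spikes,
    generate_trace,
    osmolarity_to_params,
    preprocess_trace,
    spike_metrics,
)
from conftest import match_events
from oracles import brute_force_detect


def dff_from(values, dt=30.0):
    values = np.asarray(values, dtype=float)
    return DffTrace(np.arange(len(values)) * dt, values, f0=100.0, baseline_frames=(0, 10))


def gaussian_bumps(n, dt, bumps, width=60.0):
    t = np.arange(n) * dt
    x = np.zeros(n)
    for center, amp in bumps:
        x += amp * np.exp(-((t - center) ** 2) / (2 * width**2))
    return dff_from(x, dt)


class TestDetectSpikes:
    def test_flat_trace_no_events(self):
        assert detect_spikes(dff_from(np.zeros(100))) == []

    def test_two_bumps_detected_with_their_peaks(self):
        dff = gaussian_bumps(100, 10.0, [(300.0, 1.5), (700.0, 4.5)])
        events = detect_spikes(dff, DetectionConfig(smoothing_width=1))
        assert len(events) == 2
        assert events[0].peak_dff == pytest.approx(1.5, rel=1e-3)
        assert events[1].peak_dff == pytest.approx(4.5, rel=1e-3)
        assert events[0].spike_class == "small" and events[1].spike_class == "large"

    def test_subthreshold_bump_ignored(self):
        dff = gaussian_bumps(100, 10.0, [(300.0, 0.8)])
        assert detect_spikes(dff) == []

    def test_event_geometry_invariants(self, wt_noisefree):
        _, trace, _ = wt_noisefree
        events = detect_spikes(preprocess_trace(trace))
        for e in events:
            assert e.onset_time < e.peak_time < e.offset_time
            assert e.duration > 0
        for a, b in zip(events, events[1:]):
            assert a.peak_time < b.peak_time
            assert a.offset_time <= b.onset_time  # no overlap

    def test_time_shift_equivariance(self):
        dff = gaussian_bumps(200, 10.0, [(500.0, 2.0), (1200.0, 5.0)])
        shifted = DffTrace(dff.times + 777.0, dff.dff, f0=1.0, baseline_frames=(0, 10))
        ev0 = detect_spikes(dff)
        ev1 = detect_spikes(shifted)
        assert len(ev0) == len(ev1)
        for a, b in zip(ev0, ev1):
            assert b.peak_time == pytest.approx(a.peak_time + 777.0)
            assert b.peak_dff == pytest.approx(a.peak_dff)

    def test_plateau_tie_breaks_to_first_frame(self):
        x = np.zeros(60)
        x[20:23] = 3.0  # flat-topped event
        events = detect_spikes(dff_from(x, 10.0), DetectionConfig(smoothing_width=1))
        assert len(events) == 1
        assert events[0].peak_time == pytest.approx(200.0)

    def test_noise_free_recovery_exact(self, wt_noisefree):
        _, trace, truth = wt_noisefree
        events = detect_spikes(preprocess_trace(trace))
        det = [e.peak_time for e in events]
        matched, n_det, n_true = match_events(det, truth.spike_times, tol_s=30.0)
        assert matched == n_det == n_true
        # classes agree event by event
        order = np.argsort(truth.spike_times)
        for e, i in zip(events, order):
            assert e.spike_class == truth.spike_classes[i]


class TestOracleEquivalence:
    """detect_spikes must agree with an exhaustive frame-by-frame scan."""

    def traces(self):
        yield gaussian_bumps(100, 10.0, [(300.0, 1.5), (700.0, 4.5)])
        yield dff_from(np.zeros(50))
        rng = np.random.default_rng(3)
        yield dff_from(np.abs(rng.normal(0.4, 0.5, 800)))  # noise with chance crossings
        for seed in (0, 5):
            for noise in (0.0, 5.0):
                p = osmolarity_to_params(420.0, seed=seed, noise_sd=noise)
                trace, _ = generate_trace(p)
                yield preprocess_trace(trace)

    @pytest.mark.parametrize("cfg", [DetectionConfig(), DetectionConfig(smoothing_width=1, min_gap_s=90.0)])
    def test_agreement_on_battery(self, cfg):
        for dff in self.traces():
            assert len(dff.dff) <= 1000
            got = detect_spikes(dff, cfg)
            expected = brute_force_detect(dff.times, dff.dff, cfg)
            assert len(got) == len(expected)
            for g, e in zip(got, expected):
                assert g.peak_time == pytest.approx(e.peak_time)
                assert g.peak_dff == pytest.approx(e.peak_dff)
                assert g.onset_time == pytest.approx(e.onset_time)
                assert g.offset_time == pytest.approx(e.offset_time)
                assert g.spike_class == e.spike_class


class TestClassify:
    @pytest.mark.parametrize(
        "peak, expected",
        [(1.5, "small"), (4.0, "large"), (3.999, "small"), (6.5, "large"), (1.0, "small")],
    )
    def test_threshold_boundary(self, peak, expected):
        assert classify_spike(peak) == expected

    def test_raising_threshold_never_promotes(self):
        peaks = np.linspace(1.0, 7.0, 25)
        lo = [classify_spike(p, DetectionConfig(large_min_dff=4.0)) for p in peaks]
        hi = [classify_spike(p, DetectionConfig(large_min_dff=5.0)) for p in peaks]
        for a, b in zip(lo, hi):
            assert not (a == "small" and b == "large")


class TestSpikeMetrics:
    def ev(self, t, peak, cls):
        return SpikeEvent(t, peak, 0.1, t - 30.0, t + 60.0, cls)

    def test_empty_events(self):
        m = spike_metrics([])
        assert m.small.count == 0 and m.large.count == 0
        assert m.small.period_mean is None
        assert m.large.frequency_per_min == 0.0

    def test_three_large_events_period_and_frequency(self):
        events = [self.ev(t, 5.0, "large") for t in (0.0, 300.0, 600.0)]
        m = spike_metrics(events)
        assert m.large.count == 3
        assert m.large.period_mean == pytest.approx(300.0)
        assert m.large.frequency_per_min == pytest.approx(0.2)

    def test_period_undefined_for_single_event(self):
        m = spike_metrics([self.ev(100.0, 2.0, "small")])
        assert m.small.count == 1 and m.small.period_mean is None
        assert m.small.frequency_per_min == 0.0

    def test_recovered_period_matches_truth_within_one_frame(self, wt_noisefree):
        _, trace, truth = wt_noisefree
        events = detect_spikes(preprocess_trace(trace))
        m = spike_metrics(events)
        for cls in ("small", "large"):
            gaps = truth.class_periods(cls)
            if len(gaps) >= 1:
                assert m.for_class(cls).period_mean == pytest.approx(np.mean(gaps), abs=30.0)

    def test_amplitude_and_prominence_both_reported(self):
        events = [self.ev(0.0, 5.0, "large"), self.ev(300.0, 6.0, "large")]
        m = spike_metrics(events)
        assert m.large.amplitude_mean == pytest.approx(5.5)
        assert m.large.prominence_mean == pytest.approx(5.4)
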