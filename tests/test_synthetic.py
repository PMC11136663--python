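"""Generator contracts: determinism, construction identities, monotone
osmolarity->dynamics mapping, and class separability of the ground truth."""

import numpy as np
import pytest

from pollenca import (
    GenerativeParams,
    InvalidInputError,
    InvalidLayoutError,
    PhaseBlock,
    PhasePlan,
    ShockParams,
    generate_cohort,
    generate_image_stack,
    generate_shock_trace,
    generate_trace,
    osmolarity_to_params,
)
from pollenca.simulate import MUTANT, PERIOD_JITTER, WT, germination_dynamics


def empty_plan_params(**kw):
    defaults = dict(
        frame_interval_s=30.0,
        n_frames=100,
        baseline_f0=100.0,
        bleach_rate=2e-4,
        noise_sd=0.0,
        phase_plan=PhasePlan((PhaseBlock("RePh1", 3000.0),)),
        seed=0,
    )
    defaults.update(kw)
    return GenerativeParams(**defaults)


class TestGenerateTrace:
    def test_no_events_is_pure_bleach_decay(self):
        params = empty_plan_params()
        trace, truth = generate_trace(params)
        expected = 100.0 * np.exp(-2e-4 * trace.times)
        np.testing.assert_allclose(trace.values, expected, rtol=1e-12)
        assert truth.n_events == 0

    def test_single_event_peak_reached_exactly(self):
        # one large event: the bleach-corrected dF/F0 maximum equals the
        # true peak because onsets are snapped to the frame grid
        plan = PhasePlan((
            PhaseBlock("RePh1", 600.0),
            PhaseBlock("CaOscL", 700.0, "large", 800.0, amp_lo=4.5, amp_hi=4.5),
            PhaseBlock("RePh3", 600.0),
        ))
        params = empty_plan_params(phase_plan=plan, bleach_rate=0.0)
        trace, truth = generate_trace(params)
        assert truth.n_events == 1
        dff = (trace.values - 100.0) / 100.0
        assert dff.max() == pytest.approx(4.5, rel=1e-12)

    def test_determinism_bit_identical(self):
        p = osmolarity_to_params(420.0, WT, seed=5)
        t1, g1 = generate_trace(p)
        t2, g2 = generate_trace(p)
        np.testing.assert_array_equal(t1.values, t2.values)
        np.testing.assert_array_equal(g1.spike_times, g2.spike_times)

    def test_different_seeds_differ(self):
        t1, _ = generate_trace(osmolarity_to_params(420.0, WT, seed=1))
        t2, _ = generate_trace(osmolarity_to_params(420.0, WT, seed=2))
        assert not np.array_equal(t1.values, t2.values)

    def test_mean_interval_matches_plan_over_seeds(self):
        """Across many seeds the realized mean inter-event interval equals the
        planned period (independent of the detection pipeline)."""
        gaps = []
        for seed in range(100):
            p = osmolarity_to_params(535.0, WT, seed=seed, noise_sd=0.0)
            _, truth = generate_trace(p)
            gaps.extend(truth.class_periods("small"))
        period = germination_dynamics(535.0, WT)["small_period_s"]
        se = np.std(gaps, ddof=1) / np.sqrt(len(gaps))
        # grid snapping adds at most half a frame of rounding per gap
        assert abs(np.mean(gaps) - period) < 3 * se + 15.0

    def test_ground_truth_classes_recoverable_by_thresholding(self, wt_noisefree):
        _, _, truth = wt_noisefree
        for peak, cls in zip(truth.spike_peaks, truth.spike_classes):
            assert (cls == "large") == (peak >= 4.0)
            assert peak >= 1.0
            assert not (2.0 < peak < 4.0)  # the ambiguous band is never sampled


class TestOsmolarityMapping:
    OSMS = [150.0, 350.0, 420.0, 535.0, 680.0, 900.0]

    @pytest.mark.parametrize("genotype", [WT, MUTANT])
    def test_strictly_monotone_rate_amplitude_period(self, genotype):
        dyns = [germination_dynamics(o, genotype) for o in self.OSMS]
        for key in ("small_period_s", "large_period_s"):
            vals = [d[key] for d in dyns]
            assert all(a < b for a, b in zip(vals, vals[1:])), key
        for key in ("small_amp_lo", "large_amp_center"):
            vals = [d[key] for d in dyns]
            assert all(a > b for a, b in zip(vals, vals[1:])), key

    def test_mutant_slower_sparser_weaker_everywhere(self):
        for osm in self.OSMS:
            wt, mut = germination_dynamics(osm, WT), germination_dynamics(osm, MUTANT)
            assert mut["reph1_s"] > wt["reph1_s"]
            assert mut["small_period_s"] > wt["small_period_s"]
            assert mut["large_period_s"] > wt["large_period_s"]
            assert mut["small_amp_lo"] < wt["small_amp_lo"]
            assert mut["large_amp_center"] < wt["large_amp_center"]
            assert mut["reph2_s"] == 0.0  # abolished second resting phase

    def test_spike_rate_higher_at_lower_osmolarity(self):
        lo = osmolarity_to_params(350.0, WT).phase_plan
        hi = osmolarity_to_params(680.0, WT).phase_plan
        rate = lambda plan, lbl: next(b.spike_rate_per_min for b in plan.blocks if b.label == lbl)
        assert rate(lo, "CaOscS") > rate(hi, "CaOscS")
        assert rate(lo, "CaOscL") > rate(hi, "CaOscL")

    def test_out_of_range_osmolarity_rejected(self):
        with pytest.raises(InvalidInputError):
            osmolarity_to_params(50.0, WT)
        with pytest.raises(InvalidInputError):
            osmolarity_to_params(1200.0, WT)

    def test_deterministic_parameter_sets(self):
        assert osmolarity_to_params(420.0, WT, seed=3) == osmolarity_to_params(420.0, WT, seed=3)

    def test_within_train_gaps_stay_below_resting_criterion(self):
        """The jittered period never produces a within-train gap that the
        default segmentation would mistake for a resting phase."""
        for osm in self.OSMS:
            for geno in (WT, MUTANT):
                d = germination_dynamics(osm, geno)
                worst = max(d["small_period_s"], d["large_period_s"]) * (1 + PERIOD_JITTER)
                assert worst + 30.0 < 600.0


class TestShockTraces:
    def make(self, factor, n=3, noise=0.0, seed=0):
        p = osmolarity_to_params(500.0, WT, mode="shock", seed=seed, noise_sd=noise,
                                 n_shocks=n, desensitization_factor=factor)
        return generate_shock_trace(p)

    def test_no_desensitization_equal_peaks(self):
        _, truth = self.make(1.0, n=2)
        assert truth.shock_peaks[0] == pytest.approx(truth.shock_peaks[1])

    def test_half_desensitization_halves_peaks(self):
        _, truth = self.make(0.5, n=2)
        assert truth.shock_peaks[1] / truth.shock_peaks[0] == pytest.approx(0.5)

    def test_flat_before_shock(self):
        trace, truth = self.make(1.0, n=1)
        pre = trace.values[trace.times < truth.shock_times[0]]
        np.testing.assert_allclose(pre, 100.0, rtol=1e-12)

    def test_peak_increases_with_preincubation_osmolarity(self):
        peaks = []
        for osm in (300.0, 500.0, 700.0):
            p = osmolarity_to_params(osm, WT, mode="shock", seed=1, noise_sd=0.0)
            _, truth = generate_shock_trace(p)
            peaks.append(truth.shock_peaks[0])
        assert peaks[0] < peaks[1] < peaks[2]

    def test_missing_shock_params_rejected(self):
        with pytest.raises(InvalidInputError):
            generate_shock_trace(empty_plan_params())


class TestImageStack:
    def layout_params(self):
        plan = PhasePlan((
            PhaseBlock("RePh1", 600.0),
            PhaseBlock("CaOscL", 1200.0, "large", 500.0, amp_lo=4.5, amp_hi=6.0),
        ))
        return empty_plan_params(phase_plan=plan, n_frames=80, bleach_rate=0.0)

    def test_single_grain_roundtrip_within_quantization(self):
        from pollenca import extract_roi_traces

        params = self.layout_params()
        stack, rois, pairs = generate_image_stack(params, [(20.0, 20.0, 6.0)])
        assert stack.dtype == np.uint16
        [rec] = extract_roi_traces(stack, rois, params.frame_interval_s)
        np.testing.assert_allclose(rec.values, pairs[0][0].values, atol=0.5)

    def test_two_grains_recover_their_own_truths(self):
        from pollenca import extract_roi_traces

        params = self.layout_params()
        stack, rois, pairs = generate_image_stack(params, [(16.0, 16.0, 5.0), (46.0, 46.0, 5.0)])
        recs = extract_roi_traces(stack, rois, params.frame_interval_s)
        assert not np.array_equal(pairs[0][0].values, pairs[1][0].values)
        for rec, (truth_trace, _) in zip(recs, pairs):
            np.testing.assert_allclose(rec.values, truth_trace.values, atol=0.5)

    def test_overlapping_grains_rejected(self):
        with pytest.raises(InvalidLayoutError):
            generate_image_stack(self.layout_params(), [(20.0, 20.0, 8.0), (30.0, 20.0, 8.0)])

    def test_zero_grains_background_only(self):
        stack, rois, pairs = generate_image_stack(self.layout_params(), [], background=20.0)
        assert rois == [] and pairs == []
        assert np.all(stack == 20)


class TestCohort:
    def test_byte_identical_reruns(self):
        a = generate_cohort([WT], [350.0, 680.0], 3, seed=1)
        b = generate_cohort([WT], [350.0, 680.0], 3, seed=1)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.trace.values, rb.trace.values)

    def test_true_counts_decrease_with_osmolarity(self):
        recs = generate_cohort([WT], [350.0, 680.0], 6, seed=2, noise_sd=0.0)
        total = lambda osm: sum(r.truth.n_events for r in recs if r.osmolarity_mosm == osm)
        assert total(350.0) > total(680.0)

    def test_mutant_near_zero_large_events_at_high_osmolarity(self):
        recs = generate_cohort([MUTANT], [680.0], 6, seed=3, noise_sd=0.0)
        n_large = [r.truth.spike_classes.count("large") for r in recs]
        assert np.mean(n_large) <= 2.0
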