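"""Shared fixtures: synthetic traces reused by several test modules."""

import numpy as np
import pytest

from pollenca import (
    RawTrace,
    TraceMeta,
    generate_trace,
    osmolarity_to_params,
)


@pytest.fixture(scope="session")
def wt_noisefree():
    """Noise-free wild-type germination trace at standard osmolarity."""
    params = osmolarity_to_params(535.0, "WT", seed=11, noise_sd=0.0)
    trace, truth = generate_trace(params)
    return params, trace, truth


@pytest.fixture(scope="session")
def mutant_noisefree():
    params = osmolarity_to_params(535.0, "osca2.1/2.2", seed=11, noise_sd=0.0)
    trace, truth = generate_trace(params)
    return params, trace, truth


@pytest.fixture()
def flat_trace():
    """Constant-fluorescence trace (no events, no bleaching, no noise)."""
    times = np.arange(100) * 30.0
    return RawTrace(times, np.full(100, 100.0), "flat", TraceMeta(frame_interval_s=30.0))


def match_events(detected_times, truth_times, tol_s):
    """Greedy one-to-one matching; returns (n_matched, n_detected, n_truth)."""
    used = set()
    matched = 0
    for t in truth_times:
        best = None
        for i, d in enumerate(detected_times):
            if i in used or abs(d - t) > tol_s:
                continue
            if best is None or abs(d - t) < abs(detected_times[best] - t):
                best = i
        if best is not None:
            used.add(best)
            matched += 1
    return matched, len(detected_times), len(truth_times)
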