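"""Independent brute-force oracles, written as plain frame-by-frame scans.

These deliberately avoid numpy vectorization and the library's own helpers so
they can serve as an independent check of the detection semantics.
"""

from pollenca.spikes import DetectionConfig, SpikeEvent


def brute_force_detect(times, values, cfg: DetectionConfig) -> list[SpikeEvent]:
    """Exhaustive scan implementing the documented detection rules."""
    x = [float(v) for v in values]
    t = [float(v) for v in times]
    n = len(x)
    if n < 3:
        return []
    dt = t[1] - t[0]
    min_gap = cfg.min_gap_s if cfg.min_gap_s is not None else 2.0 * dt
    w = cfg.smoothing_width
    h = w // 2

    # moving average with reflect padding, one frame at a time
    padded = [x[h - i] for i in range(1, h + 1)][::-1] + x + [x[n - 2 - i] for i in range(h)]
    s = [sum(padded[i : i + w]) / w for i in range(n)]

    # interior local maxima of the smoothed series (plateau -> first frame)
    refined = {}
    for i in range(1, n - 1):
        if s[i] > s[i - 1] and s[i] >= s[i + 1]:
            lo, hi = max(0, i - h), min(n - 1, i + h)
            j, best = lo, x[lo]
            for k in range(lo, hi + 1):
                if x[k] > best:
                    j, best = k, x[k]
            if 0 < j < n - 1 and x[j] >= cfg.detect_min_dff:
                refined[j] = x[j]

    # greedy acceptance by descending raw height
    order = sorted(refined, key=lambda j: (-refined[j], t[j]))
    kept = []
    for j in order:
        if all(abs(t[j] - t[k]) >= min_gap for k in kept):
            kept.append(j)
    kept.sort()

    events = []
    for idx, j in enumerate(kept):
        thr = cfg.onset_fraction * x[j]
        k = j - 1
        while k > 0 and x[k] > thr:
            k -= 1
        onset = t[k]
        k = j + 1
        while k < n - 1 and x[k] > thr:
            k += 1
        offset = t[k]
        hi = kept[idx + 1] if idx + 1 < len(kept) else n
        if j + 1 < hi:
            trough = min(x[j + 1 : hi])
        else:
            trough = x[min(j + 1, n - 1)]
        cls = "large" if x[j] >= cfg.large_min_dff else "small"
        events.append(SpikeEvent(t[j], x[j], trough, onset, offset, cls))

    for i in range(len(events) - 1):
        a, b = events[i], events[i + 1]
        if a.offset_time > b.onset_time:
            events[i] = SpikeEvent(a.peak_time, a.peak_dff, a.trough_dff, a.onset_time,
                                   max(b.onset_time, a.peak_time + dt / 2), a.spike_class)
    for i in range(1, len(events)):
        a, b = events[i - 1], events[i]
        if b.onset_time < a.offset_time:
            events[i] = SpikeEvent(b.peak_time, b.peak_dff, b.trough_dff,
                                   min(a.offset_time, b.peak_time - dt / 2), b.offset_time, b.spike_class)
    return events


def brute_force_stable_window(values, window, cv_max):
    """Earliest window with CV <= cv_max, by scanning every start index."""
    n = len(values)
    for start in range(n - window + 1):
        seg = [float(v) for v in values[start : start + window]]
        m = sum(seg) / window
        if m <= 0:
            continue
        var = sum((v - m) ** 2 for v in seg) / window
        if (var**0.5) / m <= cv_max:
            return (start, start + window)
    return None
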