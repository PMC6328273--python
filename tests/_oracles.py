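"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive Python scans (not the package's vectorized
paths) so that agreement is a meaningful check.
"""

from __future__ import annotations

import numpy as np


def brute_segment(times, max_isi, min_spikes):
    """O(n) run scan: maximal runs with consecutive gaps <= max_isi."""
    times = list(times)
    if not times:
        return []
    runs, cur = [], [times[0]]
    for a, b in zip(times[:-1], times[1:]):
        if b - a <= max_isi:
            cur.append(b)
        else:
            runs.append(cur)
            cur = [b]
    runs.append(cur)
    return [r for r in runs if len(r) >= min_spikes]


def brute_bin_means(times, values, window, width):
    """Group-by loop over bins; empty bins are (nan, 0)."""
    start, end = window
    n_bins = int(np.floor((end - start) / width))
    out = []
    for k in range(n_bins):
        lo, hi = start + k * width, start + (k + 1) * width
        vals = [v for t, v in zip(times, values) if lo <= t < hi]
        out.append((np.mean(vals) if vals else np.nan, len(vals)))
    return out


def brute_annotate(times, labels, min_sustain, window):
    """Pointer scan implementing the sustained-transition rule directly."""
    w0, w1 = window
    n = len(labels)
    ends = list(times[1:]) + [w1]
    committed = labels[0]
    segs = [(committed, w0)]
    k = 1
    while k < n:
        if labels[k] == committed:
            k += 1
            continue
        j = k
        while j < n and labels[j] == labels[k]:
            j += 1
        run_duration = ends[j - 1] - times[k]
        if run_duration >= min_sustain - 1e-9 or j == n:
            committed = labels[k]
            segs.append((committed, times[k]))
        k = j
    out = []
    for i, (lab, s) in enumerate(segs):
        e = segs[i + 1][1] if i + 1 < len(segs) else w1
        out.append((lab, s, e))
    return out
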