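"""Spike detection, burst segmentation, and cycle/binned rhythm metrics.

The quantities follow the standard conventions for pyloric/cardiac rhythm
analysis: the cycle period is onset-to-next-onset of consecutive bursts,
instantaneous burst frequency is its reciprocal, and duty cycle is burst
duration (first to last spike) divided by the period. Summaries over an
analysis window are arithmetic means in uniform 10-s half-open bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import BinnedSeries, Burst, CycleMetrics, SpikeTrain, Trace

__all__ = [
    "ThresholdSpec",
    "detect_spikes",
    "segment_bursts",
    "cycle_metrics",
    "firing_rate",
    "bin_means",
    "DEFAULT_BIN_S",
]

DEFAULT_BIN_S = 10.0


@dataclass(frozen=True)
class ThresholdSpec:
    """Spike threshold: absolute (mV) or adaptive ``median + k * robust SD``.

    The robust SD is ``1.4826 * MAD`` of the whole trace, which keeps the
    threshold stable when bursts dominate the amplitude histogram.
    """

    absolute_mv: float | None = None
    k_mad: float = 4.0

    def level(self, samples: np.ndarray) -> float:
        if self.absolute_mv is not None:
            return float(self.absolute_mv)
        med = float(np.median(samples))
        robust_sd = 1.4826 * float(np.median(np.abs(samples - med)))
        return med + self.k_mad * robust_sd


def detect_spikes(trace: Trace, threshold: ThresholdSpec | float | None = None,
                  refractory: float = 0.002) -> SpikeTrain:
    """Detect spikes as upward threshold crossings of a voltage trace.

    One event is emitted per upward crossing, timestamped at the local
    maximum between the crossing and the following downward crossing.
    Events closer than ``refractory`` (default 2 ms) to the previous kept
    event are discarded.
    """
    if not isinstance(trace, Trace):
        raise TypeError("detect_spikes expects a Trace")
    v = trace.samples
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("trace is empty or contains non-finite samples")
    if isinstance(threshold, (int, float)):
        threshold = ThresholdSpec(absolute_mv=float(threshold))
    elif threshold is None:
        threshold = ThresholdSpec()
    thr = threshold.level(v)

    above = v >= thr
    up = np.flatnonzero(~above[:-1] & above[1:]) + 1
    down = np.flatnonzero(above[:-1] & ~above[1:]) + 1

    times = []
    last = -np.inf
    for i in up:
        j = down[np.searchsorted(down, i)] if np.searchsorted(down, i) < down.size else v.size
        peak = i + int(np.argmax(v[i:j]))
        t = trace.start_time + peak / trace.sample_rate
        if t - last >= refractory:
            times.append(t)
            last = t
    return SpikeTrain(np.asarray(times), trace.label)


def segment_bursts(spikes: SpikeTrain, max_intraburst_isi: float,
                   min_spikes: int = 1) -> list[Burst]:
    """Group spikes into bursts by the inter-spike-interval gap criterion.

    Maximal runs of spikes whose consecutive ISIs are all
    ``<= max_intraburst_isi`` form candidate bursts; runs with fewer than
    ``min_spikes`` spikes are discarded. The burst period (onset to next
    onset) is attached to every burst except the last.

    An empty train yields an empty list.
    """
    if max_intraburst_isi <= 0:
        raise ValueError("max_intraburst_isi must be positive")
    if min_spikes < 1:
        raise ValueError("min_spikes must be >= 1")
    t = spikes.times
    if t.size == 0:
        return []
    # split indices where the gap exceeds the criterion
    gaps = np.flatnonzero(np.diff(t) > max_intraburst_isi) + 1
    runs = [r for r in np.split(t, gaps) if r.size >= min_spikes]
    bursts: list[Burst] = []
    for i, r in enumerate(runs):
        period = runs[i + 1][0] - r[0] if i + 1 < len(runs) else None
        bursts.append(Burst(r, period))
    return bursts


def cycle_metrics(bursts: list[Burst]) -> CycleMetrics:
    """Per-cycle frequency, spikes/burst and duty cycle from a burst list.

    The final burst is excluded (it has no onset-to-next-onset period).
    Fewer than two bursts yield empty metrics with a warning.
    """
    complete = [b for b in bursts if b.period is not None]
    if len(bursts) < 2 or not complete:
        warnings.warn("fewer than two bursts: no complete cycle to measure",
                      stacklevel=2)
        return CycleMetrics()
    onset = np.array([b.onset for b in complete])
    period = np.array([b.period for b in complete])
    dur = np.array([b.duration for b in complete])
    return CycleMetrics(
        cycle_onset=onset,
        frequency=1.0 / period,
        spikes_per_burst=np.array([b.n_spikes for b in complete], dtype=float),
        duty_cycle=dur / period,
    )


def firing_rate(spikes: SpikeTrain) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous firing rate, the reciprocal of each inter-spike interval.

    Returns ``(times, rates)`` with one value per consecutive spike pair,
    timestamped at the earlier spike. Fewer than two spikes yield empty
    arrays.
    """
    t = spikes.times
    if t.size < 2:
        return np.empty(0), np.empty(0)
    return t[:-1].copy(), 1.0 / np.diff(t)


def bin_means(times: np.ndarray, values: np.ndarray, window: tuple[float, float],
              bin_width: float = DEFAULT_BIN_S) -> BinnedSeries:
    """Arithmetic means of a timestamped series in uniform half-open bins.

    Bins are aligned to the window start; ``n_bins = floor(len/width)``, so
    an 8-min window with 10-s bins yields exactly 48 bins. Values whose
    timestamps fall outside ``[start, start + n_bins*width)`` are ignored;
    empty bins are reported as ``nan`` with count 0.
    """
    start, end = window
    if end - start < bin_width:
        raise ValueError("analysis window is shorter than one bin")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValueError("times and values must have the same shape")
    n_bins = int(np.floor((end - start) / bin_width))
    edges = start + bin_width * np.arange(n_bins + 1)
    idx = np.floor((times - start) / bin_width).astype(int)
    ok = (times >= start) & (idx < n_bins) & (idx >= 0)
    counts = np.bincount(idx[ok], minlength=n_bins)
    sums = np.bincount(idx[ok], weights=values[ok], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinnedSeries(bin_edges=edges, bin_means=means, n_per_bin=counts)
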