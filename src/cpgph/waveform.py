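"""Intracellular waveform measures: slow-wave/spike decomposition.

The intracellular trace is split into a slow wave (zero-phase low-pass
filtered membrane oscillation) and a residual containing the spikes
(``residual = trace - slow``, so the decomposition reconstructs the trace
exactly). From these the standard intracellular measures are computed:
minimum membrane potential between bursts, slow-wave amplitude per cycle,
spike amplitude (trough to peak of the residual around each spike), and
burst frequency from consecutive slow-wave troughs.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .core import Burst, SpikeTrain, Trace

__all__ = [
    "decompose_slow_wave",
    "min_membrane_potential",
    "slow_wave_amplitude",
    "spike_amplitude",
    "trough_frequency",
    "DEFAULT_CUTOFF_HZ",
]

#: Default low-pass cutoff for pyloric-range rhythms (well above the burst
#: frequency, far below the spike band of a ~3 ms action potential).
DEFAULT_CUTOFF_HZ = 10.0


def decompose_slow_wave(trace: Trace, cutoff: float = DEFAULT_CUTOFF_HZ,
                        order: int = 4) -> tuple[Trace, Trace]:
    """Split a trace into slow wave and spike residual.

    The slow wave is a zero-phase (forward-backward) Butterworth low-pass
    of the trace; the residual is the sample-wise difference, so
    ``slow + residual == trace`` exactly.
    """
    nyq = trace.sample_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, Nyquist={nyq} Hz)")
    sos = sps.butter(order, cutoff, btype="low", fs=trace.sample_rate, output="sos")
    # pad a few filter time constants so edge transients do not leak into
    # the slow wave (the default pad is too short for low cutoffs)
    padlen = min(len(trace) - 1, int(3 * trace.sample_rate / cutoff))
    slow = sps.sosfiltfilt(sos, trace.samples, padlen=padlen)
    residual = trace.samples - slow
    return (Trace(slow, trace.sample_rate, trace.start_time, trace.label),
            Trace(residual, trace.sample_rate, trace.start_time, trace.label))


def min_membrane_potential(trace: Trace, bursts: list[Burst]
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Minimum voltage in each inter-burst interval.

    Returns ``(times, minima)`` with one value per interval
    ``(offset_i, onset_{i+1})``, timestamped at the argmin. An empty result
    is returned when fewer than two bursts bracket an interval.
    """
    times, minima = [], []
    for a, b in zip(bursts[:-1], bursts[1:]):
        seg = trace.slice(a.offset, b.onset) if b.onset > a.offset else None
        if seg is None or len(seg) == 0:
            continue
        i = int(np.argmin(seg.samples))
        times.append(seg.start_time + i / seg.sample_rate)
        minima.append(float(seg.samples[i]))
    return np.asarray(times), np.asarray(minima)


def slow_wave_amplitude(slow: Trace, cycle_bounds: np.ndarray) -> np.ndarray:
    """Trough-to-peak slow-wave amplitude per cycle.

    ``cycle_bounds`` are ordered cycle boundary times (slow-wave troughs or
    burst onsets); the amplitude of cycle i is ``max - min`` of the slow
    wave over ``[bounds[i], bounds[i+1])``. Cycles shorter than two samples
    are skipped with a warning.
    """
    cycle_bounds = np.asarray(cycle_bounds, dtype=float)
    amps = []
    for t0, t1 in zip(cycle_bounds[:-1], cycle_bounds[1:]):
        if (t1 - t0) * slow.sample_rate < 2:
            warnings.warn(f"cycle [{t0:.3f}, {t1:.3f}) shorter than 2 samples; skipped",
                          stacklevel=2)
            continue
        seg = slow.slice(t0, t1).samples
        amps.append(float(seg.max() - seg.min()))
    return np.asarray(amps)


def spike_amplitude(residual: Trace, spikes: SpikeTrain,
                    half_width: float = 0.0045) -> np.ndarray:
    """Trough-to-peak residual amplitude around each spike.

    The window is ``spike time +/- half_width`` (default 4.5 ms, 1.5x the
    3 ms template width). Spikes whose window extends past the trace edge
    are skipped.
    """
    amps = []
    for ts in spikes.times:
        t0, t1 = ts - half_width, ts + half_width
        if t0 < residual.start_time or t1 > residual.end_time:
            continue
        seg = residual.slice(t0, t1).samples
        amps.append(float(seg.max() - seg.min()))
    return np.asarray(amps)


def trough_frequency(slow: Trace, level_fraction: float = 0.25
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Burst frequency from consecutive slow-wave troughs.

    One trough is located per excursion of the slow wave below a level
    ``level_fraction`` of the overall excursion (95th - 5th percentile,
    robust to edge transients) above its floor, at the midpoint of the
    sub-level region. The region midpoint is phase-stable even when the
    inter-burst trough is flat, where the raw sample argmin is set by
    numerical ripple. Regions truncated by the trace edges are dropped.

    Returns ``(trough_times, frequencies)`` with one frequency per
    consecutive trough pair (``1 / dt``, timestamped at the earlier
    trough); fewer than two troughs yield empty arrays.
    """
    v = slow.samples
    lo, hi = np.percentile(v, [5, 95])
    excursion = float(hi - lo)
    if excursion <= 0:
        return np.empty(0), np.empty(0)
    below = v < lo + level_fraction * excursion
    starts = np.flatnonzero(~below[:-1] & below[1:]) + 1
    ends = np.flatnonzero(below[:-1] & ~below[1:]) + 1
    if below[0]:  # truncated leading region
        ends = ends[1:] if ends.size else ends
    if below[-1]:  # truncated trailing region
        starts = starts[:-1] if starts.size else starts
    n = min(starts.size, ends.size)
    if n < 2:
        return np.empty(0), np.empty(0)
    mid = 0.5 * (starts[:n] + ends[:n] - 1)
    t = slow.start_time + mid / slow.sample_rate
    return t[:-1], 1.0 / np.diff(t)
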