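"""Core containers for rhythm analysis.

Time convention: seconds, 0-based from recording start; all intervals are
half-open ``[start, end)``. Voltages are millivolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trace", "SpikeTrain", "Burst", "CycleMetrics", "BinnedSeries"]


@dataclass
class Trace:
    """A regularly sampled single-channel voltage recording.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in mV.
    sample_rate : float
        Sampling rate in Hz; must be positive.
    start_time : float
        Time of the first sample, seconds.
    label : str
        Unit or nerve name (e.g. ``"PD"``, ``"lvn"``).
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("trace must be a non-empty 1-D array")
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sample_rate

    def slice(self, start: float, end: float) -> "Trace":
        """Return the sub-trace covering ``[start, end)``."""
        i0 = max(0, int(np.ceil((start - self.start_time) * self.sample_rate - 1e-9)))
        i1 = min(len(self), int(np.ceil((end - self.start_time) * self.sample_rate - 1e-9)))
        if i1 <= i0:
            raise ValueError(f"empty slice [{start}, {end}) of trace spanning "
                             f"[{self.start_time}, {self.end_time})")
        return Trace(self.samples[i0:i1], self.sample_rate,
                     self.start_time + i0 / self.sample_rate, self.label)


@dataclass
class SpikeTrain:
    """Sorted spike event times (seconds) for one labelled unit."""

    times: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be 1-D")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def between(self, start: float, end: float) -> "SpikeTrain":
        """Spikes with times in ``[start, end)``."""
        m = (self.times >= start) & (self.times < end)
        return SpikeTrain(self.times[m], self.label)


@dataclass
class Burst:
    """A group of spikes; onset/offset are first/last spike times.

    ``period`` is onset-to-next-onset and is ``None`` for the final burst
    of a train.
    """

    spike_times: np.ndarray
    period: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size == 0:
            raise ValueError("a burst must contain at least one spike")
        if self.period is not None and self.period <= self.duration:
            raise ValueError("burst period must exceed burst duration")

    @property
    def onset(self) -> float:
        return float(self.spike_times[0])

    @property
    def offset(self) -> float:
        return float(self.spike_times[-1])

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class CycleMetrics:
    """Per-cycle rhythm measures (final burst excluded: it has no period)."""

    cycle_onset: np.ndarray = field(default_factory=lambda: np.empty(0))
    frequency: np.ndarray = field(default_factory=lambda: np.empty(0))
    spikes_per_burst: np.ndarray = field(default_factory=lambda: np.empty(0))
    duty_cycle: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return self.cycle_onset.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle_onset": self.cycle_onset,
            "frequency": self.frequency,
            "spikes_per_burst": self.spikes_per_burst,
            "duty_cycle": self.duty_cycle,
        })


@dataclass
class BinnedSeries:
    """Means of a timestamped series over uniform half-open bins.

    Empty bins hold ``nan`` (missing, not zero) and ``n_per_bin`` 0.
    """

    bin_edges: np.ndarray
    bin_means: np.ndarray
    n_per_bin: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.bin_means.size

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "mean": self.bin_means,
            "n": self.n_per_bin,
        })
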