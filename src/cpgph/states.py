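"""Rule-based rhythm-state classification and sustained-state annotation.

Pyloric activity is classified into five states (normal triphasic, weak
triphasic, intermittent triphasic, all silent, atypical) and cardiac
activity into four (SC and LC bursting, SC only, all silent, atypical).
Candidate labels from short sliding evaluation windows are turned into a
state annotation with a hysteresis rule: a transition is committed only
when the new state is maintained for at least 10 s, and shorter excursions
are absorbed into the surrounding state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Burst, SpikeTrain
from .metrics import segment_bursts

__all__ = [
    "PYLORIC_STATES",
    "CARDIAC_STATES",
    "RHYTHMIC_STATES",
    "UnitActivity",
    "StateAnnotation",
    "window_activity",
    "classify_window",
    "annotate_states",
    "annotate_window",
    "state_fractions",
    "rhythmicity",
]

PYLORIC_STATES = ("normal_triphasic", "weak_triphasic", "intermittent_triphasic",
                  "all_silent", "atypical")
CARDIAC_STATES = ("sc_lc_bursting", "sc_only", "all_silent", "atypical")

#: States counting as a "normal rhythm" for the rhythmicity metric:
#: triphasic (normal or weak) for the STG, SC-and-LC bursting for the CG.
RHYTHMIC_STATES = {
    "STG": frozenset({"normal_triphasic", "weak_triphasic"}),
    "CG": frozenset({"sc_lc_bursting"}),
}

DEFAULT_MIN_SUSTAIN_S = 10.0


def _admissible(ganglion: str) -> tuple[str, ...]:
    if ganglion == "STG":
        return PYLORIC_STATES
    if ganglion == "CG":
        return CARDIAC_STATES
    raise ValueError(f"unknown ganglion {ganglion!r}")


@dataclass
class UnitActivity:
    """One unit's activity inside an evaluation window."""

    n_spikes: int
    bursts: list[Burst]

    @property
    def periods(self) -> np.ndarray:
        return np.array([b.period for b in self.bursts if b.period is not None])

    def is_cycling(self, cv_max: float = 1.0) -> bool:
        """A unit counts as cycling with >= 2 bursts of regular period
        (coefficient of variation below ``cv_max``)."""
        if len(self.bursts) < 2:
            return False
        p = self.periods
        if p.size == 0 or np.any(p <= 0):
            return False
        return float(np.std(p) / np.mean(p)) < cv_max

    def spikes_per_burst(self) -> float:
        """Median spikes per burst (nan without bursts)."""
        if not self.bursts:
            return float("nan")
        return float(np.median([b.n_spikes for b in self.bursts]))


def window_activity(spike_trains: dict[str, SpikeTrain],
                    window: tuple[float, float],
                    max_intraburst_isi: float,
                    min_spikes: int = 1) -> dict[str, UnitActivity]:
    """Windowed per-unit activity for classification.

    Bursts overlapping the window edges (within one ISI criterion of the
    boundary) are dropped so that truncated bursts do not masquerade as
    weak ones.
    """
    w0, w1 = window
    out = {}
    for unit, train in spike_trains.items():
        sub = train.between(w0, w1)
        bursts = segment_bursts(sub, max_intraburst_isi, min_spikes)
        kept = [b for b in bursts
                if b.onset >= w0 + max_intraburst_isi
                and b.offset <= w1 - max_intraburst_isi]
        out[unit] = UnitActivity(n_spikes=len(sub), bursts=kept)
    return out


def classify_window(activity: dict[str, UnitActivity], ganglion: str,
                    full_spikes: int = 3, cv_max: float = 1.0,
                    lc_consistency: float = 0.9) -> str:
    """Deterministic rhythm-state label for one evaluation window.

    Pyloric precedence: silence on all units -> ``all_silent``; a silent
    unit while others cycle -> ``intermittent_triphasic`` (absence
    dominates weakness); all three units cycling with at least
    ``full_spikes`` spikes per burst each -> ``normal_triphasic``; all
    cycling but some unit spiking only once or twice -> ``weak_triphasic``;
    anything else (e.g. tonic firing without cycles) -> ``atypical``.

    Cardiac: SC bursts each carrying at least one LC spike (in at least
    ``lc_consistency`` of bursts) -> ``sc_lc_bursting``; SC bursting with
    absent or inconsistent LC spiking -> ``sc_only``; no spikes ->
    ``all_silent``; otherwise ``atypical``.
    """
    states = _admissible(ganglion)
    if sum(a.n_spikes for a in activity.values()) == 0:
        return "all_silent"
    if ganglion == "STG":
        if set(activity) != {"PD", "LP", "PY"}:
            raise ValueError("pyloric classification needs PD, LP and PY activity")
        cycling = {u: a.is_cycling(cv_max) for u, a in activity.items()}
        silent = [u for u, a in activity.items() if a.n_spikes == 0]
        if silent and any(cycling.values()):
            return "intermittent_triphasic"
        if all(cycling.values()):
            spb = [a.spikes_per_burst() for a in activity.values()]
            if all(s >= full_spikes for s in spb):
                return "normal_triphasic"
            return "weak_triphasic"
        return "atypical"
    # cardiac
    if set(activity) != {"SC", "LC"}:
        raise ValueError("cardiac classification needs SC and LC activity")
    sc, lc = activity["SC"], activity["LC"]
    if not sc.is_cycling(cv_max):
        return "atypical"
    if lc.n_spikes > 0 and sc.bursts:
        lc_times = np.concatenate([b.spike_times for b in lc.bursts]) \
            if lc.bursts else np.empty(0)
        # count LC spikes inside each SC burst span
        hits = sum(
            1 for b in sc.bursts
            if np.any((lc_times >= b.onset) & (lc_times <= b.offset)))
        if hits / len(sc.bursts) >= lc_consistency:
            return "sc_lc_bursting"
    return "sc_only"


@dataclass
class StateAnnotation:
    """Contiguous labelled segments covering an analysis window.

    Interior segments last at least the sustain threshold; the first and
    last segments may be truncated by the window.
    """

    segments: list[tuple[str, float, float]]
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("annotation has no segments")
        w0, w1 = self.window
        if abs(self.segments[0][1] - w0) > 1e-9 or abs(self.segments[-1][2] - w1) > 1e-9:
            raise ValueError("segments do not cover the window")
        for (_, _, e0), (_, s1, _) in zip(self.segments[:-1], self.segments[1:]):
            if abs(e0 - s1) > 1e-9:
                raise ValueError("segments are not contiguous")

    @property
    def duration(self) -> float:
        return self.window[1] - self.window[0]

    def state_at(self, t: float) -> str:
        for state, s, e in self.segments:
            if s - 1e-12 <= t < e:
                return state
        return self.segments[-1][0]


def annotate_states(times: np.ndarray, labels: list[str],
                    min_sustain: float = DEFAULT_MIN_SUSTAIN_S,
                    window: tuple[float, float] | None = None) -> StateAnnotation:
    """Turn a time-ordered candidate label stream into a state annotation.

    A new state is committed only once it has been held for at least
    ``min_sustain`` seconds, with the transition stamped at the start of
    the sustained run; shorter excursions are absorbed into the surrounding
    state. The first run is always committed (window edge), and the final
    run is committed even when short, since it is truncated by the window
    rather than demonstrably transient.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or len(labels) != times.size:
        raise ValueError("empty label stream or mismatched times/labels")
    if times.size > 1:
        dt = float(np.median(np.diff(times)))
        if dt <= 0:
            raise ValueError("label times must be increasing")
        if dt > min_sustain:
            raise ValueError("label stream is coarser than the sustain threshold")
    else:
        dt = min_sustain
    if window is None:
        window = (float(times[0]), float(times[-1]) + dt)
    w0, w1 = window

    # run-length encode the label stream
    runs: list[tuple[str, float, float]] = []  # (label, start, end)
    start = w0
    for i in range(1, times.size):
        if labels[i] != labels[i - 1]:
            runs.append((labels[i - 1], start, float(times[i])))
            start = float(times[i])
    runs.append((labels[-1], start, w1))

    committed: list[tuple[str, float]] = [(runs[0][0], w0)]
    for j, (lab, s, e) in enumerate(runs[1:], start=1):
        sustained = (e - s) >= min_sustain - 1e-9 or j == len(runs) - 1
        if sustained and lab != committed[-1][0]:
            committed.append((lab, s))

    segments = [
        (lab, s, committed[k + 1][1] if k + 1 < len(committed) else w1)
        for k, (lab, s) in enumerate(committed)
    ]
    return StateAnnotation(segments, (w0, w1))


def annotate_window(spike_trains: dict[str, SpikeTrain],
                    window: tuple[float, float], ganglion: str,
                    max_intraburst_isi: float = 0.25,
                    eval_window: float = 10.0, stride: float = 1.0,
                    min_sustain: float = DEFAULT_MIN_SUSTAIN_S,
                    **classify_kw) -> StateAnnotation:
    """Classify sliding evaluation windows and annotate with hysteresis.

    Evaluation windows of ``eval_window`` seconds advance by ``stride``
    over the analysis window; each label is assigned to the stride slot at
    the window start, and the resulting stream is run through
    :func:`annotate_states`.
    """
    w0, w1 = window
    if w1 - w0 < eval_window:
        raise ValueError("analysis window shorter than one evaluation window")
    starts = np.arange(w0, w1 - eval_window + 1e-9, stride)
    labels = []
    for s in starts:
        act = window_activity(spike_trains, (s, s + eval_window), max_intraburst_isi)
        labels.append(classify_window(act, ganglion, **classify_kw))
    return annotate_states(starts, labels, min_sustain, window=(w0, w1))


def state_fractions(annotation: StateAnnotation,
                    ganglion: str | None = None) -> dict[str, float]:
    """Fraction of the window spent in each state (sums to 1).

    With ``ganglion`` given, every admissible state appears in the result,
    zero-filled when unvisited.
    """
    if annotation.duration <= 0:
        raise ValueError("zero-length annotation window")
    out: dict[str, float] = {s: 0.0 for s in _admissible(ganglion)} if ganglion else {}
    for state, s, e in annotation.segments:
        out[state] = out.get(state, 0.0) + (e - s) / annotation.duration
    return out


def rhythmicity(annotation: StateAnnotation, ganglion: str) -> float:
    """Fraction of time with a normal rhythm: triphasic (normal or weak)
    for the STG, SC-and-LC bursting for the CG."""
    rhythmic = RHYTHMIC_STATES[ganglion]
    return sum(f for s, f in state_fractions(annotation).items() if s in rhythmic)
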