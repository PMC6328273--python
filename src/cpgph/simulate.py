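"""Synthetic bursting-neuron recordings with known ground truth.

The generator emulates the statistical structure that the analysis pipeline
assumes: slow-wave bursting with stereotyped spikes riding the depolarized
plateau, triphasic (PD/LP/PY) or cardiac (SC/LC) patterning, additive
Gaussian noise, and a pH-dependent modulation of frequency, spikes per
burst, amplitudes and rhythm state over a stepped superfusion protocol.

Waveform model
--------------
Each cycle of period ``T = 1/burst_frequency`` contains a raised-cosine
plateau: a half-cosine ramp up (``RAMP_FRACTION`` of the period), a flat
top lasting ``duty_cycle * T``, and a half-cosine ramp down; the baseline
between bursts sits exactly at ``v_min`` and the flat top at
``v_min + slow_amplitude``. Spikes are monophasic raised-cosine bumps of
fixed width (3 ms) whose peaks span the flat top exactly, so that the
first-to-last-spike span equals ``duty_cycle * T`` and the global extrema
of a noiseless trace are ``v_min`` and
``v_min + slow_amplitude + spike_amplitude`` by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import SpikeTrain, Trace
from .protocol import PHProtocol, PHStep, build_protocol

__all__ = [
    "InfeasibleParametersError",
    "BursterParams",
    "PHResponseCurve",
    "StepGroundTruth",
    "Experiment",
    "burst_event_times",
    "generate_burster_trace",
    "apply_ph_response",
    "apply_state",
    "generate_experiment",
    "sample_population",
    "generate_null_dataset",
    "simulate_rhythmicity_table",
    "generate_correlated_frequencies",
    "default_pyloric_curve",
    "default_cardiac_curves",
    "default_stg_base_params",
    "default_cg_base_params",
    "STG_UNITS",
    "CG_UNITS",
]

SPIKE_WIDTH_S = 0.003
RAMP_FRACTION = 0.15

STG_UNITS = ("PD", "LP", "PY")
CG_UNITS = ("SC", "LC")

class InfeasibleParametersError(ValueError):
    """Spike count, refractory width and plateau duration are inconsistent."""


@dataclass(frozen=True)
class BursterParams:
    """Ground-truth parameters of one bursting unit.

    burst_frequency : Hz, > 0
    duty_cycle : fraction of the period occupied by the spike-carrying
        plateau, in (0, 1)
    spikes_per_burst : integer >= 0
    v_min : inter-burst minimum membrane potential, mV
    slow_amplitude : trough-to-peak of the slow wave, mV, >= 0
    spike_amplitude : trough-to-peak of each spike above the slow wave, mV
    noise_sd : additive white Gaussian noise SD, mV
    phase_offset : cycle-start offset as a fraction of the period, [0, 1)
    """

    burst_frequency: float = 1.0
    duty_cycle: float = 0.30
    spikes_per_burst: int = 5
    v_min: float = -55.0
    slow_amplitude: float = 20.0
    spike_amplitude: float = 10.0
    noise_sd: float = 0.5
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.burst_frequency > 0:
            raise ValueError("burst_frequency must be > 0")
        if not 0 < self.duty_cycle < 1:
            raise ValueError("duty_cycle must be in (0, 1)")
        if self.spikes_per_burst < 0:
            raise ValueError("spikes_per_burst must be >= 0")
        for name in ("slow_amplitude", "spike_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.phase_offset < 1:
            raise ValueError("phase_offset must be in [0, 1)")

    @property
    def period(self) -> float:
        return 1.0 / self.burst_frequency

    def ramp_fraction(self) -> float:
        # keep a true baseline between bursts: ramps never close the gap
        return min(RAMP_FRACTION, 0.45 * (1.0 - self.duty_cycle))


def _check_feasible(params: BursterParams) -> None:
    n = params.spikes_per_burst
    if n == 0:
        return
    plateau = params.duty_cycle * params.period
    if plateau < SPIKE_WIDTH_S:
        raise InfeasibleParametersError(
            f"plateau {plateau * 1e3:.1f} ms shorter than the {SPIKE_WIDTH_S * 1e3:.0f} ms "
            "spike template")
    if n >= 2 and plateau / (n - 1) < SPIKE_WIDTH_S:
        raise InfeasibleParametersError(
            f"{n} spikes do not fit a {plateau * 1e3:.1f} ms plateau at "
            f"{SPIKE_WIDTH_S * 1e3:.0f} ms spacing")


def burst_event_times(params: BursterParams, duration: float, t0: float = 0.0
                      ) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Analytic spike times and plateau (flat-top) windows for complete bursts.

    A burst is complete when its whole envelope bump lies inside
    ``[t0, t0 + duration)``; each complete plateau carries exactly
    ``spikes_per_burst`` spikes whose peaks span the flat top.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    _check_feasible(params)
    T = params.period
    r = params.ramp_fraction()
    d = params.duty_cycle
    spikes: list[float] = []
    plateaus: list[tuple[float, float]] = []
    k0 = int(math.floor(-params.phase_offset))
    k = k0
    while True:
        cyc = t0 + (k + params.phase_offset) * T
        k += 1
        if cyc < t0 - 1e-12:
            continue
        bump_end = cyc + (2 * r + d) * T
        if bump_end > t0 + duration + 1e-12:
            break
        flat0 = cyc + r * T
        flat1 = flat0 + d * T
        plateaus.append((flat0, flat1))
        n = params.spikes_per_burst
        if n == 1:
            spikes.append(0.5 * (flat0 + flat1))
        elif n >= 2:
            spikes.extend(np.linspace(flat0, flat1, n))
    return np.asarray(spikes), plateaus


def _envelope(phase: np.ndarray, duty: float, ramp: float) -> np.ndarray:
    """Raised-cosine burst envelope in [0, 1] as a function of cycle phase."""
    e = np.zeros_like(phase)
    up = (phase >= 0) & (phase < ramp)
    e[up] = 0.5 * (1 - np.cos(np.pi * phase[up] / ramp))
    e[(phase >= ramp) & (phase <= ramp + duty)] = 1.0
    down = (phase > ramp + duty) & (phase < 2 * ramp + duty)
    e[down] = 0.5 * (1 + np.cos(np.pi * (phase[down] - ramp - duty) / ramp))
    return e


def _render(params: BursterParams, n_samples: int, sample_rate: float,
            t0: float, step_origin: float,
            event_horizon: float | None = None) -> np.ndarray:
    """Noiseless waveform samples for ``n_samples`` starting at time ``t0``.

    ``step_origin`` anchors the cycle grid (cycles start at
    ``step_origin + (k + phase_offset) * T``); ``event_horizon`` is the span
    (from the origin) over which bursts count as complete and carry spikes
    — it defaults to the rendered window, but a partial rendering of a
    longer recording passes the full recording span so that spikes of
    bursts straddling the window edge are not dropped.
    """
    t = t0 + np.arange(n_samples) / sample_rate
    T = params.period
    r = params.ramp_fraction()
    phase = ((t - step_origin) / T - params.phase_offset) % 1.0
    v = params.v_min + params.slow_amplitude * _envelope(phase, params.duty_cycle, r)
    if event_horizon is None:
        event_horizon = (t[-1] - step_origin) + 1.0 / sample_rate
    # spikes only on complete plateaus
    spike_times, _ = burst_event_times(params, duration=event_horizon,
                                       t0=step_origin)
    w = SPIKE_WIDTH_S
    for ts in spike_times:
        i0 = max(0, int(np.ceil((ts - w / 2 - t0) * sample_rate)))
        i1 = min(n_samples, int(np.floor((ts + w / 2 - t0) * sample_rate)) + 1)
        if i1 <= i0:
            continue
        tt = t0 + np.arange(i0, i1) / sample_rate
        v[i0:i1] += params.spike_amplitude * 0.5 * (1 + np.cos(2 * np.pi * (tt - ts) / w))
    return v


def generate_burster_trace(params: BursterParams, duration: float,
                           sample_rate: float, seed: int = 0,
                           label: str = "") -> Trace:
    """Generate a voltage trace of a single bursting unit.

    The trace has exactly ``round(duration * sample_rate)`` samples,
    contains one complete burst per full cycle inside the window, and adds
    white Gaussian noise of SD ``noise_sd``. Identical ``params`` and
    ``seed`` give bit-identical traces.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate < 1000:
        raise ValueError("sample_rate must be >= 1000 Hz to resolve spikes")
    _check_feasible(params)
    n = int(round(duration * sample_rate))
    v = _render(params, n, sample_rate, t0=0.0, step_origin=0.0)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, params.noise_sd, n)
    return Trace(v, sample_rate, 0.0, label)


# ---------------------------------------------------------------------------
# pH response curves

_MODULATED = ("burst_frequency", "duty_cycle", "spikes_per_burst",
              "v_min", "slow_amplitude", "spike_amplitude")


def _interp(table: tuple[tuple[float, float], ...], ph: float, default: float) -> float:
    if not table:
        return default
    xs = np.array([p for p, _ in table])
    ys = np.array([v for _, v in table])
    return float(np.interp(ph, xs, ys))


@dataclass(frozen=True)
class PHResponseCurve:
    """Piecewise-linear modulation of burster parameters as a function of pH.

    ``scales`` multiply and ``shifts`` add to the base value of each named
    parameter; both are anchored tables interpolated linearly in pH and are
    the identity (scale 1, shift 0) at the reference pH 7.8.
    ``state_schedule`` maps pH to the intended rhythm state; lookups snap to
    the nearest anchor (the protocol ladder values).
    """

    scales: dict[str, tuple[tuple[float, float], ...]] = field(default_factory=dict)
    shifts: dict[str, tuple[tuple[float, float], ...]] = field(default_factory=dict)
    state_schedule: tuple[tuple[float, str], ...] = ()
    ph_range: tuple[float, float] = (5.5, 10.4)
    reference_ph: float = 7.8

    def __post_init__(self) -> None:
        for name in list(self.scales) + list(self.shifts):
            if name not in _MODULATED:
                raise ValueError(f"unknown modulated parameter {name!r}")
        for name, table in self.scales.items():
            if abs(_interp(table, self.reference_ph, 1.0) - 1.0) > 1e-9:
                raise ValueError(f"scale table for {name!r} is not identity at "
                                 f"reference pH {self.reference_ph}")
        for name, table in self.shifts.items():
            if abs(_interp(table, self.reference_ph, 0.0)) > 1e-9:
                raise ValueError(f"shift table for {name!r} is not zero at "
                                 f"reference pH {self.reference_ph}")

    def _check(self, ph: float) -> None:
        lo, hi = self.ph_range
        if not lo - 1e-9 <= ph <= hi + 1e-9:
            raise ValueError(f"pH {ph} outside calibrated range [{lo}, {hi}]")

    def scale(self, name: str, ph: float) -> float:
        self._check(ph)
        return _interp(self.scales.get(name, ()), ph, 1.0)

    def shift(self, name: str, ph: float) -> float:
        self._check(ph)
        return _interp(self.shifts.get(name, ()), ph, 0.0)

    def state_at(self, ph: float) -> str | None:
        self._check(ph)
        if not self.state_schedule:
            return None
        anchors = np.array([p for p, _ in self.state_schedule])
        return self.state_schedule[int(np.argmin(np.abs(anchors - ph)))][1]


def apply_ph_response(base: BursterParams, curve: PHResponseCurve,
                      ph: float) -> BursterParams:
    """Modulate base parameters by the pH response curve.

    At the reference pH (7.8) the base is returned unchanged, field for
    field. Spike counts are rounded to integers; duty cycle is clipped to
    (0.01, 0.90).
    """
    kw: dict[str, float | int] = {}
    for name in _MODULATED:
        value = getattr(base, name) * curve.scale(name, ph) + curve.shift(name, ph)
        if name == "spikes_per_burst":
            value = max(0, int(round(value)))
        elif name == "duty_cycle":
            value = min(0.90, max(0.01, value))
        kw[name] = value
    return replace(base, **kw)


def default_pyloric_curve() -> PHResponseCurve:
    """Default STG modulation: trend directions of the pyloric rhythm.

    Burst frequency falls in base and is comparatively invariant in acid;
    spikes per burst and amplitudes collapse toward extreme acid; the state
    schedule degrades through weak/intermittent toward silence at pH 5.5
    (acid-sensitive) while staying rhythmic through moderate base.
    """
    return PHResponseCurve(
        scales={
            "burst_frequency": ((5.5, 0.80), (6.1, 0.95), (7.8, 1.0),
                                (8.8, 0.95), (9.3, 0.85), (9.8, 0.72), (10.4, 0.60)),
            "spikes_per_burst": ((5.5, 0.30), (6.1, 0.80), (7.8, 1.0),
                                 (9.8, 0.85), (10.4, 0.60)),
            "duty_cycle": ((5.5, 0.95), (6.1, 1.05), (7.8, 1.0), (10.4, 0.90)),
            "slow_amplitude": ((5.5, 0.40), (6.7, 1.0), (8.8, 1.0), (10.4, 0.60)),
            "spike_amplitude": ((5.5, 0.50), (6.1, 0.80), (7.8, 1.0), (10.4, 0.90)),
        },
        shifts={"v_min": ((5.5, 8.0), (6.1, 4.0), (7.8, 0.0), (10.4, -2.0))},
        state_schedule=(
            (5.5, "all_silent"), (6.1, "weak_triphasic"),
            (6.7, "normal_triphasic"), (7.2, "normal_triphasic"),
            (7.8, "normal_triphasic"), (8.3, "normal_triphasic"),
            (8.8, "normal_triphasic"), (9.3, "weak_triphasic"),
            (9.8, "intermittent_triphasic"), (10.4, "intermittent_triphasic"),
        ),
    )


def default_cardiac_curves() -> dict[str, PHResponseCurve]:
    """Default CG modulation per unit (SC pacemakers, LC motor neurons).

    Cardiac frequency declines at both extremes, LC spikes per burst rise in
    acid and fall in base, and the state schedule is base-sensitive:
    bursting persists into moderate acid but LC drop out and the rhythm
    silences toward pH 10.4.
    """
    schedule = (
        (5.5, "sc_only"), (6.1, "sc_lc_bursting"), (6.7, "sc_lc_bursting"),
        (7.2, "sc_lc_bursting"), (7.8, "sc_lc_bursting"), (8.3, "sc_lc_bursting"),
        (8.8, "sc_lc_bursting"), (9.3, "sc_only"), (9.8, "sc_only"),
        (10.4, "all_silent"),
    )
    freq = ((5.5, 0.80), (6.1, 0.90), (7.8, 1.0), (9.3, 0.90), (10.4, 0.70))
    sc = PHResponseCurve(
        scales={"burst_frequency": freq,
                "slow_amplitude": ((5.5, 0.70), (7.8, 1.0), (10.4, 0.50))},
        state_schedule=schedule,
    )
    lc = PHResponseCurve(
        scales={"burst_frequency": freq,
                "spikes_per_burst": ((5.5, 1.5), (6.1, 1.3), (7.8, 1.0),
                                     (9.8, 0.60), (10.4, 0.40)),
                "slow_amplitude": ((5.5, 0.80), (7.8, 1.0), (10.4, 0.50))},
        state_schedule=schedule,
    )
    return {"SC": sc, "LC": lc}


def default_stg_base_params() -> dict[str, BursterParams]:
    """Baseline triphasic parameters: PD leads; LP and PY fire anti-phase
    in the PD inter-burst interval."""
    return {
        "PD": BursterParams(burst_frequency=1.0, duty_cycle=0.30, spikes_per_burst=5,
                            v_min=-55.0, slow_amplitude=20.0, spike_amplitude=10.0,
                            phase_offset=0.0),
        "LP": BursterParams(burst_frequency=1.0, duty_cycle=0.18, spikes_per_burst=6,
                            v_min=-58.0, slow_amplitude=18.0, spike_amplitude=12.0,
                            phase_offset=0.45),
        "PY": BursterParams(burst_frequency=1.0, duty_cycle=0.22, spikes_per_burst=5,
                            v_min=-56.0, slow_amplitude=15.0, spike_amplitude=9.0,
                            phase_offset=0.70),
    }


def default_cg_base_params() -> dict[str, BursterParams]:
    """Baseline cardiac parameters: LC bursts ride within each SC burst."""
    return {
        "SC": BursterParams(burst_frequency=0.6, duty_cycle=0.25, spikes_per_burst=8,
                            v_min=-52.0, slow_amplitude=10.0, spike_amplitude=6.0,
                            phase_offset=0.0),
        "LC": BursterParams(burst_frequency=0.6, duty_cycle=0.20, spikes_per_burst=4,
                            v_min=-55.0, slow_amplitude=12.0, spike_amplitude=10.0,
                            phase_offset=0.02),
    }


def apply_state(params: BursterParams, state: str | None, unit: str,
                ganglion: str) -> BursterParams:
    """Adjust unit parameters so the generated activity realizes a state.

    Pyloric: ``weak_triphasic`` caps the LP spike count at 2 (some unit
    spiking only once or twice per cycle); ``intermittent_triphasic``
    silences LP while PD/PY keep cycling; ``all_silent`` removes spikes and
    slow waves from every unit. Cardiac: ``sc_only`` silences LC;
    ``all_silent`` silences both.
    """
    if state is None:
        return params
    if state == "all_silent":
        return replace(params, spikes_per_burst=0, slow_amplitude=0.0)
    if ganglion == "STG":
        if state == "normal_triphasic":
            return replace(params, spikes_per_burst=max(3, params.spikes_per_burst))
        if state == "weak_triphasic":
            if unit == "LP":
                return replace(params, spikes_per_burst=2)
            return replace(params, spikes_per_burst=max(3, params.spikes_per_burst))
        if state == "intermittent_triphasic":
            if unit == "LP":
                return replace(params, spikes_per_burst=0, slow_amplitude=0.0)
            return replace(params, spikes_per_burst=max(3, params.spikes_per_burst))
    else:
        if state == "sc_lc_bursting":
            if unit == "LC":
                return replace(params, spikes_per_burst=max(1, params.spikes_per_burst))
            return params
        if state == "sc_only":
            if unit == "LC":
                return replace(params, spikes_per_burst=0, slow_amplitude=0.0)
            return params
    return params


# ---------------------------------------------------------------------------
# Experiments

@dataclass(frozen=True)
class StepGroundTruth:
    step: PHStep
    t_start: float
    t_end: float
    state: str | None
    params: dict[str, BursterParams]


@dataclass
class Experiment:
    """A simulated preparation: spike trains spanning a full pH protocol,
    with per-step ground truth, plus deterministic on-demand trace rendering."""

    ganglion: str
    protocol: PHProtocol
    spike_trains: dict[str, SpikeTrain]
    ground_truth: list[StepGroundTruth]
    seed: int

    @property
    def units(self) -> tuple[str, ...]:
        return tuple(self.spike_trains)

    def render_trace(self, unit: str, start: float, stop: float,
                     sample_rate: float = 10_000.0) -> Trace:
        """Render the voltage trace of ``unit`` over ``[start, stop)``.

        The waveform is reconstructed from the per-step ground truth;
        noise is seeded from the experiment seed and the requested window,
        so identical calls are bit-identical.
        """
        if unit not in self.spike_trains:
            raise ValueError(f"unknown unit {unit!r}")
        if not 0 <= start < stop <= self.protocol.duration + 1e-9:
            raise ValueError("render window outside the protocol span")
        n = int(round((stop - start) * sample_rate))
        v = np.empty(n)
        t = start + np.arange(n) / sample_rate
        for gt in self.ground_truth:
            m = (t >= gt.t_start - 1e-12) & (t < gt.t_end - 1e-12)
            if not m.any():
                continue
            i0 = int(np.argmax(m))
            p = gt.params[unit]
            seg = _render(p, int(m.sum()), sample_rate,
                          t0=float(t[i0]) - gt.t_start, step_origin=0.0,
                          event_horizon=gt.t_end - gt.t_start)
            v[m] = seg
        noise_sd = self.ground_truth[0].params[unit].noise_sd
        if noise_sd > 0:
            uidx = list(self.spike_trains).index(unit)
            ss = np.random.SeedSequence(
                [self.seed, uidx, int(round(start * 1e6)), int(round(stop * 1e6))])
            v = v + np.random.default_rng(ss).normal(0.0, noise_sd, n)
        return Trace(v, sample_rate, start, unit)


def generate_experiment(ganglion: str, protocol: PHProtocol | None = None,
                        base_params: dict[str, BursterParams] | None = None,
                        curve: PHResponseCurve | dict[str, PHResponseCurve] | None = None,
                        seed: int = 0) -> Experiment:
    """Simulate one preparation over a stepped pH protocol.

    Per step, each unit's parameters are modulated by its pH response curve
    and adjusted to realize the scheduled rhythm state; spike times are laid
    down analytically (cycles restart at each step boundary). Ground truth
    (parameters and state) is recorded for every step.
    """
    if ganglion not in ("STG", "CG"):
        raise ValueError("ganglion must be 'STG' or 'CG'")
    units = STG_UNITS if ganglion == "STG" else CG_UNITS
    if protocol is None:
        protocol = build_protocol("acid_first", extreme=5.5)
    if base_params is None:
        base_params = default_stg_base_params() if ganglion == "STG" \
            else default_cg_base_params()
    if set(base_params) != set(units):
        raise ValueError(f"unit labels {sorted(base_params)} do not match "
                         f"{ganglion} units {sorted(units)}")
    if curve is None:
        curve = default_pyloric_curve() if ganglion == "STG" else default_cardiac_curves()
    curves = curve if isinstance(curve, dict) else {u: curve for u in units}
    if set(curves) != set(units):
        raise ValueError("per-unit curves must cover every unit")
    pacemaker = "PD" if ganglion == "STG" else "SC"

    ground_truth: list[StepGroundTruth] = []
    unit_times: dict[str, list[np.ndarray]] = {u: [] for u in units}
    for (t0, t1), step in zip(protocol.step_windows(), protocol.steps):
        state = curves[pacemaker].state_at(step.ph)
        step_params: dict[str, BursterParams] = {}
        for u in units:
            p = apply_ph_response(base_params[u], curves[u], step.ph)
            p = apply_state(p, state, u, ganglion)
            step_params[u] = p
            if p.spikes_per_burst > 0:
                times, _ = burst_event_times(p, duration=t1 - t0, t0=t0)
                unit_times[u].append(times)
        ground_truth.append(StepGroundTruth(step, t0, t1, state, step_params))

    trains = {
        u: SpikeTrain(np.concatenate(unit_times[u]) if unit_times[u] else np.empty(0), u)
        for u in units
    }
    return Experiment(ganglion, protocol, trains, ground_truth, seed)


def sample_population(ganglion: str, n_preparations: int,
                      cv: float = 0.15, seed: int = 0
                      ) -> list[dict[str, BursterParams]]:
    """Per-preparation baseline parameters with lognormal animal-to-animal
    spread.

    Frequency, amplitudes and duty cycle are jittered multiplicatively
    (lognormal with coefficient of variation ``cv``); the frequency
    multiplier is shared across a preparation's units so the network stays
    phase-consistent.
    """
    if n_preparations < 1:
        raise ValueError("need at least one preparation")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    base = default_stg_base_params() if ganglion == "STG" else default_cg_base_params()
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1 + cv ** 2))
    out = []
    for _ in range(n_preparations):
        f_mult = float(np.exp(rng.normal(-sigma ** 2 / 2, sigma)))
        prep = {}
        for u, p in base.items():
            a_mult = float(np.exp(rng.normal(-sigma ** 2 / 2, sigma)))
            d_mult = float(np.exp(rng.normal(-(sigma / 3) ** 2 / 2, sigma / 3)))
            prep[u] = replace(
                p,
                burst_frequency=p.burst_frequency * f_mult,
                slow_amplitude=p.slow_amplitude * a_mult,
                spike_amplitude=p.spike_amplitude * a_mult,
                duty_cycle=min(0.9, max(0.05, p.duty_cycle * d_mult)),
            )
        out.append(prep)
    return out


# ---------------------------------------------------------------------------
# Metric-level generators for statistical calibration and power studies

def generate_null_dataset(n_subjects: int, n_conditions: int,
                          effect: float | np.ndarray = 0.0,
                          noise_sd: float = 1.0, subject_sd: float = 1.0,
                          seed: int = 0) -> pd.DataFrame:
    """Subject-by-condition metric table with subject random intercepts.

    With ``effect = 0`` the true condition means are identical, which makes
    repeated tables a Monte-Carlo oracle for type-I-error calibration of
    the repeated-measures ANOVA. ``effect`` may also be a per-condition
    array of additive shifts.
    """
    if n_subjects < 3 or n_conditions < 2:
        raise ValueError("need n_subjects >= 3 and n_conditions >= 2")
    eff = np.broadcast_to(np.asarray(effect, dtype=float), (n_conditions,))
    rng = np.random.default_rng(seed)
    intercepts = rng.normal(0.0, subject_sd, n_subjects)
    rows = []
    for s in range(n_subjects):
        noise = rng.normal(0.0, noise_sd, n_conditions)
        for c in range(n_conditions):
            rows.append((f"prep{s:02d}", f"cond{c}", intercepts[s] + eff[c] + noise[c]))
    return pd.DataFrame(rows, columns=["preparation", "condition", "value"])


def simulate_rhythmicity_table(condition_means: dict[str, np.ndarray],
                               n_per_group: int = 15, noise_sd: float = 0.1,
                               subject_sd: float = 0.05, seed: int = 0,
                               clip: bool = True) -> pd.DataFrame:
    """Per-preparation time-rhythmic fractions for a two-ganglion comparison.

    ``condition_means`` maps each group label (e.g. ``"STG"``, ``"CG"``) to
    its true mean rhythmicity per pH condition; programming asymmetric
    degradation (one ganglion in acid, the other in base) yields a
    ganglion-by-pH interaction of known size for power studies.
    """
    rng = np.random.default_rng(seed)
    n_cond = {len(v) for v in condition_means.values()}
    if len(n_cond) != 1:
        raise ValueError("all groups need the same number of conditions")
    rows = []
    for g, means in condition_means.items():
        means = np.asarray(means, dtype=float)
        for s in range(n_per_group):
            b = rng.normal(0.0, subject_sd)
            vals = means + b + rng.normal(0.0, noise_sd, means.size)
            if clip:
                vals = np.clip(vals, 0.0, 1.0)
            for c, v in enumerate(vals):
                rows.append((f"{g}_prep{s:02d}", g, f"cond{c}", v))
    return pd.DataFrame(rows, columns=["preparation", "ganglion", "condition", "value"])


def generate_correlated_frequencies(n_preps: int = 15, rho: float = 0.8,
                                    baseline_mean: float = 1.0,
                                    baseline_sd: float = 0.2,
                                    extreme_mean: float = 0.6,
                                    extreme_sd: float = 0.15,
                                    seed: int = 0) -> pd.DataFrame:
    """Paired per-preparation baseline and extreme-pH frequencies.

    The pair is bivariate normal with Pearson correlation ``rho``,
    emulating preparations whose baseline speed predicts their speed under
    extreme acid or base.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.normal(size=n_preps)
    z2 = rng.normal(size=n_preps)
    base = baseline_mean + baseline_sd * z1
    extreme = extreme_mean + extreme_sd * (rho * z1 + math.sqrt(1 - rho ** 2) * z2)
    return pd.DataFrame({
        "preparation": [f"prep{i:02d}" for i in range(n_preps)],
        "baseline": base,
        "extreme": extreme,
    })
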