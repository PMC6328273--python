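"""pH step protocols and temperature-compensated electrode calibration.

A protocol is an ordered list of 15-min bath steps: control pH 7.8, graded
steps of ~0.5 pH toward an acid or base extreme, then a recovery period of
at least 30 min back at control. Condition labels use the pH values of the
saline ladder measured at the 11 degC bath temperature.

The pH electrode is modelled as Nernstian: output voltage is linear in pH
with a slope proportional to absolute temperature
(``2.303 * R * T / F`` = 59.16 mV per pH unit at 25 degC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PH_LADDER_11C",
    "CONTROL_PH",
    "PHStep",
    "PHProtocol",
    "build_protocol",
    "nernst_slope_mv",
    "CalibrationModel",
    "calibrate_electrode",
    "voltage_to_ph",
    "ph_to_voltage",
]

#: Saline ladder as measured at the 11 degC bath temperature.
PH_LADDER_11C = (5.5, 6.1, 6.7, 7.2, 7.8, 8.3, 8.8, 9.3, 9.8, 10.4)
CONTROL_PH = 7.8

_R = 8.314462618  # J / (mol K)
_F = 96485.33212  # C / mol
_LN10 = np.log(10.0)


@dataclass(frozen=True)
class PHStep:
    """One bath condition: nominal pH (at bath temperature), duration, role."""

    ph: float
    duration: float = 900.0
    role: str = "step"  # control | step | recovery

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("step duration must be positive")
        if not 5.0 <= self.ph <= 11.0:
            raise ValueError(f"pH {self.ph} outside protocol range [5.0, 11.0]")
        if self.role not in ("control", "step", "recovery"):
            raise ValueError(f"unknown step role {self.role!r}")


@dataclass(frozen=True)
class PHProtocol:
    """Ordered, contiguous pH steps with a direction and bath temperature."""

    steps: tuple[PHStep, ...]
    direction: str = "acid_first"
    temperature: float = 11.0

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("protocol has no steps")
        if self.direction not in ("acid_first", "base_first"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.steps[0].role != "control":
            raise ValueError("protocol must begin at the control pH")

    @property
    def duration(self) -> float:
        return float(sum(s.duration for s in self.steps))

    def step_windows(self) -> list[tuple[float, float]]:
        """Half-open ``[start, end)`` window of each step."""
        edges = np.concatenate([[0.0], np.cumsum([s.duration for s in self.steps])])
        return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]

    def analysis_windows(self, window_s: float = 480.0) -> list[tuple[float, float]]:
        """The last ``window_s`` seconds of each step, ``[end - w, end)``."""
        out = []
        for (t0, t1) in self.step_windows():
            if t1 - t0 < window_s:
                raise ValueError(f"step shorter than the {window_s} s analysis window")
            out.append((t1 - window_s, t1))
        return out


def build_protocol(direction: str = "acid_first", extreme: float = 5.5,
                   control: float = CONTROL_PH,
                   ladder: tuple[float, ...] = PH_LADDER_11C,
                   step_duration: float = 900.0,
                   recovery_duration: float = 1800.0,
                   temperature: float = 11.0) -> PHProtocol:
    """Build a stepped protocol: control -> graded steps to the extreme ->
    recovery at control.

    The graded steps are the ladder values strictly between the control and
    the extreme, ordered toward the extreme; recovery lasts at least 30 min.
    """
    if direction not in ("acid_first", "base_first"):
        raise ValueError(f"unknown direction {direction!r}")
    if direction == "acid_first" and not extreme < control:
        raise ValueError("acid-first protocol needs extreme below control pH")
    if direction == "base_first" and not extreme > control:
        raise ValueError("base-first protocol needs extreme above control pH")
    if recovery_duration < 1800.0:
        raise ValueError("recovery must last at least 30 min")
    vals = sorted([p for p in ladder if min(control, extreme) <= p <= max(control, extreme)],
                  reverse=(direction == "acid_first"))
    if not vals or abs(vals[0] - control) > 1e-9 or abs(vals[-1] - extreme) > 1e-9:
        raise ValueError("ladder must contain both the control and the extreme pH")
    steps = [PHStep(control, step_duration, "control")]
    steps += [PHStep(p, step_duration, "step") for p in vals[1:]]
    steps += [PHStep(control, recovery_duration, "recovery")]
    return PHProtocol(tuple(steps), direction, temperature)


# ---------------------------------------------------------------------------
# Electrode calibration

def nernst_slope_mv(temperature_c: float) -> float:
    """Ideal Nernstian electrode slope, mV per pH unit, at ``temperature_c``."""
    return 1000.0 * _LN10 * _R * (temperature_c + 273.15) / _F


@dataclass
class CalibrationModel:
    """Fitted electrode model ``V = offset + efficiency * k(T) * pH`` with
    ``k(T)`` the ideal Nernst slope at absolute temperature ``T``.

    ``efficiency`` is dimensionless (-1 for an ideal electrode in the
    voltage-falls-with-pH convention); the realized slope at temperature T
    is ``efficiency * k(T)``.
    """

    offset_mv: float = 0.0
    efficiency: float = 0.0
    fitted: bool = False

    def slope_mv_per_ph(self, temperature_c: float) -> float:
        self._require_fitted()
        return self.efficiency * nernst_slope_mv(temperature_c)

    def _require_fitted(self) -> None:
        if not self.fitted:
            raise RuntimeError("calibration model is not fitted")


def calibrate_electrode(points) -> CalibrationModel:
    """Fit offset and temperature-scaled slope from calibration points.

    ``points`` is an iterable of ``(buffer_ph, voltage_mv, temperature_c)``
    triples; at least two with distinct buffer pH values are required. With
    more than two points the fit is least squares.
    """
    pts = [(float(p), float(v), float(t)) for p, v, t in points]
    if len(pts) < 2:
        raise ValueError("need at least two calibration points")
    ph = np.array([p for p, _, _ in pts])
    v = np.array([x for _, x, _ in pts])
    temp = np.array([t for _, _, t in pts])
    if np.ptp(ph) < 1e-12:
        raise ValueError("degenerate calibration: identical buffer pH values")
    if np.any(temp < -273.15):
        raise ValueError("temperature below absolute zero")
    x = np.array([nernst_slope_mv(t) for t in temp]) * ph
    design = np.column_stack([np.ones_like(x), x])
    (offset, eff), *_ = np.linalg.lstsq(design, v, rcond=None)
    return CalibrationModel(float(offset), float(eff), fitted=True)


def voltage_to_ph(model: CalibrationModel, voltage_mv, temperature_c: float):
    """Invert the calibrated Nernstian relation at the stated temperature."""
    model._require_fitted()
    if not 0.0 <= temperature_c <= 40.0:
        raise ValueError("temperature outside the supported 0-40 degC range")
    if model.efficiency == 0.0:
        raise ValueError("zero electrode slope: cannot invert")
    return (np.asarray(voltage_mv, dtype=float) - model.offset_mv) / (
        model.efficiency * nernst_slope_mv(temperature_c))


def ph_to_voltage(model: CalibrationModel, ph, temperature_c: float):
    """Forward calibrated relation: expected electrode output for a pH."""
    model._require_fitted()
    return model.offset_mv + model.efficiency * nernst_slope_mv(temperature_c) * \
        np.asarray(ph, dtype=float)
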