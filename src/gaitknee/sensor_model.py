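"""Physical and calibration model of the textile capacitive pressure sensor.

A parallel-plate fabric sensor changes capacitance when loaded: C = eps_r *
eps_0 * A / d.  Bench calibration of the sensor gives a piecewise-linear
relative-capacitance-change curve, linear below a breakpoint pressure and
flatter (saturating) above it.  This module holds the plate-capacitor
arithmetic, the force/area pressure conversion, and the forward/inverse
calibration map used to turn measured capacitance counts into kPa.

Units: areas in m^2, thicknesses in m, forces in N, pressures in kPa,
capacitances in F (pF only where a field name says so).  Sensitivities are
relative capacitance change per MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Vacuum permittivity, F/m.
EPSILON_0 = 8.854e-12

#: Relative permittivity assumed for the nonwoven fabric dielectric.  The
#: value only sets the zero-load base capacitance, which cancels out of the
#: relative-change calibration, so downstream results are insensitive to it.
DEFAULT_DIELECTRIC_EPS_R = 1.2


class InvalidSensorSpecError(ValueError):
    """Raised for non-physical sensor geometry."""


@dataclass(frozen=True)
class SensorSpec:
    """Geometry and material of one parallel-plate capacitive sensor."""

    electrode_area: float  # m^2
    dielectric_thickness: float  # m
    relative_permittivity: float = DEFAULT_DIELECTRIC_EPS_R
    vacuum_permittivity: float = EPSILON_0

    def __post_init__(self) -> None:
        for name in ("electrode_area", "dielectric_thickness",
                     "relative_permittivity", "vacuum_permittivity"):
            if not getattr(self, name) > 0:
                raise InvalidSensorSpecError(
                    f"{name} must be strictly positive, got {getattr(self, name)!r}")


#: The 1 cm x 1 cm insole sensor with a 1 mm nonwoven dielectric.
DEFAULT_INSOLE_SENSOR = SensorSpec(electrode_area=1.0e-4,
                                   dielectric_thickness=1.0e-3)


def parallel_plate_capacitance(spec: SensorSpec) -> float:
    """Capacitance (F) of the plate capacitor: eps_r * eps_0 * A / d."""
    return (spec.relative_permittivity * spec.vacuum_permittivity
            * spec.electrode_area / spec.dielectric_thickness)


@dataclass(frozen=True)
class LoadCase:
    """A force applied over a contact area (e.g. body weight on an insole)."""

    force: float  # N
    stress_area: float  # m^2

    def __post_init__(self) -> None:
        if self.force < 0:
            raise ValueError(f"force must be >= 0, got {self.force!r}")
        if not self.stress_area > 0:
            raise ValueError(
                f"stress_area must be strictly positive, got {self.stress_area!r}")


def pressure_from_force(case: LoadCase) -> float:
    """Uniform pressure P = F / S, returned in kPa."""
    return case.force / case.stress_area / 1000.0


def _default_base_capacitance_pF() -> float:
    return parallel_plate_capacitance(DEFAULT_INSOLE_SENSOR) * 1e12


@dataclass(frozen=True)
class CalibrationCurve:
    """Piecewise-linear pressure -> relative capacitance change map.

    The ordinate is dC/C0 (dimensionless); the slope is ``low_sensitivity``
    (per MPa) up to ``breakpoint_pressure`` (kPa) and ``high_sensitivity``
    above it.  Continuity at the breakpoint and strictly positive slopes make
    the map strictly increasing, hence invertible.
    """

    base_capacitance: float = field(default_factory=_default_base_capacitance_pF)  # pF
    breakpoint_pressure: float = 11.0  # kPa
    low_sensitivity: float = 0.232  # 1/MPa
    high_sensitivity: float = 0.070  # 1/MPa

    def __post_init__(self) -> None:
        if not (self.low_sensitivity > 0 and self.high_sensitivity > 0):
            raise ValueError("sensitivities must be strictly positive")
        if self.low_sensitivity < self.high_sensitivity:
            raise ValueError(
                "saturating curve requires low_sensitivity >= high_sensitivity")
        if not (self.breakpoint_pressure > 0 and self.base_capacitance > 0):
            raise ValueError("breakpoint and base capacitance must be positive")

    def to_dict(self) -> dict:
        return {
            "base_capacitance_pF": self.base_capacitance,
            "breakpoint_kPa": self.breakpoint_pressure,
            "low_sensitivity_per_MPa": self.low_sensitivity,
            "high_sensitivity_per_MPa": self.high_sensitivity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(base_capacitance=d["base_capacitance_pF"],
                   breakpoint_pressure=d["breakpoint_kPa"],
                   low_sensitivity=d["low_sensitivity_per_MPa"],
                   high_sensitivity=d["high_sensitivity_per_MPa"])


def relative_capacitance_change(pressure, curve: CalibrationCurve | None = None):
    """Forward calibration: pressure (kPa) -> dC/C0 (dimensionless).

    Accepts scalars or arrays; negative pressures are a domain error.
    """
    if curve is None:
        curve = CalibrationCurve()
    p = np.asarray(pressure, dtype=float)
    if np.any(p < 0):
        raise ValueError("pressure must be >= 0 kPa")
    bp = curve.breakpoint_pressure
    # sensitivities are per MPa, pressures in kPa
    low = curve.low_sensitivity * p / 1000.0
    high = (curve.low_sensitivity * bp / 1000.0
            + curve.high_sensitivity * (p - bp) / 1000.0)
    out = np.where(p <= bp, low, high)
    return float(out) if np.isscalar(pressure) else out


def pressure_from_capacitance(fraction, curve: CalibrationCurve | None = None):
    """Inverse calibration: dC/C0 -> pressure (kPa).

    Exact inverse of :func:`relative_capacitance_change` on its range.
    """
    if curve is None:
        curve = CalibrationCurve()
    f = np.asarray(fraction, dtype=float)
    if np.any(f < 0):
        raise ValueError("capacitance-change fraction must be >= 0")
    f_break = curve.low_sensitivity * curve.breakpoint_pressure / 1000.0
    low = f * 1000.0 / curve.low_sensitivity
    high = (curve.breakpoint_pressure
            + (f - f_break) * 1000.0 / curve.high_sensitivity)
    out = np.where(f <= f_break, low, high)
    return float(out) if np.isscalar(fraction) else out
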