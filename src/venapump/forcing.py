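"""Time-dependent boundary forcings.

Two periodic drivers act on the circuit:

* the cardiac pump — a sinusoidal inlet pressure
  ``p(t) = mean + amplitude * sin(2*pi*t/T)``;
* the calf muscle pump — a prescribed radial wall velocity on the deformable
  venous trunk, separable into an axial half-sine and a temporal sinusoid:

  ``v_r(z, t) = a * pi * sin(pi (z - z0)/L) * (1/T0) * sin(2*pi*t/T0)``

  for ``z0 <= z <= z0 + L`` and zero elsewhere. ``a`` is the peak radial wall
  displacement reached at the segment midpoint at the end of the contraction
  half-cycle; positive ``v_r`` means the wall moves inward (compression).

The first half-cycle ``[0, T0/2)`` is the muscle contraction (systole), the
second half the relaxation (diastole). Over one full period the wall returns
exactly to its resting shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuit import CALF_LENGTH_CM, CALF_Z0_CM, InletLaw
from .errors import InvalidParameterError

#: canonical peak radial wall displacement (cm): 50 um, chosen so that the
#: swept volume per muscle systole is 4*R*a*L = 0.15 mL, which together with
#: the ~0.05 mL resting arterial throughput yields the healthy walking output.
CANONICAL_DISPLACEMENT_CM = 5e-3


@dataclass(frozen=True)
class WallMotionLaw:
    """Prescribed radial-velocity forcing of the calf trunk."""

    displacement_amplitude_cm: float = CANONICAL_DISPLACEMENT_CM
    z0_cm: float = CALF_Z0_CM
    length_cm: float = CALF_LENGTH_CM
    period_s: float = 1.0

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.period_s <= 0:
            raise InvalidParameterError("wall motion needs positive length and period")
        if self.displacement_amplitude_cm < 0:
            raise InvalidParameterError("displacement amplitude must be >= 0")


@dataclass(frozen=True)
class ForcingSchedule:
    """Complete forcing: inlet law plus optional wall motion."""

    inlet: InletLaw
    wall_motion: WallMotionLaw | None = None

    def __post_init__(self) -> None:
        if self.wall_motion is not None and not math.isclose(
            self.wall_motion.period_s, self.inlet.period_s
        ):
            raise InvalidParameterError(
                "wall-motion period must equal the reporting cycle length"
            )

    @property
    def cycle_period_s(self) -> float:
        """Reporting cycle: wall-motion period if active, else cardiac period."""
        if self.wall_motion is not None:
            return self.wall_motion.period_s
        return self.inlet.period_s


def inlet_pressure(t_s: float, law: InletLaw) -> float:
    """Inlet pressure (mmHg) at time ``t_s``."""
    if t_s < 0:
        raise InvalidParameterError("time must be >= 0")
    return law.mean_mmhg + law.amplitude_mmhg * math.sin(2 * math.pi * t_s / law.period_s)


def wall_radial_velocity(z_cm, t_s: float, law: WallMotionLaw):
    """Radial wall velocity (cm/s, positive inward) at height ``z`` and time ``t``.

    Vectorized over ``z_cm``.
    """
    if t_s < 0:
        raise InvalidParameterError("time must be >= 0")
    z = np.asarray(z_cm, dtype=float)
    zeta = (z - law.z0_cm) / law.length_cm
    inside = (zeta >= 0.0) & (zeta <= 1.0)
    v_z = law.displacement_amplitude_cm * math.pi * np.sin(math.pi * np.clip(zeta, 0.0, 1.0))
    v_t = math.sin(2 * math.pi * t_s / law.period_s) / law.period_s
    out = np.where(inside, v_z * v_t, 0.0)
    return out if out.ndim else float(out)


def wall_displacement(z_cm, t_s: float, law: WallMotionLaw):
    """Inward radial wall displacement (cm): time integral of the velocity law."""
    z = np.asarray(z_cm, dtype=float)
    zeta = (z - law.z0_cm) / law.length_cm
    inside = (zeta >= 0.0) & (zeta <= 1.0)
    shape = law.displacement_amplitude_cm / 2.0 * np.sin(math.pi * np.clip(zeta, 0.0, 1.0))
    temporal = 1.0 - math.cos(2 * math.pi * t_s / law.period_s)
    out = np.where(inside, shape * temporal, 0.0)
    return out if out.ndim else float(out)


def swept_rate_ml_s(t_s: float, law: WallMotionLaw, radius_cm: float) -> float:
    """Volume displacement rate of the whole trunk (mL/s, positive = expelling).

    Thin-wall surface integral of ``v_r`` over the trunk:
    ``2*pi*R * integral(V_z dz) * V_t = 4*pi*R*a*L * sin(2*pi*t/T0)/T0``.
    """
    v_t = math.sin(2 * math.pi * t_s / law.period_s) / law.period_s
    return 4.0 * math.pi * radius_cm * law.displacement_amplitude_cm * law.length_cm * v_t


def swept_volume_half_cycle(law: WallMotionLaw, radius_cm: float) -> float:
    """Closed-form volume swept during one muscle systole: ``4*R*a*L`` (mL)."""
    if radius_cm <= 0:
        raise InvalidParameterError("radius must be > 0")
    return 4.0 * radius_cm * law.displacement_amplitude_cm * law.length_cm
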