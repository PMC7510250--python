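"""Ball check valves bracketing the calf trunk.

Each venous valve is idealized as a caged ball slightly larger than the
vessel lumen. Forward (heart-ward) pressure lifts the ball off its seat into
the cage, opening the full lumen; reverse pressure drives it back onto the
seat. The ball never touches the seat: a residual clearance ``min_gap``
remains at the closed stop — 0.016 cm for a competent valve, about 0.2 cm for
a severely incompetent one — so a seated valve always leaks a little.

Hydraulic closure of a valve edge
---------------------------------
The pressure drop across the valve combines

* a quadratic orifice loss ``(rho/2) (Q/A_eff)^2 sign(Q)`` on the
  position-dependent effective area,
* a seat-film viscous resistance, dominant when the ball is seated: the
  closed-stop leak resistance follows creeping-orifice (Sampson) scaling on
  the residual leak area, ``R_seat = R_REF * (A_ref/A_leak)^{3/2}``, and
  decays as ``(A_leak/A_eff)^3`` once the ball lifts, so an open valve is
  hydraulically transparent. The reference resistance is anchored at the
  competent 0.016 cm gap (1% leak area) and calibrated once against the
  dysfunction grading of the canonical scenarios (see docs/methods.md),
* the (negligible) Poiseuille term of the seat lumen over the ball length.

The residual leak *area* at the closed stop scales linearly with the gap,
anchored at 1% of the full opening for the competent 0.016 cm gap and capped
at 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from . import units
from .circuit import BLOOD, FluidProperties, poiseuille_resistance
from .errors import InvalidParameterError, StateViolationError

#: competent-valve seat clearance (cm) — the leak-area and leak-resistance anchor
GAP_REF_CM = 0.016
HEALTHY_GAP_CM = 0.016
SEVERE_GAP_CM = 0.2

#: residual leak area at the competent closed stop, fraction of full opening
RESIDUAL_AREA_FRACTION_REF = 0.01

#: seat-film viscous resistance at the competent closed stop (mmHg.s/mL);
#: single calibrated closure constant of the leak law (see docs/methods.md)
SEAT_LEAK_RESISTANCE_REF_MMHG_S_ML = 1.3e5

#: Sampson (creeping orifice) scaling of the closed-stop leak resistance
#: with leak area, R ~ A^{-3/2}
SEAT_LEAK_AREA_EXPONENT = 1.5

#: exponent of the lift-off decay of the seat-film resistance
SEAT_LEAK_DECAY_EXPONENT = 3.0


def residual_area_fraction_for_gap(min_gap_cm: float) -> float:
    """Linear gap -> leak-area mapping, anchored at the competent stop, capped at 1."""
    if min_gap_cm <= 0:
        raise InvalidParameterError("min_gap must be > 0")
    return min(1.0, RESIDUAL_AREA_FRACTION_REF * min_gap_cm / GAP_REF_CM)


@dataclass(frozen=True)
class BallValveSpec:
    """Geometry and dynamic parameters of one ball check valve."""

    ball_diameter_cm: float = 0.52
    seat_diameter_cm: float = 0.50
    travel_max_cm: float = 0.5
    min_gap_cm: float = HEALTHY_GAP_CM
    fully_open_area_cm2: float | None = None  # default: seat lumen area
    residual_area_fraction: float | None = None  # default: gap mapping
    ball_density_kg_m3: float | None = None  # default: neutrally buoyant
    relaxation_time_s: float = 5e-3
    dynamics: str = "relaxation"  # "relaxation" | "inertial"
    seat_leak_resistance_ref_mmhg_s_ml: float = SEAT_LEAK_RESISTANCE_REF_MMHG_S_ML

    def __post_init__(self) -> None:
        if self.ball_diameter_cm <= self.seat_diameter_cm:
            raise InvalidParameterError("ball must be larger than the seat lumen")
        if not (0 < self.min_gap_cm < self.travel_max_cm):
            raise InvalidParameterError("need 0 < min_gap < travel_max")
        frac = self.leak_area_fraction
        if not (0 < frac <= 1):
            raise InvalidParameterError("residual area fraction must be in (0, 1]")
        if self.relaxation_time_s <= 0:
            raise InvalidParameterError("relaxation time must be > 0")
        if self.dynamics not in ("relaxation", "inertial"):
            raise InvalidParameterError(f"unknown ball dynamics {self.dynamics!r}")

    @property
    def seat_area_cm2(self) -> float:
        return math.pi * (self.seat_diameter_cm / 2.0) ** 2

    @property
    def open_area_cm2(self) -> float:
        return self.fully_open_area_cm2 if self.fully_open_area_cm2 is not None else self.seat_area_cm2

    @property
    def leak_area_fraction(self) -> float:
        if self.residual_area_fraction is not None:
            return self.residual_area_fraction
        return residual_area_fraction_for_gap(self.min_gap_cm)

    @property
    def leak_area_cm2(self) -> float:
        return self.leak_area_fraction * self.open_area_cm2

    @property
    def ball_density(self) -> float | None:
        return self.ball_density_kg_m3

    @property
    def ball_volume_m3(self) -> float:
        r = units.cm_to_m(self.ball_diameter_cm / 2.0)
        return 4.0 / 3.0 * math.pi * r**3

    @property
    def ball_cross_section_m2(self) -> float:
        r = units.cm_to_m(self.ball_diameter_cm / 2.0)
        return math.pi * r**2


@dataclass(frozen=True)
class BallValveState:
    """Instantaneous ball state. ``position = 0`` is the seated (closed) stop."""

    position_cm: float
    velocity_cm_s: float
    effective_area_cm2: float
    orientation: str  # "distal" | "proximal"

    def __post_init__(self) -> None:
        if self.orientation not in ("distal", "proximal"):
            raise InvalidParameterError(f"unknown orientation {self.orientation!r}")


def initial_state(spec: BallValveSpec, orientation: str, open_: bool = True) -> BallValveState:
    pos = spec.travel_max_cm if open_ else 0.0
    return BallValveState(pos, 0.0, effective_orifice_area(pos, spec), orientation)


def effective_orifice_area(position_cm: float, spec: BallValveSpec) -> float:
    """Flow area (cm^2) presented by the valve at the given ball position.

    Linear interpolation between the residual leak area at the closed stop
    and the full opening at ``travel_max``.
    """
    if not (-1e-12 <= position_cm <= spec.travel_max_cm + 1e-12):
        raise StateViolationError(
            f"ball position {position_cm} outside [0, {spec.travel_max_cm}]"
        )
    s = min(1.0, max(0.0, position_cm / spec.travel_max_cm))
    a_leak = spec.leak_area_cm2
    return a_leak + (spec.open_area_cm2 - a_leak) * s


def seat_viscous_resistance(position_cm: float, spec: BallValveSpec) -> float:
    """Seat-film viscous resistance (mmHg.s/mL) at the given ball position."""
    a_eff = effective_orifice_area(position_cm, spec)
    a_ref = RESIDUAL_AREA_FRACTION_REF * spec.open_area_cm2
    r_closed = spec.seat_leak_resistance_ref_mmhg_s_ml * \
        (a_ref / spec.leak_area_cm2) ** SEAT_LEAK_AREA_EXPONENT
    return r_closed * (spec.leak_area_cm2 / a_eff) ** SEAT_LEAK_DECAY_EXPONENT


def valve_edge_resistance_si(position_cm: float, spec: BallValveSpec,
                             fluid: FluidProperties = BLOOD) -> float:
    """Linear-in-flow part of the valve pressure drop, Pa.s/m^3."""
    r_seat = units.resistance_clinical_to_si(seat_viscous_resistance(position_cm, spec))
    r_pois = units.resistance_clinical_to_si(
        poiseuille_resistance(spec.ball_diameter_cm, spec.seat_diameter_cm, fluid)
    )
    return r_seat + r_pois


def valve_quadratic_coeff_si(position_cm: float, spec: BallValveSpec,
                             fluid: FluidProperties = BLOOD) -> float:
    """Orifice-loss coefficient K (Pa.s^2/m^6): dp = K * Q * |Q|."""
    a_eff_m2 = effective_orifice_area(position_cm, spec) * units.CM_M**2
    return fluid.density / (2.0 * a_eff_m2**2)


def ball_force_balance(state: BallValveState, spec: BallValveSpec,
                       upstream_p_mmhg: float, downstream_p_mmhg: float,
                       local_flow_ml_s: float,
                       fluid: FluidProperties = BLOOD,
                       gravity_m_s2: float = 0.0) -> float:
    """Net axial force on the ball (N), positive toward opening.

    Pressure force on the ball cross-section (forward pressure difference
    opens), Stokes drag from the relative fluid velocity, and net weight of a
    non-neutrally-buoyant ball projected on the (vertical, opening-up) travel
    axis. Pressures are the dynamic (hydrostatic-free) values, so a neutrally
    buoyant ball in stagnant fluid feels no force regardless of gravity.
    """
    dp_pa = units.mmhg_to_pa(upstream_p_mmhg - downstream_p_mmhg)
    f_pressure = dp_pa * spec.ball_cross_section_m2
    seat_area_m2 = spec.seat_area_cm2 * units.CM_M**2
    v_fluid = units.ml_to_m3(local_flow_ml_s) / seat_area_m2
    v_ball = units.cm_to_m(state.velocity_cm_s)
    f_drag = 3.0 * math.pi * fluid.viscosity * units.cm_to_m(spec.ball_diameter_cm) * (v_fluid - v_ball)
    rho_ball = spec.ball_density_kg_m3 if spec.ball_density_kg_m3 is not None else fluid.density
    f_weight = -(rho_ball - fluid.density) * spec.ball_volume_m3 * gravity_m_s2
    return f_pressure + f_drag + f_weight


def advance_ball(state: BallValveState, force_n: float, dt_s: float,
                 spec: BallValveSpec) -> BallValveState:
    """Advance the ball one time step with hard stops.

    Default dynamics is first-order relaxation toward the stop selected by
    the force sign, with time constant ``relaxation_time_s`` (the ball's
    response time); the optional inertial mode integrates Newton's law for
    the ball mass instead.
    """
    if dt_s <= 0:
        raise InvalidParameterError("dt must be > 0")
    x = state.position_cm
    if spec.dynamics == "relaxation":
        if force_n > 0:
            x_eq = spec.travel_max_cm
        elif force_n < 0:
            x_eq = 0.0
        else:
            x_eq = x
        decay = math.exp(-dt_s / spec.relaxation_time_s)
        x_new = x_eq + (x - x_eq) * decay
        v_new = (x_new - x) / dt_s
    else:  # inertial
        rho_ball = spec.ball_density_kg_m3 if spec.ball_density_kg_m3 is not None else BLOOD.density
        mass = rho_ball * spec.ball_volume_m3
        v_si = units.cm_to_m(state.velocity_cm_s) + force_n / mass * dt_s
        v_new = units.m_to_cm(v_si)
        x_new = x + v_new * dt_s
    if x_new <= 0.0:
        x_new, v_new = 0.0, 0.0
    elif x_new >= spec.travel_max_cm:
        x_new, v_new = spec.travel_max_cm, 0.0
    return BallValveState(x_new, v_new, effective_orifice_area(x_new, spec), state.orientation)


def configure_incompetence(valve_pair: tuple[BallValveSpec, BallValveSpec],
                           grade: str) -> tuple[BallValveSpec, BallValveSpec]:
    """Set the (distal, proximal) closed-stop gaps for a dysfunction grade.

    healthy: both competent (0.016 cm); severe: both restricted (~0.2 cm);
    partial: distal restricted, proximal competent.
    """
    distal, proximal = valve_pair
    gaps = {
        "healthy": (HEALTHY_GAP_CM, HEALTHY_GAP_CM),
        "severe": (SEVERE_GAP_CM, SEVERE_GAP_CM),
        "partial": (SEVERE_GAP_CM, HEALTHY_GAP_CM),
    }
    if grade not in gaps:
        raise InvalidParameterError(f"unknown incompetence grade {grade!r}")
    g_d, g_p = gaps[grade]
    return (replace(distal, min_gap_cm=g_d, residual_area_fraction=None),
            replace(proximal, min_gap_cm=g_p, residual_area_fraction=None))
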