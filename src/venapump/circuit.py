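"""Idealized systemic circuit for the lower-limb venous pump.

The circulation between heart and foot is reduced to a U-shaped single-vessel
loop: a narrow arterial arm descending 130 cm from the heart, a porous baffle
standing in for the arteriolar/capillary resistance at foot level, and a wide
venous arm ascending back to the heart. A 30 cm stretch of the venous arm (the
"calf trunk", a stand-in for the posterior tibial vein) has prescribed wall
motion and is bracketed by two ball check valves.

Diameters are sized from the continuity equation ``A v = const`` so that each
vessel class carries its typical blood velocity; they are functional values,
not anatomical ones. Hydraulic resistances of the canonical circuit are
calibrated against the resting pressure budget (aorta 100, artery-at-feet 95,
vein-at-feet 15, vena cava 0 mmHg) at the reference venous flow, because the
sub-millimetre functional diameters would otherwise give laminar drops far in
excess of the available 100 mmHg head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from . import units
from .errors import CalibrationError, InvalidParameterError

#: standard gravity used throughout (m/s^2)
GRAVITY_M_S2 = 9.81

#: resting ("clinostatic") pressure budget used to size the circuit, mmHg
CLINOSTATIC_PRESSURES_MMHG = {"aorta": 100.0, "artery": 95.0, "vein": 15.0}

#: typical velocities per vessel class used for continuity sizing, cm/s
REFERENCE_VELOCITIES_CM_S = {"aorta": 35.0, "artery": 9.8, "vein": 0.25}

#: calf trunk geometry (cm)
CALF_RADIUS_CM = 0.25
CALF_LENGTH_CM = 30.0
CALF_Z0_CM = 10.0

#: heart-to-foot arm length (cm)
ARM_LENGTH_CM = 130.0


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise InvalidParameterError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood: density (kg/m^3) and dynamic viscosity (Pa.s)."""

    density: float = 1060.0
    viscosity: float = 0.0035

    def __post_init__(self) -> None:
        _require_positive(density=self.density, viscosity=self.viscosity)


BLOOD = FluidProperties()


@dataclass(frozen=True)
class VesselSegment:
    """One straight stretch of the loop.

    ``elevation_drop_cm`` is signed along the flow direction, positive when
    the flow descends.  ``resistance_mmhg_s_ml`` overrides the Poiseuille
    closure with a calibrated total hydraulic resistance for the segment; when
    ``None`` the laminar (Poiseuille) value for the printed diameter is used.
    """

    name: str
    length_cm: float
    diameter_cm: float
    elevation_drop_cm: float = 0.0
    wall: str = "rigid"  # "rigid" | "prescribed-motion"
    role: str = "vein"  # "aorta" | "artery" | "vein" | "calf"
    resistance_mmhg_s_ml: float | None = None

    def __post_init__(self) -> None:
        _require_positive(length_cm=self.length_cm, diameter_cm=self.diameter_cm)
        if abs(self.elevation_drop_cm) > self.length_cm * (1 + 1e-12):
            raise InvalidParameterError(
                f"segment {self.name}: |elevation_drop| ({self.elevation_drop_cm}) "
                f"exceeds length ({self.length_cm})"
            )
        if self.wall not in ("rigid", "prescribed-motion"):
            raise InvalidParameterError(f"unknown wall type {self.wall!r}")
        if self.role not in ("aorta", "artery", "vein", "calf"):
            raise InvalidParameterError(f"unknown segment role {self.role!r}")
        if self.resistance_mmhg_s_ml is not None and self.resistance_mmhg_s_ml < 0:
            raise InvalidParameterError("resistance override must be >= 0")

    @property
    def area_cm2(self) -> float:
        return math.pi * (self.diameter_cm / 2.0) ** 2

    def hydraulic_resistance_mmhg_s_ml(self, fluid: FluidProperties) -> float:
        """Total segment resistance: calibrated override or Poiseuille."""
        if self.resistance_mmhg_s_ml is not None:
            return self.resistance_mmhg_s_ml
        return poiseuille_resistance(self.length_cm, self.diameter_cm, fluid)


@dataclass(frozen=True)
class PorousInterface:
    """Linear (Darcy) lumped resistance standing in for the capillary bed."""

    resistance_mmhg_s_ml: float

    def __post_init__(self) -> None:
        _require_positive(resistance_mmhg_s_ml=self.resistance_mmhg_s_ml)


@dataclass(frozen=True)
class InletLaw:
    """Sinusoidal aortic pressure: mean + amplitude*sin(2*pi*t/period), mmHg."""

    mean_mmhg: float = 100.0
    amplitude_mmhg: float = 20.0
    period_s: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(period_s=self.period_s)
        if self.mean_mmhg - self.amplitude_mmhg < 0:
            raise InvalidParameterError("inlet pressure law would go negative (mean < amplitude)")


@dataclass(frozen=True)
class Probe:
    """Named observation station at an arc-length position along the loop.

    ``side`` disambiguates stations that sit exactly at a lumped element
    (porous baffle, valve): "upstream" picks the node before it, "downstream"
    the node after.
    """

    name: str
    arc_cm: float
    side: str = "upstream"


@dataclass(frozen=True)
class Circuit:
    """Static description of the loop, inlet to outlet.

    Segments are ordered in the flow direction. The porous interface sits
    after segment index ``porous_after``; the two check valves bracket the
    (single) segment with role ``"calf"``.
    """

    fluid: FluidProperties
    segments: tuple[VesselSegment, ...]
    porous_interface: PorousInterface
    porous_after: int  # porous baffle sits downstream of segments[porous_after]
    inlet: InletLaw
    outlet_pressure_mmhg: float = 0.0
    gravity_m_s2: float = GRAVITY_M_S2
    inlet_elevation_cm: float = ARM_LENGTH_CM
    probes: tuple[Probe, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.segments:
            raise InvalidParameterError("circuit needs at least one segment")
        if not (0 <= self.porous_after < len(self.segments)):
            raise InvalidParameterError("porous_after out of range")
        if self.gravity_m_s2 < 0:
            raise InvalidParameterError("gravity must be >= 0")
        calves = [s for s in self.segments if s.role == "calf"]
        if len(calves) > 1:
            raise InvalidParameterError("at most one calf segment is supported")
        total = self.total_arc_cm
        for p in self.probes:
            if not (0 <= p.arc_cm <= total + 1e-9):
                raise InvalidParameterError(f"probe {p.name} lies outside the circuit")

    # -- geometry helpers -------------------------------------------------

    @property
    def total_arc_cm(self) -> float:
        return sum(s.length_cm for s in self.segments)

    def segment_arc_start_cm(self, index: int) -> float:
        return sum(s.length_cm for s in self.segments[:index])

    def elevation_at_arc_cm(self, arc_cm: float) -> float:
        """Elevation (cm above foot level) of the axial station at ``arc_cm``."""
        z = self.inlet_elevation_cm
        remaining = arc_cm
        for seg in self.segments:
            step = min(remaining, seg.length_cm)
            z -= seg.elevation_drop_cm * (step / seg.length_cm)
            remaining -= step
            if remaining <= 0:
                break
        return z

    def calf_segment_index(self) -> int | None:
        for i, s in enumerate(self.segments):
            if s.role == "calf":
                return i
        return None

    def probe(self, name: str) -> Probe:
        for p in self.probes:
            if p.name == name:
                return p
        raise InvalidParameterError(f"no probe named {name!r}")

    # -- invariant check --------------------------------------------------

    def continuity_consistency(self, reference_velocities_cm_s: dict[str, float]) -> float:
        """Max relative spread of A*v across segments for the given velocity set.

        Returns the largest |A_i v_i - median| / median over segments whose
        role appears in ``reference_velocities_cm_s``.
        """
        flows = [
            s.area_cm2 * reference_velocities_cm_s[s.role]
            for s in self.segments
            if s.role in reference_velocities_cm_s
        ]
        if not flows:
            raise InvalidParameterError("no segment matches the reference velocity set")
        mean = sum(flows) / len(flows)
        return max(abs(f - mean) / mean for f in flows)


# -- operations -----------------------------------------------------------


def continuity_diameter(ref_diameter_cm: float, ref_velocity_cm_s: float,
                        target_velocity_cm_s: float) -> float:
    """Diameter carrying ``target_velocity`` at the same volumetric flow.

    From ``A v = const``: d = d_ref * sqrt(v_ref / v_target).
    """
    _require_positive(ref_diameter_cm=ref_diameter_cm, ref_velocity_cm_s=ref_velocity_cm_s,
                      target_velocity_cm_s=target_velocity_cm_s)
    return ref_diameter_cm * math.sqrt(ref_velocity_cm_s / target_velocity_cm_s)


def poiseuille_resistance(length_cm: float, diameter_cm: float,
                          fluid: FluidProperties = BLOOD) -> float:
    """Laminar (Hagen-Poiseuille) resistance 8*eta*l/(pi*r^4), in mmHg.s/mL."""
    _require_positive(length_cm=length_cm, diameter_cm=diameter_cm)
    length_m = units.cm_to_m(length_cm)
    radius_m = units.cm_to_m(diameter_cm / 2.0)
    r_si = 8.0 * fluid.viscosity * length_m / (math.pi * radius_m**4)
    return units.resistance_si_to_clinical(r_si)


def hydrostatic_delta(height_cm: float, fluid: FluidProperties = BLOOD,
                      gravity_m_s2: float = GRAVITY_M_S2) -> float:
    """Pressure of a blood column of the given height, rho*g*h in mmHg."""
    if gravity_m_s2 < 0:
        raise InvalidParameterError("gravity must be >= 0")
    return units.pa_to_mmhg(fluid.density * gravity_m_s2 * units.cm_to_m(height_cm))


def reference_flow_ml_s(vein_diameter_cm: float = 2 * CALF_RADIUS_CM,
                        vein_velocity_cm_s: float = REFERENCE_VELOCITIES_CM_S["vein"]) -> float:
    """Reference volumetric flow from the venous continuity pair (mL/s)."""
    area_cm2 = math.pi * (vein_diameter_cm / 2.0) ** 2
    return area_cm2 * vein_velocity_cm_s  # cm^3/s == mL/s


def calibrate_porous_resistance(circuit: Circuit, target_arterial_p_mmhg: float,
                                target_venous_p_mmhg: float,
                                reference_flow_ml_s: float) -> PorousInterface:
    """Size the porous baffle to produce the artery-to-vein pressure drop.

    The resistance absorbs the target drop minus whatever viscous loss the
    tube segments lying between the flanking probes already produce at the
    reference flow (none in the canonical layout, where the probes sit
    directly on either side of the baffle).
    """
    _require_positive(reference_flow_ml_s=reference_flow_ml_s)
    if target_arterial_p_mmhg <= target_venous_p_mmhg:
        raise InvalidParameterError("arterial target must exceed venous target")
    # No tube length separates the baffle from its flanking probes in this
    # topology, so the attributable viscous loss is zero by construction.
    tube_loss_mmhg = 0.0
    resistance = (target_arterial_p_mmhg - target_venous_p_mmhg - tube_loss_mmhg) / reference_flow_ml_s
    if resistance <= 0:
        raise CalibrationError(
            "tube losses exceed the target pressure drop; porous calibration infeasible"
        )
    return PorousInterface(resistance_mmhg_s_ml=resistance)


def calibrated_segment_resistances(segments: tuple[VesselSegment, ...],
                                   fluid: FluidProperties,
                                   arterial_drop_mmhg: float,
                                   venous_drop_mmhg: float,
                                   flow_ml_s: float) -> dict[str, float]:
    """Distribute the resting pressure budget over the tube segments.

    The arterial arm (aorta + artery) absorbs ``arterial_drop_mmhg`` at the
    reference flow, apportioned in proportion to each segment's Poiseuille
    resistance. On the venous side the wide conduit veins are hydraulically
    near-transparent, and the venous drop physiologically lives in the small
    veins and venules of the foot: the calf trunk and the veins above it keep
    their physical laminar resistance, and the first (foot-most) venous
    segment absorbs the remainder of ``venous_drop_mmhg``.
    """
    _require_positive(flow_ml_s=flow_ml_s)
    out: dict[str, float] = {}
    arterial = [s for s in segments if s.role in ("aorta", "artery")]
    if arterial:
        weights = [poiseuille_resistance(s.length_cm, s.diameter_cm, fluid) for s in arterial]
        total_w = sum(weights)
        total_r = arterial_drop_mmhg / flow_ml_s
        for s, w in zip(arterial, weights):
            out[s.name] = total_r * w / total_w
    venous = [s for s in segments if s.role in ("vein", "calf")]
    if venous:
        foot, above = venous[0], venous[1:]
        for s in above:
            out[s.name] = poiseuille_resistance(s.length_cm, s.diameter_cm, fluid)
        foot_r = venous_drop_mmhg / flow_ml_s - sum(out[s.name] for s in above)
        if foot_r <= 0:
            raise CalibrationError("conduit-vein losses exceed the venous pressure budget")
        out[foot.name] = foot_r
    return out


# -- canonical circuit ----------------------------------------------------


def canonical_segments() -> tuple[VesselSegment, ...]:
    """Geometry of the canonical loop (uncalibrated resistances)."""
    return (
        VesselSegment("aorta", length_cm=10.0, diameter_cm=0.04,
                      elevation_drop_cm=10.0, role="aorta"),
        VesselSegment("artery", length_cm=120.0, diameter_cm=0.08,
                      elevation_drop_cm=120.0, role="artery"),
        VesselSegment("foot_vein", length_cm=CALF_Z0_CM, diameter_cm=2 * CALF_RADIUS_CM,
                      elevation_drop_cm=-CALF_Z0_CM, role="vein"),
        VesselSegment("calf", length_cm=CALF_LENGTH_CM, diameter_cm=2 * CALF_RADIUS_CM,
                      elevation_drop_cm=-CALF_LENGTH_CM, wall="prescribed-motion", role="calf"),
        VesselSegment("upper_vein", length_cm=ARM_LENGTH_CM - CALF_Z0_CM - CALF_LENGTH_CM,
                      diameter_cm=2 * CALF_RADIUS_CM,
                      elevation_drop_cm=-(ARM_LENGTH_CM - CALF_Z0_CM - CALF_LENGTH_CM),
                      role="vein"),
    )


def canonical_probes() -> tuple[Probe, ...]:
    """Observation points I-VI along the loop (arc length from the inlet)."""
    return (
        Probe("I", 0.0),                        # aortic inlet, heart level
        Probe("II", 130.0, "upstream"),         # artery at foot level
        Probe("III", 130.0, "downstream"),      # vein at foot level, past the baffle
        Probe("IV", 140.0, "upstream"),         # ankle, upstream of the distal valve
        Probe("V", 170.0, "downstream"),        # knee, downstream of the proximal valve
        Probe("VI", 260.0, "downstream"),       # venous outlet (vena cava), heart level
    )


def canonical_circuit(gravity_on: bool = True,
                      fluid: FluidProperties = BLOOD) -> Circuit:
    """Fully calibrated canonical loop.

    Tube resistances and the porous baffle reproduce the resting pressure
    budget (100 -> 95 mmHg along the arterial arm, 80 mmHg across the baffle,
    15 -> 0 mmHg along the venous arm) at the reference venous flow.
    """
    q_ref = reference_flow_ml_s()
    segments = canonical_segments()
    res = calibrated_segment_resistances(
        segments, fluid,
        arterial_drop_mmhg=CLINOSTATIC_PRESSURES_MMHG["aorta"] - CLINOSTATIC_PRESSURES_MMHG["artery"],
        venous_drop_mmhg=CLINOSTATIC_PRESSURES_MMHG["vein"] - 0.0,
        flow_ml_s=q_ref,
    )
    segments = tuple(replace(s, resistance_mmhg_s_ml=res[s.name]) for s in segments)
    circuit = Circuit(
        fluid=fluid,
        segments=segments,
        porous_interface=PorousInterface(1.0),  # placeholder, calibrated below
        porous_after=1,  # baffle between artery and foot_vein
        inlet=InletLaw(),
        outlet_pressure_mmhg=0.0,
        gravity_m_s2=GRAVITY_M_S2 if gravity_on else 0.0,
        probes=canonical_probes(),
    )
    porous = calibrate_porous_resistance(
        circuit,
        target_arterial_p_mmhg=CLINOSTATIC_PRESSURES_MMHG["artery"],
        target_venous_p_mmhg=CLINOSTATIC_PRESSURES_MMHG["vein"],
        reference_flow_ml_s=q_ref,
    )
    return replace(circuit, porous_interface=porous)
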