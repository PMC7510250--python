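"""Reduced-order (quasi-1D transmission-line) solver for the circuit.

The loop is discretized into a chain of nodes and edges. Each plain edge
carries an inertance ``rho*l/A`` and a laminar resistance; the porous baffle
is a purely resistive edge; the two valve edges carry the position-dependent
orifice and seat-film losses of the ball valves. Nodes are rigid
incompressible junctions: nodal mass balance (with swept-volume source terms
on the calf nodes, where the prescribed wall motion changes the lumen) is
solved algebraically each step together with the edge momentum equations

    L_j dQ_j/dt = (p_up - p_down) - R_j Q_j - K_j Q_j |Q_j| - rho g dz_j

using a semi-implicit scheme: implicit in the pressure and the linear(ized)
friction/orifice terms, explicit in the forcing and the valve state. Because
the network is a single unbranched chain, the nodal pressure system is
tridiagonal and is solved directly, so every step conserves mass to solver
precision regardless of dt. An explicit-friction mode exists for oracle
cross-checks at small dt.

Two time steps mirror the two dynamical regimes: a slow step (default
1e-2 s) for resting postures and a fast step (default 2e-4 s) when the
muscle pump is active. The CFL number ``v dt / dx`` is checked against 1
with a reference velocity before a run is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from . import units
from .circuit import Circuit
from .errors import (DiscretizationError, InvalidParameterError,
                     NumericalFailureError, StabilityError)
from .forcing import ForcingSchedule, inlet_pressure, wall_displacement
from .valves import (BallValveSpec, BallValveState, advance_ball,
                     ball_force_balance, effective_orifice_area,
                     valve_edge_resistance_si, valve_quadratic_coeff_si)

EDGE_PLAIN = 0
EDGE_POROUS = 1
EDGE_VALVE_DISTAL = 2
EDGE_VALVE_PROXIMAL = 3

#: axial extent (cm) attributed to a valve edge for its inertance
VALVE_EDGE_LENGTH_CM = 0.52
#: ditto for the porous baffle (uses the upstream edge area)
POROUS_EDGE_LENGTH_CM = 1.0


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings of a run."""

    dt_slow_s: float = 1e-2
    dt_fast_s: float = 2e-4
    total_cycles: int = 10
    dx_cm: float = 1.0
    scheme: str = "semi-implicit"  # "semi-implicit" | "explicit"
    transient_rel_tol: float = 0.01
    min_discard_cycles: int = 2
    node_compliance_ml_mmhg: float = 0.0
    cfl_velocity_ref_m_s: float = 0.35
    cadence_s: float | None = None  # None: record every step
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.dt_fast_s <= self.dt_slow_s):
            raise InvalidParameterError("need 0 < dt_fast <= dt_slow")
        if self.total_cycles < 2:
            raise InvalidParameterError("need at least 2 cycles")
        if self.scheme not in ("semi-implicit", "explicit"):
            raise InvalidParameterError(f"unknown scheme {self.scheme!r}")

    def dt_for(self, forcing: ForcingSchedule) -> float:
        """Fast step when the muscle pump is active, slow step otherwise."""
        active = forcing.wall_motion is not None and \
            forcing.wall_motion.displacement_amplitude_cm > 0
        return self.dt_fast_s if active else self.dt_slow_s


@dataclass
class Discretization:
    """Node/edge arrays of the chain discretization."""

    node_arc_cm: np.ndarray
    node_elev_cm: np.ndarray
    edge_length_cm: np.ndarray
    edge_area_cm2: np.ndarray
    edge_kind: np.ndarray          # int codes EDGE_*
    edge_resistance_si: np.ndarray  # Pa.s/m^3, linear part (valves updated live)
    edge_inertance_si: np.ndarray   # Pa.s^2/m^3
    edge_dz_m: np.ndarray           # elevation gain along flow, m
    calf_node_weight_cm2: np.ndarray  # swept-rate geometric weight per node
    calf_node_z_cm: np.ndarray       # node elevations inside the calf (NaN outside)
    probe_nodes: dict[str, int]
    dx_cm: float

    @property
    def n_edges(self) -> int:
        return len(self.edge_length_cm)

    @property
    def n_nodes(self) -> int:
        return len(self.node_arc_cm)

    def edge_index(self, kind: int) -> int:
        idx = np.nonzero(self.edge_kind == kind)[0]
        if len(idx) != 1:
            raise DiscretizationError(f"expected exactly one edge of kind {kind}")
        return int(idx[0])


@dataclass
class SimulationState:
    """Snapshot of the evolving system (clinical units)."""

    time_s: float
    node_pressures_mmhg: np.ndarray
    edge_flows_ml_s: np.ndarray
    calf_areas_cm2: np.ndarray
    valve_states: tuple[BallValveState, BallValveState]  # (distal, proximal)


def cfl_number(velocity_m_s: float, dt_s: float, dx_m: float) -> float:
    """Courant number ``v dt / dx``."""
    if dx_m <= 0:
        raise InvalidParameterError("dx must be > 0")
    return velocity_m_s * dt_s / dx_m


def build_discretization(circuit: Circuit, target_dx_cm: float) -> Discretization:
    """Subdivide the circuit into a chain of edges of ~``target_dx_cm``.

    Valve edges (zero arc length, ball-diameter inertance) are inserted at
    the two ends of the calf segment; the porous edge after the arterial arm.
    Per-edge resistance is the segment's hydraulic resistance apportioned by
    length, the inertance is ``rho l / A``.
    """
    if target_dx_cm <= 0:
        raise InvalidParameterError("target_dx must be > 0")
    min_seg = min(s.length_cm for s in circuit.segments)
    if target_dx_cm > min_seg:
        raise DiscretizationError(
            f"target_dx {target_dx_cm} cm exceeds shortest segment ({min_seg} cm)")

    rho = circuit.fluid.density
    calf_idx = circuit.calf_segment_index()

    arcs = [0.0]
    elevs = [circuit.inlet_elevation_cm]
    e_len, e_area, e_kind, e_res, e_iner = [], [], [], [], []
    calf_weights: list[float] = []
    calf_z: list[float] = []

    def push_edge(length_cm, area_cm2, kind, res_si, iner_si, dz_cm):
        e_len.append(length_cm)
        e_area.append(area_cm2)
        e_kind.append(kind)
        e_res.append(res_si)
        e_iner.append(iner_si)
        arcs.append(arcs[-1] + length_cm)
        elevs.append(elevs[-1] + dz_cm)

    for si, seg in enumerate(circuit.segments):
        area_m2 = seg.area_cm2 * units.CM_M**2
        if si == calf_idx:
            # distal valve edge just upstream of the calf trunk
            push_edge(0.0, seg.area_cm2, EDGE_VALVE_DISTAL, 0.0,
                      rho * units.cm_to_m(VALVE_EDGE_LENGTH_CM) / area_m2, 0.0)
        n_sub = max(1, round(seg.length_cm / target_dx_cm))
        sub = seg.length_cm / n_sub
        r_total_si = units.resistance_clinical_to_si(
            seg.hydraulic_resistance_mmhg_s_ml(circuit.fluid))
        for _ in range(n_sub):
            push_edge(sub, seg.area_cm2, EDGE_PLAIN, r_total_si / n_sub,
                      rho * units.cm_to_m(sub) / area_m2,
                      -seg.elevation_drop_cm / n_sub)
        if si == calf_idx:
            push_edge(0.0, seg.area_cm2, EDGE_VALVE_PROXIMAL, 0.0,
                      rho * units.cm_to_m(VALVE_EDGE_LENGTH_CM) / area_m2, 0.0)
        if si == circuit.porous_after:
            push_edge(0.0, seg.area_cm2, EDGE_POROUS,
                      units.resistance_clinical_to_si(
                          circuit.porous_interface.resistance_mmhg_s_ml),
                      rho * units.cm_to_m(POROUS_EDGE_LENGTH_CM) / area_m2, 0.0)

    node_arc = np.asarray(arcs)
    node_elev = np.asarray(elevs)
    n_nodes = len(node_arc)

    # swept-volume weights: node i collects half of the exact axial integral
    # of sin(pi (z-z0)/L) over each adjacent calf sub-interval (thin wall)
    weights = np.zeros(n_nodes)
    calf_z_arr = np.full(n_nodes, np.nan)
    if calf_idx is not None:
        seg = circuit.segments[calf_idx]
        radius_cm = seg.diameter_cm / 2.0
        length = seg.length_cm
        kinds = np.asarray(e_kind)
        # calf sub-edges are those between the two valve edges
        i_d = int(np.nonzero(kinds == EDGE_VALVE_DISTAL)[0][0])
        i_p = int(np.nonzero(kinds == EDGE_VALVE_PROXIMAL)[0][0])
        calf_edges = list(range(i_d + 1, i_p))
        z0 = node_elev[calf_edges[0]]
        for j in calf_edges:
            za, zb = node_elev[j], node_elev[j + 1]
            integral = (length / math.pi) * (
                math.cos(math.pi * (za - z0) / length)
                - math.cos(math.pi * (zb - z0) / length))
            # times a*pi (axial shape) later; geometric part only here
            half = 2.0 * math.pi * radius_cm * math.pi * integral / 2.0
            weights[j] += half
            weights[j + 1] += half
        on_calf = weights != 0.0
        calf_z_arr[on_calf] = node_elev[on_calf]

    probe_nodes: dict[str, int] = {}
    for p in circuit.probes:
        close = np.nonzero(np.abs(node_arc - p.arc_cm) < 1e-9)[0]
        if len(close) == 0:
            probe_nodes[p.name] = int(np.argmin(np.abs(node_arc - p.arc_cm)))
        elif getattr(p, "side", "upstream") == "downstream":
            probe_nodes[p.name] = int(close[-1])
        else:
            probe_nodes[p.name] = int(close[0])

    plain = np.asarray(e_kind) == EDGE_PLAIN
    dx = float(np.min(np.asarray(e_len)[plain]))
    dz_m = units.cm_to_m(np.diff(node_elev))

    return Discretization(
        node_arc_cm=node_arc, node_elev_cm=node_elev,
        edge_length_cm=np.asarray(e_len), edge_area_cm2=np.asarray(e_area),
        edge_kind=np.asarray(e_kind), edge_resistance_si=np.asarray(e_res),
        edge_inertance_si=np.asarray(e_iner), edge_dz_m=dz_m,
        calf_node_weight_cm2=weights, calf_node_z_cm=calf_z_arr,
        probe_nodes=probe_nodes, dx_cm=dx,
    )


@dataclass
class RunResult:
    """Probe time series and run metadata returned by :func:`run`."""

    data: pd.DataFrame
    circuit: Circuit
    forcing: ForcingSchedule
    config: SolverConfig
    discretization: Discretization
    dt_s: float
    final_state: SimulationState

    @property
    def cycle_period_s(self) -> float:
        return self.forcing.cycle_period_s


class NetworkSolver:
    """Stateful stepper over a fixed discretization."""

    def __init__(self, circuit: Circuit, forcing: ForcingSchedule,
                 valve_specs: tuple[BallValveSpec, BallValveSpec],
                 disc: Discretization, config: SolverConfig,
                 dt_s: float | None = None,
                 initial_velocity_cm_s: float = 35.0,
                 initial_pressure_mmhg: float = 100.0):
        self.circuit = circuit
        self.forcing = forcing
        self.disc = disc
        self.config = config
        self.specs = valve_specs
        self.dt = dt_s if dt_s is not None else config.dt_for(forcing)
        c = cfl_number(config.cfl_velocity_ref_m_s, self.dt, units.cm_to_m(disc.dx_cm))
        if c > 1.0:
            raise StabilityError(
                f"CFL number {c:.3g} > 1 for dt={self.dt} s, dx={disc.dx_cm} cm")

        self.g = circuit.gravity_m_s2
        self.rho = circuit.fluid.density
        self.i_distal = disc.edge_index(EDGE_VALVE_DISTAL) if \
            (disc.edge_kind == EDGE_VALVE_DISTAL).any() else None
        self.i_proximal = disc.edge_index(EDGE_VALVE_PROXIMAL) if \
            (disc.edge_kind == EDGE_VALVE_PROXIMAL).any() else None

        # static arrays
        self.R0 = disc.edge_resistance_si.copy()
        self.L = disc.edge_inertance_si.copy()
        self.hydro = self.rho * self.g * disc.edge_dz_m  # Pa per edge
        self.K = np.zeros(disc.n_edges)  # quadratic coeff (valves only)
        self.calf_mask = disc.calf_node_weight_cm2 != 0.0
        self.calf_radius_cm = None
        ci = circuit.calf_segment_index()
        if ci is not None:
            self.calf_radius_cm = circuit.segments[ci].diameter_cm / 2.0

        # initial conditions: p0 = 100 mmHg everywhere, Q0 from the aortic
        # initialization velocity through the first segment's lumen
        self.t = 0.0
        self.p = np.full(disc.n_nodes, units.mmhg_to_pa(initial_pressure_mmhg))
        q0 = units.ml_to_m3(circuit.segments[0].area_cm2 * initial_velocity_cm_s)
        self.q = np.full(disc.n_edges, q0)
        self.valve_states: list[BallValveState] = []
        for spec, orient in zip(valve_specs, ("distal", "proximal")):
            self.valve_states.append(
                BallValveState(spec.travel_max_cm, 0.0,
                               effective_orifice_area(spec.travel_max_cm, spec), orient))
        self._sync_valve_edges()
        self._steps_done = 0

    # ------------------------------------------------------------------

    def _sync_valve_edges(self) -> None:
        for idx, state, spec in zip((self.i_distal, self.i_proximal),
                                    self.valve_states, self.specs):
            if idx is None:
                continue
            self.R0[idx] = valve_edge_resistance_si(state.position_cm, spec,
                                                    self.circuit.fluid)
            self.K[idx] = valve_quadratic_coeff_si(state.position_cm, spec,
                                                   self.circuit.fluid)

    def _advance_valves(self, dt: float) -> None:
        for k, idx in enumerate((self.i_distal, self.i_proximal)):
            if idx is None:
                continue
            spec = self.specs[k]
            state = self.valve_states[k]
            p_up = units.pa_to_mmhg(self.p[idx])
            p_dn = units.pa_to_mmhg(self.p[idx + 1])
            force = ball_force_balance(state, spec, p_up, p_dn,
                                       units.m3_to_ml(self.q[idx]),
                                       self.circuit.fluid, self.g)
            self.valve_states[k] = advance_ball(state, force, dt, spec)
        self._sync_valve_edges()

    def _swept_sources_si(self, t: float) -> np.ndarray:
        """Nodal dV/dt (m^3/s) from the prescribed wall motion."""
        wm = self.forcing.wall_motion
        if wm is None or wm.displacement_amplitude_cm == 0.0:
            return np.zeros(self.disc.n_nodes)
        v_t = math.sin(2 * math.pi * t / wm.period_s) / wm.period_s
        # weight * a * V_t = inward swept rate (cm^3/s); dV/dt is its negative
        rate_cm3_s = self.disc.calf_node_weight_cm2 * wm.displacement_amplitude_cm * v_t
        return -units.ml_to_m3(rate_cm3_s)

    def step(self) -> None:
        """Advance one time step (semi-implicit network solve)."""
        dt = self.dt
        t_new = self.t + dt
        # (1) wall-motion sources at the new time, (2) valve dynamics from
        # the current pressures/flows, (3) nodal solve, (4) boundary values
        sources = self._swept_sources_si(t_new)
        self._advance_valves(dt)

        if self.config.scheme == "semi-implicit":
            beta = self.L / dt + self.R0 + self.K * np.abs(self.q)
            rhs_edge = self.L / dt * self.q - self.hydro
        else:  # explicit friction
            beta = self.L / dt
            rhs_edge = (self.L / dt * self.q - self.hydro
                        - self.R0 * self.q - self.K * np.abs(self.q) * self.q)
        b = 1.0 / beta
        a = b * rhs_edge

        n = self.disc.n_nodes
        p_in = units.mmhg_to_pa(inlet_pressure(t_new, self.forcing.inlet))
        p_out = units.mmhg_to_pa(self.circuit.outlet_pressure_mmhg)

        # interior nodes 1..n-2: -b[i-1] p[i-1] + (b[i-1]+b[i]) p[i] - b[i] p[i+1]
        #                        = a[i-1] - a[i] - S[i]
        diag = b[:-1] + b[1:]
        lower = -b[1:-1]
        upper = -b[1:-1]
        rhs = a[:-1] - a[1:] - sources[1:-1]
        comp = units.ml_to_m3(self.config.node_compliance_ml_mmhg) / units.MMHG_PA
        if comp > 0:
            diag = diag + comp / dt
            rhs = rhs + comp / dt * self.p[1:-1]
        rhs[0] += b[0] * p_in
        rhs[-1] += b[-1] * p_out

        ab = np.zeros((3, n - 2))
        ab[0, 1:] = upper
        ab[1, :] = diag
        ab[2, :-1] = lower
        p_int = solve_banded((1, 1), ab, rhs)

        p = np.empty(n)
        p[0], p[-1] = p_in, p_out
        p[1:-1] = p_int
        q = a + b * (p[:-1] - p[1:])

        self.p, self.q, self.t = p, q, t_new
        self._steps_done += 1
        if self._steps_done % 50 == 0 and not (
                np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
            raise NumericalFailureError("solver state became non-finite",
                                        last_valid_time=self.t - 50 * dt)

    # ------------------------------------------------------------------

    def mass_defect_ml(self) -> float:
        """Largest nodal mass-balance residual of the last step, in mL."""
        sources = self._swept_sources_si(self.t)
        res = self.q[:-1] - self.q[1:] - sources[1:-1]
        return float(np.max(np.abs(res)) * self.dt / units.ML_M3)

    def calf_areas_cm2(self) -> np.ndarray:
        z = self.disc.calf_node_z_cm[self.calf_mask]
        wm = self.forcing.wall_motion
        if wm is None or self.calf_radius_cm is None:
            return np.full(z.shape, math.pi * (self.calf_radius_cm or 0.0) ** 2)
        delta = wall_displacement(z, self.t, wm)
        return math.pi * (self.calf_radius_cm - np.asarray(delta)) ** 2

    def snapshot(self) -> SimulationState:
        return SimulationState(
            time_s=self.t,
            node_pressures_mmhg=units.pa_to_mmhg(self.p.copy()),
            edge_flows_ml_s=units.m3_to_ml(self.q.copy()),
            calf_areas_cm2=self.calf_areas_cm2(),
            valve_states=(self.valve_states[0], self.valve_states[1]),
        )


def step(state: SimulationState, forcing: ForcingSchedule, disc: Discretization,
         cfg: SolverConfig, circuit: Circuit,
         valve_specs: tuple[BallValveSpec, BallValveSpec]) -> SimulationState:
    """Advance a snapshot one time step (functional wrapper over the stepper)."""
    solver = NetworkSolver(circuit, forcing, valve_specs, disc, cfg)
    solver.t = state.time_s
    solver.p = units.mmhg_to_pa(np.asarray(state.node_pressures_mmhg, dtype=float))
    solver.q = units.ml_to_m3(np.asarray(state.edge_flows_ml_s, dtype=float))
    solver.valve_states = list(state.valve_states)
    solver._sync_valve_edges()
    solver.step()
    return solver.snapshot()


def run(circuit: Circuit, forcing: ForcingSchedule,
        valve_specs: tuple[BallValveSpec, BallValveSpec],
        config: SolverConfig) -> RunResult:
    """Simulate ``config.total_cycles`` forcing cycles and collect probe series.

    The time step is the fast one when the muscle pump is active, the slow
    one otherwise, snapped so that an integer number of steps tiles one
    cycle. Probe pressures (I-VI), the ankle/knee cross-section flows (the
    valve edges), the boundary flows and the valve ball positions are
    recorded every ``cadence_s`` (default: every step).
    """
    period = forcing.cycle_period_s
    dt_nominal = config.dt_for(forcing)
    n_per_cycle = max(1, round(period / dt_nominal))
    dt = period / n_per_cycle

    disc = build_discretization(circuit, config.dx_cm)
    solver = NetworkSolver(circuit, forcing, valve_specs, disc, config, dt_s=dt)

    record_every = 1 if config.cadence_s is None else max(1, round(config.cadence_s / dt))
    n_steps = n_per_cycle * config.total_cycles
    n_rec = n_steps // record_every + 1

    probe_names = list(disc.probe_nodes)
    probe_idx = np.asarray([disc.probe_nodes[k] for k in probe_names])
    i_d, i_p = solver.i_distal, solver.i_proximal

    cols = (["time_s"] + [f"p_{k}_mmhg" for k in probe_names]
            + ["Q_ankle_ml_s", "Q_knee_ml_s", "Q_inlet_ml_s", "Q_outlet_ml_s",
               "x_distal_cm", "x_proximal_cm", "a_distal_cm2", "a_proximal_cm2"])
    buf = np.empty((n_rec, len(cols)))

    def record(row: int) -> None:
        p_mmhg = units.pa_to_mmhg(solver.p[probe_idx])
        q_ml = units.m3_to_ml(solver.q)
        vd, vp = solver.valve_states
        buf[row] = [solver.t, *p_mmhg,
                    q_ml[i_d] if i_d is not None else q_ml[0],
                    q_ml[i_p] if i_p is not None else q_ml[-1],
                    q_ml[0], q_ml[-1],
                    vd.position_cm, vp.position_cm,
                    vd.effective_area_cm2, vp.effective_area_cm2]

    record(0)
    row = 1
    for istep in range(1, n_steps + 1):
        solver.step()
        if istep % record_every == 0:
            record(row)
            row += 1

    data = pd.DataFrame(buf[:row], columns=cols)
    return RunResult(data=data, circuit=circuit, forcing=forcing, config=config,
                     discretization=disc, dt_s=dt, final_state=solver.snapshot())
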