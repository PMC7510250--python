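"""Discretization bookkeeping and analytic oracles for the network stepper."""

import math

import numpy as np
import pytest

import venapump as vp
from venapump import units
from venapump.circuit import (Circuit, FluidProperties, InletLaw,
                              PorousInterface, Probe, VesselSegment)
from venapump.errors import DiscretizationError, StabilityError
from venapump.solver import EDGE_PLAIN, EDGE_POROUS, NetworkSolver


def straight_tube_circuit(gravity_on=False, inlet_mean=10.0, inlet_amp=0.0,
                          length=65.0, diameter=0.5, drop=0.0):
    """Two plain segments with a (negligible) porous edge between them."""
    segs = (
        VesselSegment("down", length, diameter, elevation_drop_cm=drop, role="artery"),
        VesselSegment("up", length, diameter, elevation_drop_cm=-drop, role="vein"),
    )
    return Circuit(
        fluid=FluidProperties(), segments=segs,
        porous_interface=PorousInterface(1e-9), porous_after=0,
        inlet=InletLaw(inlet_mean, inlet_amp, 1.0), outlet_pressure_mmhg=0.0,
        gravity_m_s2=9.81 if gravity_on else 0.0,
        inlet_elevation_cm=drop if drop else 0.0,
        probes=(Probe("mid", length),),
    )


def no_valves():
    return (vp.BallValveSpec(), vp.BallValveSpec())


class TestBuildDiscretization:
    def test_single_segment_edge_count_and_length(self):
        c = straight_tube_circuit(length=15.0)
        disc = vp.build_discretization(c, 1.0)
        plain = disc.edge_kind == EDGE_PLAIN
        assert plain.sum() == 30  # 15 + 15 cm at 1 cm spacing
        assert disc.edge_length_cm[plain].sum() == pytest.approx(30.0)
        assert (disc.edge_kind == EDGE_POROUS).sum() == 1

    def test_edge_inertance_value(self):
        # 1 cm of 0.5 cm-diameter tube: rho l / A = 5.40e5 Pa s^2 / m^3
        c = straight_tube_circuit()
        disc = vp.build_discretization(c, 1.0)
        i_plain = np.nonzero(disc.edge_kind == EDGE_PLAIN)[0][0]
        assert disc.edge_inertance_si[i_plain] == pytest.approx(5.40e5, rel=1e-3)

    def test_canonical_probes_resolve(self):
        c = vp.canonical_circuit()
        disc = vp.build_discretization(c, 1.0)
        assert set(disc.probe_nodes) == {"I", "II", "III", "IV", "V", "VI"}
        assert disc.probe_nodes["I"] == 0
        assert disc.probe_nodes["VI"] == disc.n_nodes - 1
        # III sits after the porous edge, II before it
        assert disc.probe_nodes["III"] == disc.probe_nodes["II"] + 1
        # total arc conserved
        assert disc.node_arc_cm[-1] == pytest.approx(c.total_arc_cm)

    def test_too_large_dx_rejected(self):
        with pytest.raises(DiscretizationError):
            vp.build_discretization(vp.canonical_circuit(), 50.0)


class TestCflNumber:
    @pytest.mark.parametrize("v, dt, dx, expected", [
        (0.2, 2e-4, 5e-4, 0.08),   # pump-active operating point
        (0.0, 1.0, 1.0, 0.0),
        (1.0, 1e-3, 1e-3, 1.0),    # stability boundary
    ])
    def test_examples(self, v, dt, dx, expected):
        assert vp.cfl_number(v, dt, dx) == pytest.approx(expected)

    def test_run_refuses_unstable_dt(self):
        c = vp.canonical_circuit(gravity_on=False)
        forcing = vp.ForcingSchedule(inlet=c.inlet)
        cfg = vp.SolverConfig(dt_slow_s=0.05, total_cycles=2)
        with pytest.raises(StabilityError):
            vp.run(c, forcing, no_valves(), cfg)


class TestSteadyOracles:
    def test_poiseuille_steady_flow(self):
        """Constant head over a rigid tube settles on the laminar closed form."""
        c = straight_tube_circuit(inlet_mean=10.0)
        forcing = vp.ForcingSchedule(inlet=c.inlet)
        cfg = vp.SolverConfig(total_cycles=5, dx_cm=1.0)
        res = vp.run(c, forcing, no_valves(), cfg)
        r_total = sum(s.hydraulic_resistance_mmhg_s_ml(c.fluid) for s in c.segments)
        q_expected = 10.0 / r_total
        assert res.data["Q_outlet_ml_s"].iloc[-1] == pytest.approx(q_expected, rel=1e-3)

    def test_hydrostatic_equilibrium(self):
        """Equal end pressures at equal elevation: no flow, rho*g*h profile."""
        c = straight_tube_circuit(gravity_on=True, inlet_mean=0.0, drop=65.0)
        forcing = vp.ForcingSchedule(inlet=c.inlet)
        cfg = vp.SolverConfig(total_cycles=8)
        res = vp.run(c, forcing, no_valves(), cfg)
        assert abs(res.data["Q_outlet_ml_s"].iloc[-1]) < 1e-9
        state = res.final_state
        disc = res.discretization
        p_bottom = state.node_pressures_mmhg[disc.probe_nodes["mid"]]
        expected = vp.hydrostatic_delta(65.0)
        assert p_bottom == pytest.approx(expected, rel=1e-3)
        # pairwise: dp = rho g dh along the column
        z = disc.node_elev_cm
        p = state.node_pressures_mmhg
        for i in range(0, disc.n_nodes - 1, 10):
            dp = p[i] - p[i + 1]
            assert dp == pytest.approx(
                vp.hydrostatic_delta(z[i + 1] - z[i]), abs=2e-3 * max(1.0, abs(dp)))

    def test_zero_forcing_zero_flow_is_fixed_point(self):
        c = straight_tube_circuit(inlet_mean=0.0)
        forcing = vp.ForcingSchedule(inlet=c.inlet)
        cfg = vp.SolverConfig(total_cycles=2)
        disc = vp.build_discretization(c, 1.0)
        solver = NetworkSolver(c, forcing, no_valves(), disc, cfg,
                               initial_velocity_cm_s=0.0, initial_pressure_mmhg=0.0)
        for _ in range(10000):
            solver.step()
        assert np.max(np.abs(solver.q)) < 1e-18
        assert np.max(np.abs(solver.p)) < 1e-12


class TestConservation:
    def test_mass_defect_below_tolerance(self, walk_healthy):
        """Nodal mass balance closes to solver precision every step."""
        res = walk_healthy.run
        d = res.data
        # boundary throughput balance over the last 5 full cycles
        period = res.cycle_period_s
        n = round(5 * period / res.dt_s)
        q_in = d["Q_inlet_ml_s"].to_numpy()[-n:]
        q_out = d["Q_outlet_ml_s"].to_numpy()[-n:]
        defect_ml = np.sum(q_in - q_out) * res.dt_s
        assert abs(defect_ml) < 1e-6

    def test_knee_ankle_cycle_volumes_agree(self, walk_healthy):
        assert walk_healthy.knee.net_volume_ml == pytest.approx(
            walk_healthy.ankle.net_volume_ml, rel=0.01)

    def test_resting_scenarios_probe_consistency(self, ortho_result):
        assert ortho_result.knee.net_volume_ml == pytest.approx(
            ortho_result.ankle.net_volume_ml, rel=0.01)


class TestDualTimeStep:
    def test_slow_step_for_resting_fast_for_pumping(self):
        cfg = vp.SolverConfig()
        inlet = vp.InletLaw()
        assert cfg.dt_for(vp.ForcingSchedule(inlet)) == cfg.dt_slow_s
        assert cfg.dt_for(vp.ForcingSchedule(inlet, vp.WallMotionLaw())) == cfg.dt_fast_s
        flat = vp.WallMotionLaw(displacement_amplitude_cm=0.0)
        assert cfg.dt_for(vp.ForcingSchedule(inlet, flat)) == cfg.dt_slow_s

    def test_operating_point_is_comfortably_stable(self):
        # v = 0.2 m/s, dt = 2e-4 s, dx = 5e-4 m -> C = 0.08 << 1
        assert vp.cfl_number(0.2, 2e-4, 5e-4) < 1.0


class TestExplicitScheme:
    def test_explicit_matches_semi_implicit_at_small_dt(self):
        c = straight_tube_circuit(inlet_mean=10.0, inlet_amp=2.0)
        forcing = vp.ForcingSchedule(inlet=c.inlet)
        q = {}
        for scheme in ("semi-implicit", "explicit"):
            cfg = vp.SolverConfig(dt_slow_s=5e-5, dt_fast_s=5e-5,
                                  total_cycles=2, scheme=scheme)
            res = vp.run(c, forcing, no_valves(), cfg)
            q[scheme] = res.data["Q_outlet_ml_s"].to_numpy()[-2000:]
        assert np.allclose(q["semi-implicit"], q["explicit"], rtol=1e-3, atol=1e-8)
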