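"""Cycle metrics, canonical scenario behavior and the pump comparison."""

import math

import numpy as np
import pandas as pd
import pytest

import venapump as vp
from venapump.errors import ComparisonError, InsufficientDataError
from venapump.scenarios import CALF_VOLUME_ML, per_cycle_volumes
from venapump.valves import BallValveSpec, configure_incompetence


def series(t, q):
    return pd.Series(np.asarray(q), index=np.asarray(t))


class TestCycleVolumes:
    def test_constant_flow(self):
        t = np.linspace(0.0, 5.0, 5001)
        m = vp.cycle_volumes(series(t, np.full_like(t, 0.05)), 1.0)
        assert m.net_volume_ml == pytest.approx(0.05)
        assert m.retrograde_volume_ml == pytest.approx(0.0)

    def test_zero_mean_sinusoid(self):
        t = np.linspace(0.0, 6.0, 60001)
        q = np.sin(2 * math.pi * t)
        m = vp.cycle_volumes(series(t, q), 1.0)
        assert m.net_volume_ml == pytest.approx(0.0, abs=1e-9)
        assert m.antegrade_volume_ml == pytest.approx(-m.retrograde_volume_ml, rel=1e-6)

    def test_net_is_antegrade_plus_retrograde(self):
        t = np.linspace(0.0, 4.0, 40001)
        q = 0.3 * np.sin(2 * math.pi * t) + 0.1
        m = vp.cycle_volumes(series(t, q), 1.0)
        assert m.net_volume_ml == pytest.approx(
            m.antegrade_volume_ml + m.retrograde_volume_ml, rel=1e-9)

    def test_short_series_rejected(self):
        t = np.linspace(0.0, 0.5, 100)
        with pytest.raises(InsufficientDataError):
            vp.cycle_volumes(series(t, np.ones_like(t)), 1.0)

    def test_per_cycle_count(self):
        t = np.linspace(0.0, 7.3, 7301)
        cycles = per_cycle_volumes(t, np.ones_like(t), 1.0)
        assert len(cycles) == 7


class TestEjectionFraction:
    def test_reference_case(self):
        # 0.2 mL out of a pi*0.25^2*30 = 5.9 mL trunk
        assert vp.ejection_fraction(0.2) == pytest.approx(3.39, abs=0.01)
        assert CALF_VOLUME_ML == pytest.approx(5.9, abs=0.01)

    def test_degenerate_cases(self):
        assert vp.ejection_fraction(0.0) == 0.0
        assert vp.ejection_fraction(CALF_VOLUME_ML) == pytest.approx(100.0)


class TestRestingScenarios:
    def test_clinostatism_matches_resting_pressure_targets(self, clino_result):
        """With gravity off the probes sit on the calibrated resting budget."""
        d = clino_result.run.data
        last = d[d["time_s"] > d["time_s"].max() - 2.0]
        assert last["p_II_mmhg"].mean() == pytest.approx(95.0, rel=0.10)
        assert last["p_III_mmhg"].mean() == pytest.approx(15.0, rel=0.10)

    def test_clinostatism_residual_venous_pulsation(self, clino_result):
        """Venous flow at foot level keeps a cardiac-period modulation."""
        d = clino_result.run.data
        last = d[d["time_s"] > d["time_s"].max() - 3.0]
        q = last["Q_ankle_ml_s"]
        assert q.max() - q.min() > 0.001
        assert q.min() > 0.0  # no reflux at rest

    def test_orthostatism_cycle_volume_both_probes(self, ortho_result):
        assert ortho_result.ankle.net_volume_ml == pytest.approx(0.05, rel=0.10)
        assert ortho_result.knee.net_volume_ml == pytest.approx(0.05, rel=0.10)

    def test_orthostatism_valves_stay_open(self, ortho_result):
        d = ortho_result.run.data
        last = d[d["time_s"] > d["time_s"].max() - 2.0]
        assert last["x_distal_cm"].min() == pytest.approx(0.5)
        assert last["x_proximal_cm"].min() == pytest.approx(0.5)

    def test_orthostatism_venous_hydrostatic_pressure(self, ortho_result):
        d = ortho_result.run.data
        last = d[d["time_s"] > d["time_s"].max() - 2.0]
        # ankle venous pressure ~ blood column above it (120 cm), slightly more
        column = vp.hydrostatic_delta(120.0)
        assert last["p_IV_mmhg"].mean() > column
        assert last["p_IV_mmhg"].mean() == pytest.approx(column, rel=0.10)


class TestWalkingScenarios:
    def test_walking_with_zero_amplitude_reproduces_orthostatism(self):
        cfg = vp.SolverConfig(total_cycles=6)
        ortho = vp.run_scenario("orthostatism", solver_config=cfg)
        degenerate = vp.run_scenario("walking_healthy", solver_config=cfg,
                                     displacement_amplitude_cm=0.0)
        assert degenerate.knee.net_volume_ml == ortho.knee.net_volume_ml
        assert np.array_equal(degenerate.run.data["Q_knee_ml_s"].to_numpy(),
                              ortho.run.data["Q_knee_ml_s"].to_numpy())

    def test_dysfunction_ordering(self, all_walking):
        """Net return: healthy >= partial >= severe."""
        h = all_walking["walking_healthy"].knee.net_volume_ml
        p = all_walking["walking_partial"].knee.net_volume_ml
        s = all_walking["walking_severe"].knee.net_volume_ml
        assert h >= p >= s
        assert s > 0  # venous return persists even with severe incompetence

    def test_reflux_localized_in_diastole(self, walk_healthy, walk_severe):
        """Severe incompetence augments diastolic reflux at the knee while
        the systolic (contraction) output is unchanged within 5%."""
        assert abs(walk_severe.knee.retrograde_volume_ml) > \
            3 * abs(walk_healthy.knee.retrograde_volume_ml)
        assert walk_severe.knee.antegrade_volume_ml == pytest.approx(
            walk_healthy.knee.antegrade_volume_ml, rel=0.05)

    def test_net_volume_monotone_in_proximal_gap(self):
        cfg = vp.SolverConfig(total_cycles=6)
        nets = []
        for gap in (0.016, 0.08, 0.2):
            distal = BallValveSpec()
            proximal = BallValveSpec(min_gap_cm=gap)
            r = vp.run_scenario("walking_healthy", solver_config=cfg,
                                valve_pair=(distal, proximal))
            nets.append(r.knee.net_volume_ml)
        assert nets[0] >= nets[1] >= nets[2]

    def test_transient_is_discarded(self, walk_healthy):
        assert walk_healthy.discarded_cycles >= 2
        assert walk_healthy.converged


class TestCompareScenarios:
    def test_report(self, ortho_result, all_walking):
        metrics = {name: r.knee for name, r in all_walking.items()}
        metrics["orthostatism"] = ortho_result.knee
        report = vp.compare_scenarios(metrics)
        h = metrics["walking_healthy"].net_volume_ml
        assert report.pump_gain == pytest.approx(
            h / metrics["orthostatism"].net_volume_ml)
        assert report.reduction_pct["walking_severe"] > \
            report.reduction_pct["walking_partial"]
        # distal-only incompetence is non-critical, proximal is
        assert report.reduction_pct["walking_partial"] < 10.0
        assert report.reduction_pct["walking_severe"] > 20.0
        assert report.reflux_augmentation_ml["walking_severe"] > 0.0
        assert "walking_severe" in report.to_markdown()

    def test_missing_baseline_rejected(self, ortho_result):
        with pytest.raises(ComparisonError):
            vp.compare_scenarios({"orthostatism": ortho_result.knee})
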