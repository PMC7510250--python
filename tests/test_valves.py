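"""Ball check valve statics, dynamics and incompetence grading."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import venapump as vp
from venapump.errors import InvalidParameterError, StateViolationError
from venapump.valves import (BallValveState, residual_area_fraction_for_gap,
                             seat_viscous_resistance)


@pytest.fixture
def spec():
    return vp.BallValveSpec()


class TestEffectiveOrificeArea:
    def test_fully_open_is_seat_lumen(self, spec):
        a = vp.effective_orifice_area(spec.travel_max_cm, spec)
        assert a == pytest.approx(math.pi * 0.25**2)

    def test_healthy_closed_stop_leaks_one_percent(self, spec):
        assert vp.effective_orifice_area(0.0, spec) == pytest.approx(
            0.01 * spec.open_area_cm2)

    def test_incompetent_leak_scales_with_gap(self):
        # 0.2 cm gap -> (0.2/0.016) * 1% = 12.5% of the full opening
        assert residual_area_fraction_for_gap(0.2) == pytest.approx(0.125)
        # far larger gaps saturate at the full opening
        assert residual_area_fraction_for_gap(5.0) == 1.0

    def test_out_of_bounds_position_rejected(self, spec):
        with pytest.raises(StateViolationError):
            vp.effective_orifice_area(spec.travel_max_cm + 0.1, spec)

    @given(pos=st.floats(0.0, 0.5))
    def test_area_bounds_and_monotonicity(self, pos):
        spec = vp.BallValveSpec()
        a = vp.effective_orifice_area(pos, spec)
        assert spec.leak_area_cm2 <= a <= spec.open_area_cm2 + 1e-12
        assert vp.effective_orifice_area(min(pos + 0.01, 0.5), spec) >= a


class TestSeatLeakResistance:
    def test_decreases_with_incompetence_gap(self):
        healthy = vp.BallValveSpec(min_gap_cm=0.016)
        severe = vp.BallValveSpec(min_gap_cm=0.2)
        r_h = seat_viscous_resistance(0.0, healthy)
        r_s = seat_viscous_resistance(0.0, severe)
        # creeping-orifice scaling: R ~ A^{-3/2}, area ratio 12.5
        assert r_h / r_s == pytest.approx(12.5**1.5, rel=1e-6)

    def test_open_valve_is_hydraulically_transparent(self):
        spec = vp.BallValveSpec()
        assert seat_viscous_resistance(spec.travel_max_cm, spec) < 1.0


class TestBallForceBalance:
    def test_equilibrium_is_force_free(self, spec):
        state = BallValveState(0.2, 0.0, vp.effective_orifice_area(0.2, spec), "distal")
        f = vp.ball_force_balance(state, spec, 50.0, 50.0, 0.0, gravity_m_s2=9.81)
        assert f == pytest.approx(0.0, abs=1e-15)

    def test_unit_pressure_difference(self, spec):
        # 1 mmHg over a 0.52 cm ball: 133.3 Pa * pi*(0.0026 m)^2 = 2.83 mN
        state = BallValveState(0.2, 0.0, vp.effective_orifice_area(0.2, spec), "distal")
        f = vp.ball_force_balance(state, spec, 51.0, 50.0, 0.0)
        assert f == pytest.approx(2.83e-3, rel=1e-2)

    def test_reverse_pressure_pushes_toward_seat(self, spec):
        state = BallValveState(0.4, 0.0, vp.effective_orifice_area(0.4, spec), "proximal")
        assert vp.ball_force_balance(state, spec, 50.0, 60.0, 0.0) < 0.0

    def test_forward_flow_drags_open(self, spec):
        state = BallValveState(0.1, 0.0, vp.effective_orifice_area(0.1, spec), "distal")
        assert vp.ball_force_balance(state, spec, 50.0, 50.0, 0.5) > 0.0


class TestAdvanceBall:
    def test_sustained_forward_force_saturates_open(self, spec):
        state = BallValveState(0.0, 0.0, vp.effective_orifice_area(0.0, spec), "distal")
        for _ in range(200):
            state = vp.advance_ball(state, 1e-3, 1e-3, spec)
        assert state.position_cm == pytest.approx(spec.travel_max_cm)
        assert state.effective_area_cm2 == pytest.approx(spec.open_area_cm2)

    def test_sustained_reverse_force_seats(self, spec):
        state = BallValveState(spec.travel_max_cm, 0.0, spec.open_area_cm2, "proximal")
        for _ in range(200):
            state = vp.advance_ball(state, -1e-3, 1e-3, spec)
        assert state.position_cm == pytest.approx(0.0)
        assert state.effective_area_cm2 == pytest.approx(spec.leak_area_cm2)

    def test_zero_force_is_fixed_point(self, spec):
        state = BallValveState(0.3, 0.0, vp.effective_orifice_area(0.3, spec), "distal")
        out = vp.advance_ball(state, 0.0, 1e-3, spec)
        assert out.position_cm == state.position_cm

    def test_quasi_static_limit_matches_sign_oracle(self):
        """As the relaxation time vanishes the ball tracks sign(force)."""
        spec = vp.BallValveSpec(relaxation_time_s=1e-6)
        state = BallValveState(0.0, 0.0, vp.effective_orifice_area(0.0, spec), "distal")
        t = np.linspace(0.0, 1.0, 1001)
        dt = t[1] - t[0]
        for ti in t[1:]:
            force = math.sin(2 * math.pi * ti)
            state = vp.advance_ball(state, force, dt, spec)
            expected = spec.travel_max_cm if force > 0 else 0.0
            assert state.position_cm == pytest.approx(expected, abs=1e-6)

    def test_inertial_mode_also_saturates(self):
        spec = vp.BallValveSpec(dynamics="inertial")
        state = BallValveState(0.0, 0.0, vp.effective_orifice_area(0.0, spec), "distal")
        for _ in range(2000):
            state = vp.advance_ball(state, 1e-4, 1e-4, spec)
        assert state.position_cm == pytest.approx(spec.travel_max_cm)


class TestConfigureIncompetence:
    @pytest.mark.parametrize("grade, gaps", [
        ("healthy", (0.016, 0.016)),
        ("severe", (0.2, 0.2)),
        ("partial", (0.2, 0.016)),
    ])
    def test_grades(self, grade, gaps):
        pair = vp.configure_incompetence((vp.BallValveSpec(), vp.BallValveSpec()), grade)
        assert (pair[0].min_gap_cm, pair[1].min_gap_cm) == gaps

    def test_unknown_grade_rejected(self):
        with pytest.raises(InvalidParameterError):
            vp.configure_incompetence((vp.BallValveSpec(), vp.BallValveSpec()), "total")

    def test_ball_must_exceed_seat(self):
        with pytest.raises(InvalidParameterError):
            vp.BallValveSpec(ball_diameter_cm=0.49, seat_diameter_cm=0.50)
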