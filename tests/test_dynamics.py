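"""Plant, controller and integrator checks against closed forms."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cupball.dynamics import (
    ControllerSpec,
    CupBallState,
    DivergenceError,
    SystemParams,
    accelerations,
    impedance_force,
    mechanical_energy,
    rk4_step,
    simulate_batch,
    simulate_trial,
)

P_MEDIUM = SystemParams(pendulum_length=0.6)


class TestAccelerations:
    def test_equilibrium_is_fixed_point(self):
        xdd, thdd = accelerations((0, 0, 0.0, 0.0), P_MEDIUM, 0.0)
        assert xdd == 0.0 and thdd == 0.0

    def test_pure_force_at_bottom(self):
        # at theta=0 the coupled denominator is mc alone, not mc+mb
        xdd, thdd = accelerations((0, 0, 0.0, 0.0), P_MEDIUM, 3.0)
        assert xdd == pytest.approx(3.0 / 2.4, rel=1e-12)
        assert thdd == pytest.approx(-(3.0 / 2.4) / 0.6, rel=1e-12)
        assert thdd == pytest.approx(-2.0833, abs=1e-4)

    def test_horizontal_ball_decouples(self):
        # sin*cos vanishes at 90 deg: cart stays, ball falls at g/l
        xdd, thdd = accelerations((0, 0, math.pi / 2, 0.0), P_MEDIUM, 0.0)
        assert xdd == pytest.approx(0.0, abs=1e-12)
        assert thdd == pytest.approx(-9.81 / 0.6, rel=1e-12)

    @given(
        th=st.floats(-math.pi, math.pi),
        om=st.floats(-10, 10),
        F=st.floats(-50, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_solved_form_satisfies_implicit_equations(self, th, om, F):
        """The returned pair must satisfy both coupled equations exactly."""
        p = P_MEDIUM
        xdd, thdd = accelerations((0, 0, th, om), p, F)
        lhs1 = (p.cup_mass + p.ball_mass) * xdd
        rhs1 = p.ball_mass * p.pendulum_length * (
            om**2 * math.sin(th) - thdd * math.cos(th)
        ) + F
        assert lhs1 == pytest.approx(rhs1, abs=1e-9)
        assert thdd == pytest.approx(
            -xdd * math.cos(th) / p.pendulum_length
            - p.gravity * math.sin(th) / p.pendulum_length,
            abs=1e-9,
        )

    @given(
        th=st.floats(-math.pi, math.pi),
        om=st.floats(-10, 10),
        F=st.floats(-50, 50),
    )
    @settings(max_examples=30, deadline=None)
    def test_odd_symmetry(self, th, om, F):
        a = accelerations((0, 0, th, om), P_MEDIUM, F)
        b = accelerations((0, 0, -th, -om), P_MEDIUM, -F)
        assert a[0] == pytest.approx(-b[0], abs=1e-10)
        assert a[1] == pytest.approx(-b[1], abs=1e-10)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            accelerations((0, 0, math.nan, 0.0), P_MEDIUM, 0.0)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            SystemParams(cup_mass=-1.0)
        with pytest.raises(ValueError):
            SystemParams(rim_angle=2.0)


class TestImpedanceForce:
    def test_zero_on_desired_trajectory(self):
        ctrl = ControllerSpec(40, 70, 0.3, 0.5)
        st_ = CupBallState(ctrl.desired_position(0.3), ctrl.desired_velocity(0.3), 0, 0)
        assert impedance_force(st_, ctrl, 0.3) == pytest.approx(0.0, abs=1e-12)

    def test_restoring_spring_term(self):
        # cup 0.1 m ahead of the equilibrium trajectory: pulled back with 4 N
        ctrl = ControllerSpec(40, 70, 0.3, 0.5)
        st_ = CupBallState(ctrl.desired_position(0.0) + 0.1, ctrl.desired_velocity(0.0), 0, 0)
        assert impedance_force(st_, ctrl, 0.0) == pytest.approx(-4.0, rel=1e-12)

    def test_restoring_damper_term(self):
        ctrl = ControllerSpec(0, 70, 0.3, 0.5)
        st_ = CupBallState(0.0, ctrl.desired_velocity(0.0) - 0.2, 0, 0)
        assert impedance_force(st_, ctrl, 0.0) == pytest.approx(14.0, rel=1e-12)


class TestRK4:
    def test_equilibrium_unchanged(self):
        s0 = CupBallState(0, 0, 0, 0)
        s1 = rk4_step(s0, P_MEDIUM, lambda s, t: 0.0, 0.0, 0.01)
        assert s1 == s0

    def test_small_angle_period_with_cart_recoil(self):
        """Free oscillation period is 2 pi sqrt(l/g) shortened by the cart
        recoil factor sqrt(mc/(mc+mb))."""
        p = P_MEDIUM
        expected = (
            2 * math.pi
            * math.sqrt(p.pendulum_length / p.gravity)
            * math.sqrt(p.cup_mass / (p.cup_mass + p.ball_mass))
        )
        dt = 1e-3
        s = CupBallState(0, 0, math.radians(2.0), 0.0)
        crossings = []
        prev = s.ball_angle
        for i in range(int(8.0 / dt)):
            s = rk4_step(s, p, lambda st_, t: 0.0, i * dt, dt)
            if prev > 0 >= s.ball_angle:
                frac = prev / (prev - s.ball_angle)
                crossings.append((i + frac) * dt)
            prev = s.ball_angle
        periods = np.diff(crossings)
        assert np.mean(periods) == pytest.approx(expected, rel=1e-3)

    def test_fourth_order_convergence(self):
        """Halving dt shrinks the one-period state error ~16x."""
        p = P_MEDIUM
        ctrl = ControllerSpec(40, 70, 0.3, 0.5)

        def integrate(dt, T=2.0):
            s = CupBallState(-0.3, 0.0, math.radians(20), 0.0)
            n = int(round(T / dt))
            for i in range(n):
                s = rk4_step(s, p, lambda st_, t: impedance_force(st_, ctrl, t), i * dt, dt)
            return s.as_array()

        ref = integrate(0.0004)
        e1 = np.linalg.norm(integrate(0.04) - ref)
        e2 = np.linalg.norm(integrate(0.02) - ref)
        assert 8 < e1 / e2 < 32

    def test_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            rk4_step(CupBallState(0, 0, 0, 0), P_MEDIUM, lambda s, t: 0.0, 0.0, 0.0)


class TestSimulateTrial:
    def test_rest_stays_at_rest(self):
        ctrl = ControllerSpec(40, 70, 0.0, 0.5)
        traj = simulate_trial(P_MEDIUM, ctrl, 0.0, 0.0, duration=2.0)
        assert np.allclose(traj.cup_position, 0.0, atol=1e-12)
        assert np.allclose(traj.ball_angle, 0.0, atol=1e-12)
        assert np.allclose(traj.applied_force, 0.0, atol=1e-12)

    def test_energy_conserved_without_forcing(self):
        """Unforced cart-pendulum conserves mechanical energy to <0.1%
        over 15 s at the 10 ms production step."""
        ctrl = ControllerSpec(0.0, 0.0, 0.0, 0.5)
        traj = simulate_trial(P_MEDIUM, ctrl, math.radians(30), 0.0)
        E = mechanical_energy(traj, P_MEDIUM)
        assert np.max(np.abs(E - E[0])) < 1e-3 * E[0]

    def test_force_balance_recoverable(self):
        """(mc+mb) xdd - F_applied equals the ball reaction force implied
        by the ball states, to integration accuracy."""
        p = P_MEDIUM
        ctrl = ControllerSpec(40, 70, 0.3, 0.5)
        traj = simulate_trial(p, ctrl, math.radians(-25))
        dt = traj.dt
        xdd = np.gradient(traj.cup_velocity, dt)
        th, om = traj.ball_angle, traj.ball_angular_velocity
        thdd = np.gradient(om, dt)
        f_ball = p.ball_mass * p.pendulum_length * (om**2 * np.sin(th) - thdd * np.cos(th))
        resid = (p.cup_mass + p.ball_mass) * xdd - traj.applied_force - f_ball
        # finite-difference accelerations dominate the residual; interior only
        assert np.max(np.abs(resid[5:-5])) < 0.05 * np.max(np.abs(traj.applied_force))

    def test_worked_example_circular_variance(self):
        """Medium pendulum at the box-scale amplitude: theta0=+25 deg,
        omega0=-4 deg/s under the mirrored phase convention is the stable
        in-phase strategy with relative-phase variability ~0.01."""
        from cupball.metrics import relative_phase_variability

        ctrl = ControllerSpec(40, 70, 0.15, 0.5, phase_sign=+1)
        traj = simulate_trial(P_MEDIUM, ctrl, math.radians(25), math.radians(-4))
        res = relative_phase_variability(traj.cup_position, traj.ball_angle, traj.dt)
        assert res.circular_variance == pytest.approx(0.012, abs=0.005)

    def test_divergence_reported_with_step(self):
        # a stiffness far beyond the 10 ms RK4 stability limit explodes;
        # the error must name the failing step
        with pytest.raises(DivergenceError, match="step"):
            simulate_trial(
                P_MEDIUM, ControllerSpec(1e7, 0.0, 0.3, 0.5), 0.1, 0.0, duration=2.0
            )

    def test_batch_matches_scalar_path(self):
        ctrl = ControllerSpec(40, 70, 0.3, 0.7)
        traj = simulate_trial(P_MEDIUM, ctrl, math.radians(-30), duration=5.0)
        out = simulate_batch(
            P_MEDIUM, 40, 70, 0.3, np.array([0.7]), np.array([math.radians(-30)]),
            duration=5.0,
        )
        assert np.allclose(out["x"][:, 0], traj.cup_position, atol=1e-12)
        assert np.allclose(out["theta"][:, 0], traj.ball_angle, atol=1e-12)
        assert np.allclose(out["force"][:, 0], traj.applied_force, atol=1e-12)
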