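"""Hilbert-phase machinery, per-trial measures and stage timing."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cupball import metrics
from cupball.dynamics import ControllerSpec, SystemParams, Trajectory, simulate_trial

P_MEDIUM = SystemParams(pendulum_length=0.6)
DT = 0.01
# 8 whole cycles at 0.5 Hz: integer cycle counts avoid spectral leakage in
# the closed-form phase checks
T15 = np.arange(0, 16.0, DT)


class TestInstantaneousPhase:
    def test_cosine_phase_slope(self):
        sig = np.cos(2 * np.pi * 0.5 * T15)
        ps = metrics.instantaneous_phase(sig, DT)
        k = 200  # one nominal period of edge
        slope = np.polyfit(ps.time[k:-k], ps.phase[k:-k], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 0.5, rel=0.01)

    def test_quadrature_offset(self):
        c = np.cos(2 * np.pi * 0.5 * T15)
        s = np.sin(2 * np.pi * 0.5 * T15)
        pc = metrics.instantaneous_phase(c, DT).phase
        ps = metrics.instantaneous_phase(s, DT).phase
        diff = (pc - ps)[200:-200]
        assert np.allclose(diff, np.pi / 2, atol=0.02)

    def test_constant_signal_rejected(self):
        with pytest.raises(metrics.DegenerateSignalError):
            metrics.instantaneous_phase(np.zeros(100), DT)

    def test_offset_removed_before_transform(self):
        sig = np.cos(2 * np.pi * 0.5 * T15)
        a = metrics.instantaneous_phase(sig, DT).phase
        b = metrics.instantaneous_phase(sig + 5.0, DT).phase
        assert np.allclose(a, b, atol=1e-9)


class TestRelativePhase:
    def test_identical_signals_in_phase(self):
        sig = np.cos(2 * np.pi * 0.5 * T15)
        rp = metrics.relative_phase(sig, sig.copy(), DT)
        assert np.allclose(rp, 0.0, atol=1e-9)

    def test_negated_signal_anti_phase(self):
        sig = np.cos(2 * np.pi * 0.5 * T15)
        rp = metrics.relative_phase(sig, -sig, DT)
        assert np.allclose(np.abs(np.mod(rp[100:-100], 2 * np.pi)), np.pi, atol=0.05)

    def test_stable_simulated_trial_hovers_near_zero(self):
        ctrl = ControllerSpec(40, 70, 0.15, 0.5)
        traj = simulate_trial(P_MEDIUM, ctrl, math.radians(-25), math.radians(4))
        rp = metrics.relative_phase(traj.cup_position, traj.ball_angle, traj.dt)
        assert np.abs(np.median(rp)) < 0.3  # rad, i.e. well inside +/-20 deg

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            metrics.relative_phase(np.zeros(10), np.zeros(11), DT)


class TestCircularVariance:
    def test_concentrated(self):
        assert metrics.circular_variance(np.full(7, 1.234)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_equally_spaced_angles_maximally_spread(self, n):
        a = 2 * np.pi * np.arange(n) / n
        assert metrics.circular_variance(a) == pytest.approx(1.0, abs=1e-12)

    def test_right_angle_pair(self):
        # resultant of unit vectors at 0 and 90 deg has length sqrt(2)/2
        cv = metrics.circular_variance(np.radians([0.0, 90.0]))
        assert cv == pytest.approx(1 - math.sqrt(2) / 2, abs=1e-12)

    @given(
        angles=st.lists(st.floats(-10, 10), min_size=1, max_size=40),
        rot=st.floats(-10, 10),
    )
    @settings(max_examples=60, deadline=None)
    def test_rotation_and_permutation_invariance(self, angles, rot):
        a = np.array(angles)
        base = metrics.circular_variance(a)
        assert metrics.circular_variance(a + rot) == pytest.approx(base, abs=1e-9)
        assert metrics.circular_variance(a[::-1]) == pytest.approx(base, abs=1e-12)
        assert 0.0 <= base <= 1.0 + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            metrics.circular_variance([])


class TestInstantaneousFrequency:
    def test_pure_tone(self):
        sig = np.cos(2 * np.pi * 0.5 * T15)
        f = metrics.instantaneous_frequency(sig, DT, freq_hint=0.5)
        assert np.all(np.abs(f - 0.5) < 0.005)

    def test_chirp_monotone(self):
        # 0.3 -> 0.7 Hz linear chirp: interior estimate rises monotonically
        t = T15
        f0, f1 = 0.3, 0.7
        phase = 2 * np.pi * (f0 * t + (f1 - f0) * t**2 / (2 * t[-1]))
        f = metrics.instantaneous_frequency(np.cos(phase), DT, trim_seconds=2.0)
        smooth = np.convolve(f, np.ones(25) / 25, mode="valid")
        assert np.all(np.diff(smooth) > -5e-4)  # monotone up to edge ripple
        assert f[0] < 0.45 and f[-1] > 0.55

    def test_controller_tracks_desired_rhythm(self):
        """Steady-state cup frequency matches the desired frequency to 2%."""
        ctrl = ControllerSpec(40, 70, 0.3, 0.5)
        traj = simulate_trial(P_MEDIUM, ctrl, math.radians(-25))
        f = metrics.instantaneous_frequency(traj.cup_position, traj.dt, freq_hint=0.5)
        assert np.mean(f) == pytest.approx(0.5, rel=0.02)

    def test_constant_rejected(self):
        with pytest.raises(metrics.DegenerateSignalError):
            metrics.instantaneous_frequency(np.ones(100), DT)


class TestForceMetrics:
    def test_mean_absolute_force_constant(self):
        assert metrics.mean_absolute_force(np.full(50, 2.0)) == 2.0
        assert metrics.mean_absolute_force(np.zeros(50)) == 0.0

    def test_mean_absolute_force_sinusoid(self):
        t = np.arange(0, 10, 0.001)
        F = 5 * np.sin(2 * np.pi * 0.5 * t)
        assert metrics.mean_absolute_force(F) == pytest.approx(10 / np.pi, rel=1e-3)

    def test_ldj_scale_invariance(self):
        rng = np.random.default_rng(0)
        F = np.cumsum(rng.normal(size=500))
        a = metrics.log_dimensionless_jerk(F, DT)
        assert metrics.log_dimensionless_jerk(17.3 * F, DT) == pytest.approx(a, abs=1e-9)

    def test_ldj_time_reversal_invariance(self):
        rng = np.random.default_rng(1)
        F = np.cumsum(rng.normal(size=500))
        a = metrics.log_dimensionless_jerk(F, DT)
        assert metrics.log_dimensionless_jerk(F[::-1], DT) == pytest.approx(a, abs=1e-9)

    def test_ldj_sinusoid_closed_form(self):
        # integral of Fddot^2 over whole cycles is (2 pi f)^4 T / 2
        f0, T = 0.5, 10.0
        t = np.arange(0, T, DT)
        F = np.sin(2 * np.pi * f0 * t)
        expected = -math.log(T**4 * (2 * np.pi * f0) ** 4 / 2)
        got = metrics.log_dimensionless_jerk(F, DT)
        assert got == pytest.approx(expected, rel=0.01)

    def test_ldj_noise_reduces_smoothness(self):
        t = np.arange(0, 10, DT)
        F = np.sin(2 * np.pi * 0.5 * t)
        noisy = F + np.random.default_rng(2).normal(0, 0.05, len(F))
        assert metrics.log_dimensionless_jerk(noisy, DT) < metrics.log_dimensionless_jerk(F, DT)

    def test_ldj_zero_force_rejected(self):
        with pytest.raises(ValueError):
            metrics.log_dimensionless_jerk(np.zeros(50), DT)


class TestRisk:
    def test_ball_at_rest_at_bottom(self):
        n = 100
        r = metrics.risk_of_escape(np.zeros(n), np.zeros(n), P_MEDIUM, DT)
        assert r.risk == pytest.approx(0.0, abs=1e-12)
        assert r.escape_energy == pytest.approx(
            0.6 * 9.81 * 0.6 * (1 - math.cos(math.radians(60)))
        )

    def test_ball_resting_at_rim(self):
        th = np.full(100, P_MEDIUM.rim_angle)
        r = metrics.risk_of_escape(th, np.zeros(100), P_MEDIUM, DT)
        assert r.risk == pytest.approx(1.0, abs=1e-12)

    def test_half_escape_energy(self):
        # pick omega so kinetic energy alone is half the escape energy
        e_esc = 0.6 * 9.81 * 0.6 * (1 - math.cos(math.radians(60)))
        om = math.sqrt(e_esc / (0.6 * 0.6**2))
        r = metrics.risk_of_escape(np.zeros(100), np.full(100, om), P_MEDIUM, DT)
        assert r.risk == pytest.approx(0.5, abs=1e-12)

    def test_time_reversal_invariance(self):
        rng = np.random.default_rng(3)
        th = rng.uniform(-0.5, 0.5, 200)
        om = rng.uniform(-1, 1, 200)
        a = metrics.risk_of_escape(th, om, P_MEDIUM, DT).risk
        b = metrics.risk_of_escape(th[::-1], om[::-1], P_MEDIUM, DT).risk
        assert a == pytest.approx(b, abs=1e-12)


def _make_two_stage_trial(
    prep_s=4.0, fs=120.0, noisy_until=None, rhythmic_s=5.0, seed=0
) -> Trajectory:
    """Prep: small jiggle ending at rest; rhythmic: sweep into the right box.

    Relative phase is noisy until ``noisy_until`` (s) and locked after.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs
    n_prep = int(prep_s * fs)
    t_p = np.arange(n_prep) * dt
    f_j = 1.0
    n_cyc = round(f_j * prep_s)
    w_p = 2 * np.pi * n_cyc / prep_s
    phase = w_p * (t_p - t_p[-1])
    x_p = -0.15 + 0.04 * (np.cos(phase) - 1) / 2
    v_p = -0.02 * w_p * np.sin(phase)
    if noisy_until is None:
        rel = np.zeros(n_prep)
    else:
        k = int(noisy_until * fs)
        rel = np.zeros(n_prep)
        rel[:k] = np.cumsum(rng.normal(0, 0.25, k)) + rng.uniform(0, 2 * np.pi)
    th_p = np.radians(15.0) * np.cos(phase - rel)
    n_r = int(rhythmic_s * fs)
    t_r = np.arange(n_r) * dt
    w_r = 2 * np.pi * 0.5
    x_r = -0.15 * np.cos(w_r * t_r)
    v_r = 0.15 * w_r * np.sin(w_r * t_r)
    th_r = np.radians(15.0) * np.cos(w_r * t_r)
    x = np.concatenate([x_p, x_r])
    v = np.concatenate([v_p, v_r])  # analytic: junction sample has v = 0
    th = np.concatenate([th_p, th_r])
    t = np.arange(len(x)) * dt
    om = np.gradient(th, dt)
    return Trajectory(
        time=t, cup_position=x, cup_velocity=v, ball_angle=th,
        ball_angular_velocity=om, applied_force=np.zeros_like(x),
        stage_boundary_index=n_prep, params=P_MEDIUM,
    )


class TestStageParsing:
    def test_boundary_at_junction_velocity_zero(self):
        traj = _make_two_stage_trial()
        b = metrics.parse_stages(traj)
        assert abs(b - traj.stage_boundary_index) <= 2

    def test_never_reaching_box_rejected(self):
        n = 200
        t = np.arange(n) / 120.0
        x = -0.2 + 0.01 * np.sin(2 * np.pi * t)
        traj = Trajectory(t, x, np.gradient(x, t), np.zeros(n), np.zeros(n), np.zeros(n))
        with pytest.raises(metrics.BoundaryNotFoundError):
            metrics.parse_stages(traj)

    def test_monotone_motion_has_no_boundary(self):
        n = 200
        t = np.arange(n) / 120.0
        x = -0.3 + 0.5 * t / t[-1]
        v = np.full(n, 0.5 / t[-1])
        traj = Trajectory(t, x, v, np.zeros(n), np.zeros(n), np.zeros(n))
        with pytest.raises(metrics.BoundaryNotFoundError):
            metrics.parse_stages(traj)

    def test_preparation_duration(self):
        traj = _make_two_stage_trial(prep_s=4.0)
        assert metrics.preparation_duration(traj) == pytest.approx(4.0, abs=0.02)
        traj0 = _make_two_stage_trial(prep_s=1.0)
        traj0.stage_boundary_index = 0
        assert metrics.preparation_duration(traj0) == 0.0


class TestTimeToStablePhase:
    def test_locked_throughout_is_stable_from_start(self):
        traj = _make_two_stage_trial(noisy_until=None)
        tts, flag = metrics.time_to_stable_phase(traj)
        assert flag is True and tts == 0.0

    def test_noisy_then_locked_recovers_transition(self):
        traj = _make_two_stage_trial(prep_s=6.0, noisy_until=3.0, seed=4)
        tts, flag = metrics.time_to_stable_phase(traj)
        assert flag is False
        assert tts == pytest.approx(3.0, abs=0.6)

    def test_threshold_one_never_exceeded(self):
        traj = _make_two_stage_trial(noisy_until=2.0)
        tts, flag = metrics.time_to_stable_phase(traj, threshold=1.0)
        assert flag is True and tts == 0.0

    def test_short_preparation_rejected(self):
        traj = _make_two_stage_trial(prep_s=0.3)
        traj.stage_boundary_index = 10
        with pytest.raises(ValueError):
            metrics.time_to_stable_phase(traj)


class TestPhaseTransitionAcrossResonance:
    def test_in_phase_below_and_anti_phase_above_resonance(self):
        """Medium pendulum: relative phase concentrates near 0 for slow
        driving and near pi for fast driving (coupled resonance ~0.51 Hz)."""
        lo = simulate_trial(P_MEDIUM, ControllerSpec(40, 70, 0.3, 0.35), math.radians(-25))
        hi = simulate_trial(P_MEDIUM, ControllerSpec(40, 70, 0.3, 0.85), math.radians(30))
        rp_lo = metrics.relative_phase(lo.cup_position, lo.ball_angle, lo.dt)[200:-200]
        rp_hi = metrics.relative_phase(hi.cup_position, hi.ball_angle, hi.dt)[200:-200]
        mean_lo = np.angle(np.exp(1j * rp_lo).mean())
        mean_hi = np.angle(np.exp(1j * rp_hi).mean())
        assert abs(mean_lo) < 0.5
        assert abs(abs(mean_hi) - np.pi) < 0.5
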