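"""Cart-pendulum plant, impedance controller, and fixed-step RK4 simulation.

The cup-and-ball object is a cart of mass ``mc`` translating in 1-D with a
pendulum (ball) of mass ``mb`` on a massless rod of length ``l``.  With the
cup position ``x`` and ball angle ``theta`` (0 = bottom of the cup,
counter-clockwise positive) the coupled equations of motion are

    (mc + mb) x'' = mb l (theta'^2 sin(theta) - theta'' cos(theta)) + F
    theta''       = -x'' cos(theta)/l - g sin(theta)/l

which are mutually implicit in (x'', theta'').  Solving them simultaneously
gives the closed form used everywhere in this package:

    x''     = [mb (l w^2 sin(t) + g sin(t) cos(t)) + F] / (mc + mb sin^2(t))
    theta'' = -x'' cos(t)/l - g sin(t)/l

The denominator is bounded below by ``mc`` so the accelerations are finite
for every finite state.

The hand is modelled as a first-order impedance controller tracking a
sinusoidal equilibrium trajectory x_d(t) = -A cos(2 pi f t):

    F = K (x - x_d) + B (x' - x'_d)

Angles are radians internally; every external interface (files, CLI)
speaks degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SystemParams",
    "CupBallState",
    "ControllerSpec",
    "Trajectory",
    "accelerations",
    "impedance_force",
    "rk4_step",
    "simulate_trial",
    "simulate_batch",
    "mechanical_energy",
    "DivergenceError",
    "PENDULUM_LENGTHS",
]

#: Short / medium / long pendulum conditions (m).
PENDULUM_LENGTHS = {"short": 0.3, "medium": 0.6, "long": 1.2}


class DivergenceError(RuntimeError):
    """Raised when integration produces a non-finite state."""


@dataclass(frozen=True)
class SystemParams:
    """Physical constants of the cup-ball / cart-pendulum plant.

    Parameters
    ----------
    cup_mass : float
        Cart (cup) mass mc in kg.
    ball_mass : float
        Pendulum bob (ball) mass mb in kg.
    pendulum_length : float
        Rod length l in m; the named conditions are short 0.3, medium 0.6,
        long 1.2.
    gravity : float
        Gravitational acceleration g in m/s^2.
    rim_angle : float
        Cup rim half-angle in radians; the ball escapes beyond it.
    """

    cup_mass: float = 2.4
    ball_mass: float = 0.6
    pendulum_length: float = 0.6
    gravity: float = 9.81
    rim_angle: float = math.radians(60.0)

    def __post_init__(self) -> None:
        for name in ("cup_mass", "ball_mass", "pendulum_length", "gravity", "rim_angle"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not (0 < self.rim_angle <= math.pi / 2):
            raise ValueError("rim_angle must lie in (0, pi/2]")

    def with_length(self, pendulum_length: float) -> "SystemParams":
        return replace(self, pendulum_length=pendulum_length)


@dataclass(frozen=True)
class CupBallState:
    """Instantaneous state: cup position/velocity, ball angle/angular velocity.

    Angle and angular velocity are radians and rad/s.
    """

    cup_position: float
    cup_velocity: float
    ball_angle: float
    ball_angular_velocity: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.cup_position, self.cup_velocity, self.ball_angle, self.ball_angular_velocity]
        )

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "CupBallState":
        x, v, th, om = arr
        return cls(float(x), float(v), float(th), float(om))


@dataclass(frozen=True)
class ControllerSpec:
    """First-order impedance controller tracking a sinusoidal equilibrium
    trajectory x_d(t) = phase_sign * A cos(2 pi f t).

    The controller is restoring: it pulls the cup toward the equilibrium
    trajectory with a spring K and damper B, F = K (x_d - x) + B (v_d - v).

    Parameters
    ----------
    stiffness : float
        K in N/m (>= 0).  Landscape sweeps hold K = 40.
    damping : float
        B in N s/m (>= 0).  Landscape sweeps hold B = 70.
    desired_amplitude : float
        A in m.  Landscape sweeps use the default 0.3 m; the single-trial
        worked example and the cohort generator use 0.15 m, the
        half-excursion matching the +/-0.15 m target boxes.
    desired_frequency : float
        f in Hz (> 0).
    phase_sign : int
        -1 (default): x_d = -A cos, the cup starts on the left;
        +1: the mirror-image convention starting on the right.
    """

    stiffness: float = 40.0
    damping: float = 70.0
    desired_amplitude: float = 0.3
    desired_frequency: float = 0.5
    phase_sign: int = -1

    def __post_init__(self) -> None:
        if self.stiffness < 0 or self.damping < 0:
            raise ValueError("stiffness and damping must be >= 0")
        if not self.desired_frequency > 0:
            raise ValueError("desired_frequency must be > 0")
        if self.phase_sign not in (-1, 1):
            raise ValueError("phase_sign must be -1 or +1")

    def desired_position(self, t):
        return self.phase_sign * self.desired_amplitude * np.cos(
            2 * np.pi * self.desired_frequency * t
        )

    def desired_velocity(self, t):
        w = 2 * np.pi * self.desired_frequency
        return -self.phase_sign * self.desired_amplitude * w * np.sin(w * t)


@dataclass
class Trajectory:
    """Uniformly sampled cup/ball state and applied-force series.

    ``stage_boundary_index`` marks the preparation -> rhythmic transition
    (0 for rhythmic-only trajectories).  Angle columns are radians in
    memory; file writers convert to degrees.
    """

    time: np.ndarray
    cup_position: np.ndarray
    cup_velocity: np.ndarray
    ball_angle: np.ndarray
    ball_angular_velocity: np.ndarray
    applied_force: np.ndarray
    stage_boundary_index: int = 0
    params: SystemParams | None = None
    controller: ControllerSpec | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in (
            "cup_position",
            "cup_velocity",
            "ball_angle",
            "ball_angular_velocity",
            "applied_force",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != time length {n}")
        self.time = np.asarray(self.time, dtype=float)
        if n >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("time grid must be uniform")
        if not 0 <= self.stage_boundary_index < max(n, 1):
            raise ValueError("stage_boundary_index out of range")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def rhythmic(self) -> "Trajectory":
        """The rhythmic-stage slice (from the stage boundary onward)."""
        i = self.stage_boundary_index
        if i == 0:
            return self
        return Trajectory(
            time=self.time[i:],
            cup_position=self.cup_position[i:],
            cup_velocity=self.cup_velocity[i:],
            ball_angle=self.ball_angle[i:],
            ball_angular_velocity=self.ball_angular_velocity[i:],
            applied_force=self.applied_force[i:],
            stage_boundary_index=0,
            params=self.params,
            controller=self.controller,
        )


def accelerations(state, params: SystemParams, applied_force):
    """Simultaneously solved cart and ball accelerations.

    Accepts a :class:`CupBallState` or a ``(x, v, theta, omega)`` tuple of
    scalars/arrays; broadcasting over arrays is supported so that sweeps can
    integrate whole grids at once.

    Returns
    -------
    (cup_acceleration, ball_angular_acceleration)
        m/s^2 and rad/s^2.
    """
    if isinstance(state, CupBallState):
        theta, omega = state.ball_angle, state.ball_angular_velocity
    else:
        _, _, theta, omega = state
    mc, mb = params.cup_mass, params.ball_mass
    l, g = params.pendulum_length, params.gravity
    F = applied_force
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(omega)) and np.all(np.isfinite(F))):
        raise ValueError("non-finite state or force")
    s, c = np.sin(theta), np.cos(theta)
    xdd = (mb * (l * omega**2 * s + g * s * c) + F) / (mc + mb * s**2)
    thdd = -xdd * c / l - g * s / l
    return xdd, thdd


def impedance_force(state, ctrl: ControllerSpec, t):
    """Restoring controller force F = K (x_d - x) + B (v_d - v) at time ``t``.

    The sign convention makes the hand a spring-damper pulling the cup
    toward the equilibrium trajectory; with the cup ahead of x_d the force
    is negative (pulling back).
    """
    if isinstance(state, CupBallState):
        x, v = state.cup_position, state.cup_velocity
    else:
        x, v = state[0], state[1]
    return ctrl.stiffness * (ctrl.desired_position(t) - x) + ctrl.damping * (
        ctrl.desired_velocity(t) - v
    )


def _rhs(y, params, F):
    x, v, th, om = y
    xdd, thdd = accelerations((x, v, th, om), params, F)
    return np.array([v, xdd, om, thdd]) if isinstance(v, np.ndarray) else (v, xdd, om, thdd)


def rk4_step(
    state: CupBallState,
    params: SystemParams,
    force_fn: Callable[[CupBallState, float], float],
    t: float,
    dt: float,
) -> CupBallState:
    """One classic 4-stage Runge-Kutta update of (x, v, theta, omega).

    ``force_fn(state, time)`` supplies the applied force and is evaluated at
    the stage times t, t+dt/2, t+dt.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")

    def f(y, tt):
        st = CupBallState(*y)
        F = force_fn(st, tt)
        xdd, thdd = accelerations(st, params, F)
        return np.array([y[1], xdd, y[3], thdd])

    y0 = state.as_array()
    k1 = f(y0, t)
    k2 = f(y0 + 0.5 * dt * k1, t + 0.5 * dt)
    k3 = f(y0 + 0.5 * dt * k2, t + 0.5 * dt)
    k4 = f(y0 + dt * k3, t + dt)
    return CupBallState.from_array(y0 + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4))


def simulate_trial(
    params: SystemParams,
    ctrl: ControllerSpec,
    theta0: float,
    omega0: float = math.radians(-4.0),
    duration: float = 15.0,
    dt: float = 0.01,
) -> Trajectory:
    """Forward-simulate one rhythmic trial under the impedance controller.

    The cup starts on the desired trajectory with zero error
    (x0 = x_d(0) = -A, v0 = 0) so there is no initial force transient; the
    ball starts at ``theta0`` (rad) with angular velocity ``omega0``
    (default -4 deg/s).  Fixed-step RK4 at ``dt`` (default 10 ms) for
    ``duration`` seconds (default 15 s).

    Raises
    ------
    DivergenceError
        If the state becomes non-finite, naming the failing step.
    """
    if not duration > 0 or not dt > 0:
        raise ValueError("duration and dt must be > 0")
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    K, B, A = ctrl.stiffness, ctrl.damping, ctrl.desired_amplitude
    sp = ctrl.phase_sign
    w = 2 * math.pi * ctrl.desired_frequency
    mc, mb = params.cup_mass, params.ball_mass
    l, g = params.pendulum_length, params.gravity

    # scalar inner loop: plain floats are markedly faster than ndarray ops here
    def deriv(x, v, th, om, tt):
        xd = sp * A * math.cos(w * tt)
        vd = -sp * A * w * math.sin(w * tt)
        F = K * (xd - x) + B * (vd - v)
        s, c = math.sin(th), math.cos(th)
        xdd = (mb * (l * om * om * s + g * s * c) + F) / (mc + mb * s * s)
        return v, xdd, om, -xdd * c / l - g * s / l

    xs = np.empty(n)
    vs = np.empty(n)
    ths = np.empty(n)
    oms = np.empty(n)
    Fs = np.empty(n)
    x, v = sp * A, 0.0
    th, om = float(theta0), float(omega0)
    for i in range(n):
        tt = t[i]
        xs[i], vs[i], ths[i], oms[i] = x, v, th, om
        Fs[i] = K * (sp * A * math.cos(w * tt) - x) + B * (-sp * A * w * math.sin(w * tt) - v)
        if i == n - 1:
            break
        k1 = deriv(x, v, th, om, tt)
        k2 = deriv(
            x + 0.5 * dt * k1[0], v + 0.5 * dt * k1[1],
            th + 0.5 * dt * k1[2], om + 0.5 * dt * k1[3], tt + 0.5 * dt,
        )
        k3 = deriv(
            x + 0.5 * dt * k2[0], v + 0.5 * dt * k2[1],
            th + 0.5 * dt * k2[2], om + 0.5 * dt * k2[3], tt + 0.5 * dt,
        )
        k4 = deriv(
            x + dt * k3[0], v + dt * k3[1], th + dt * k3[2], om + dt * k3[3], tt + dt
        )
        x += (dt / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        v += (dt / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        th += (dt / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        om += (dt / 6.0) * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        if not (
            math.isfinite(x) and math.isfinite(v) and math.isfinite(th) and math.isfinite(om)
        ):
            raise DivergenceError(f"state became non-finite at step {i + 1} (t={tt + dt:.3f} s)")

    return Trajectory(
        time=t,
        cup_position=xs,
        cup_velocity=vs,
        ball_angle=ths,
        ball_angular_velocity=oms,
        applied_force=Fs,
        stage_boundary_index=0,
        params=params,
        controller=ctrl,
    )


def simulate_batch(
    params: SystemParams,
    stiffness: float,
    damping: float,
    amplitude: float,
    frequencies: np.ndarray,
    theta0: np.ndarray,
    omega0: float = math.radians(-4.0),
    duration: float = 15.0,
    dt: float = 0.01,
    phase_sign: int = -1,
):
    """Vectorised RK4 of many trials at once (one per array element).

    ``frequencies`` and ``theta0`` broadcast against each other; every trial
    shares (K, B, A, omega0, duration, dt).  Used by the landscape sweeps,
    where integrating a whole grid simultaneously is orders of magnitude
    faster than a Python loop over cells.

    Returns
    -------
    dict of arrays
        time (n,), and x/v/theta/omega/force of shape (n,) + broadcast shape.
    """
    f = np.asarray(frequencies, dtype=float)
    th0 = np.asarray(theta0, dtype=float)
    f, th0 = np.broadcast_arrays(f, th0)
    shape = f.shape
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    w = 2 * np.pi * f
    mc, mb = params.cup_mass, params.ball_mass
    l, g = params.pendulum_length, params.gravity
    K, B, A = stiffness, damping, amplitude
    sp = phase_sign

    def deriv(x, v, th, om, tt):
        xd = sp * A * np.cos(w * tt)
        vd = -sp * A * w * np.sin(w * tt)
        F = K * (xd - x) + B * (vd - v)
        s, c = np.sin(th), np.cos(th)
        xdd = (mb * (l * om**2 * s + g * s * c) + F) / (mc + mb * s**2)
        return v, xdd, om, -xdd * c / l - g * s / l

    out = {k: np.empty((n,) + shape) for k in ("x", "v", "theta", "omega", "force")}
    x = np.full(shape, sp * A)
    v = np.zeros(shape)
    th = th0.copy()
    om = np.full(shape, float(omega0))
    for i in range(n):
        tt = t[i]
        out["x"][i], out["v"][i], out["theta"][i], out["omega"][i] = x, v, th, om
        out["force"][i] = K * (sp * A * np.cos(w * tt) - x) + B * (
            -sp * A * w * np.sin(w * tt) - v
        )
        if i == n - 1:
            break
        k1 = deriv(x, v, th, om, tt)
        k2 = deriv(
            x + 0.5 * dt * k1[0], v + 0.5 * dt * k1[1],
            th + 0.5 * dt * k1[2], om + 0.5 * dt * k1[3], tt + 0.5 * dt,
        )
        k3 = deriv(
            x + 0.5 * dt * k2[0], v + 0.5 * dt * k2[1],
            th + 0.5 * dt * k2[2], om + 0.5 * dt * k2[3], tt + 0.5 * dt,
        )
        k4 = deriv(x + dt * k3[0], v + dt * k3[1], th + dt * k3[2], om + dt * k3[3], tt + dt)
        x = x + (dt / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        v = v + (dt / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        th = th + (dt / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        om = om + (dt / 6.0) * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
    out["time"] = t
    return out


def mechanical_energy(traj_or_state, params: SystemParams):
    """Total mechanical energy of cart + ball.

    E = 1/2 (mc+mb) v^2 + mb l v w cos(theta) + 1/2 mb l^2 w^2
        + mb g l (1 - cos(theta))

    Conserved when no external force acts; used as an integration oracle.
    """
    if isinstance(traj_or_state, Trajectory):
        v = traj_or_state.cup_velocity
        th = traj_or_state.ball_angle
        om = traj_or_state.ball_angular_velocity
    elif isinstance(traj_or_state, CupBallState):
        v, th, om = (
            traj_or_state.cup_velocity,
            traj_or_state.ball_angle,
            traj_or_state.ball_angular_velocity,
        )
    else:
        _, v, th, om = traj_or_state
    mc, mb = params.cup_mass, params.ball_mass
    l, g = params.pendulum_length, params.gravity
    return (
        0.5 * (mc + mb) * np.asarray(v) ** 2
        + mb * l * np.asarray(v) * np.asarray(om) * np.cos(th)
        + 0.5 * mb * l**2 * np.asarray(om) ** 2
        + mb * g * l * (1 - np.cos(th))
    )
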