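"""Stochastic open-loop optimal control of the cup-ball system.

Trial-to-trial uncertainty about the pendulum length is modelled by making
the length a state variable driven by an Ornstein-Uhlenbeck process with
reversion rate ``alpha`` and diffusion ``sigma_ou``, whose stationary
variance is sigma_l^2 = sigma_ou^2 / (2 alpha).  The hand is an impedance
controller with time-varying stiffness K(t) (damping proportional via
k_b = 0.2) plus a feedforward force F_ff(t):

    F_applied = K (x_d - x) + k_b K (v_d - v) + F_ff

To keep the physical profiles smooth, the second derivatives of K and F_ff
act as pseudo-controls; K, F_ff and their first derivatives are augmented
into a 9-dimensional state

    X = [x, v, theta, omega, l, F_ff, K, F_ff_dot, K_dot]

The open-loop planning problem propagates the mean ``m`` and covariance
``P`` of X through the (linearised) stochastic dynamics,

    m' = f(m, u),   P' = F P + P F^T + G G^T,   F = df/dX |_(m,u)

and minimises a quadratic cost on tracking error, state covariance
(variance of cup position/velocity is penalised wherever accuracy is
demanded) and control effort, by direct transcription: the pseudo-controls
are piecewise-constant on a coarse grid and optimised with SLSQP.  Raising
the length uncertainty makes co-contraction (higher K) worth its effort
cost, which is the model's account of elevated grip force in the random
protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

try:  # jitted propagation core; the pure-Python path is the reference
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "UncertaintySpec",
    "SOOCConfig",
    "OptimalSolution",
    "drift",
    "jacobian",
    "mean_cov_rhs",
    "propagate",
    "stage_cost",
    "terminal_cost",
    "trajectory_cost",
    "optimize",
    "sweep_sooc",
    "simulate_sde_paths",
    "discrete_length_stats",
]

# state indices
IX, IV, ITH, IOM, IL, IFF, IK, IDFF, IDK = range(9)


def discrete_length_stats(lengths=(0.3, 0.6, 1.2)) -> tuple[float, float]:
    """Mean and SD of the equiprobable discrete pendulum-length distribution.

    The random protocol draws the length uniformly from the three
    conditions, giving mean 0.7 m and SD 0.37 m.
    """
    a = np.asarray(lengths, dtype=float)
    return float(a.mean()), float(a.std())


@dataclass(frozen=True)
class UncertaintySpec:
    """Ornstein-Uhlenbeck uncertainty on the pendulum length.

    dl = -alpha (l - mean_length) dt + sigma_ou dW, with
    sigma_ou = length_sd * sqrt(2 alpha) so the stationary SD is
    ``length_sd``.
    """

    mean_length: float = 0.7
    length_sd: float = 0.37
    reversion_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.mean_length <= 0 or self.length_sd < 0 or self.reversion_rate <= 0:
            raise ValueError("invalid uncertainty parameters")

    @property
    def ou_sd(self) -> float:
        return self.length_sd * math.sqrt(2.0 * self.reversion_rate)

    @classmethod
    def random_protocol(cls) -> "UncertaintySpec":
        mean, _ = discrete_length_stats()
        return cls(mean_length=mean, length_sd=0.37)

    @classmethod
    def blocked_protocol(cls, pendulum_length: float) -> "UncertaintySpec":
        if pendulum_length not in (0.3, 0.6, 1.2):
            raise ValueError("blocked protocol lengths are 0.3, 0.6 or 1.2 m")
        return cls(mean_length=pendulum_length, length_sd=0.1)


@dataclass(frozen=True)
class SOOCConfig:
    """Problem definition and weights for one planning run.

    Durations in s, amplitude in m, frequency in Hz, target angle in rad.
    The weight fields follow the cost structure: ``q_pos``/``q_vel`` weight
    squared cup tracking error during the rhythmic stage, ``qv_pos``/
    ``qv_vel`` weight the cup position/velocity variances (the trace term),
    ``q_stiff`` prices holding stiffness (co-contraction effort),
    ``r_control`` prices the pseudo-controls, and ``w_prep`` is the large
    soft-constraint weight pinning (x, v, theta, omega) at the end of the
    preparation stage.
    """

    uncertainty: UncertaintySpec = field(default_factory=UncertaintySpec.random_protocol)
    damping_ratio: float = 0.2
    amplitude: float = 0.15
    frequency: float = 0.5
    theta_target: float = math.radians(-25.0)
    prep_duration: float = 2.0
    rhythmic_duration: float = 6.0
    dt: float = 0.01             # mean/covariance integration step
    control_dt: float = 0.5     # piecewise-constant pseudo-control interval
    cup_mass: float = 2.4
    ball_mass: float = 0.6
    gravity: float = 9.81
    q_pos: float = 200.0
    q_vel: float = 20.0
    qv_pos: float = 2000.0
    qv_vel: float = 200.0
    q_stiff: float = 2e-4
    r_control: float = 1e-6
    w_prep: float = 2e3
    k_init: float = 10.0

    def __post_init__(self) -> None:
        if self.prep_duration <= 0 or self.rhythmic_duration <= 0:
            raise ValueError("durations must be > 0")
        if self.r_control <= 0:
            raise ValueError("control weight must be positive definite")
        if min(self.q_pos, self.q_vel, self.qv_pos, self.qv_vel, self.q_stiff, self.w_prep) < 0:
            raise ValueError("weights must be non-negative")
        # control grid must tile the trial
        n = (self.prep_duration + self.rhythmic_duration) / self.control_dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("control_dt must divide the total duration")

    @property
    def total_duration(self) -> float:
        return self.prep_duration + self.rhythmic_duration

    def desired_cup(self, t: float) -> tuple[float, float]:
        """Desired cup position/velocity at trial time ``t``.

        During preparation the reference is held at the start-of-rhythm
        state (-A, 0); during the rhythmic stage it is the box-to-box
        sinusoid, phased to continue smoothly from -A.
        """
        A, f = self.amplitude, self.frequency
        if t < self.prep_duration:
            return -A, 0.0
        w = 2 * math.pi * f
        tr = t - self.prep_duration
        return -A * math.cos(w * tr), A * w * math.sin(w * tr)


@dataclass
class OptimalSolution:
    """Optimised SOOC trajectories and diagnostics."""

    config: SOOCConfig
    time: np.ndarray                # propagation grid
    mean: np.ndarray                # (n, 9)
    cov: np.ndarray                 # (n, 9, 9)
    controls: np.ndarray            # (n_intervals, 2) pseudo-controls [Kddot, Fddot]
    control_times: np.ndarray       # left edges of control intervals
    cost: float
    converged: bool
    message: str
    n_iter: int

    @property
    def stiffness(self) -> np.ndarray:
        return self.mean[:, IK]

    @property
    def feedforward_force(self) -> np.ndarray:
        return self.mean[:, IFF]

    def applied_force(self) -> np.ndarray:
        """Controller force along the mean trajectory."""
        cfg = self.config
        out = np.empty(len(self.time))
        for i, t in enumerate(self.time):
            xd, vd = cfg.desired_cup(t)
            m = self.mean[i]
            out[i] = m[IK] * (xd - m[IX]) + cfg.damping_ratio * m[IK] * (
                vd - m[IV]
            ) + m[IFF]
        return out

    def mean_rhythmic_stiffness(self) -> float:
        i = int(round(self.config.prep_duration / self.config.dt))
        return float(self.mean[i:, IK].mean())


def _applied_force(m: np.ndarray, xd: float, vd: float, kb: float) -> float:
    return m[IK] * (xd - m[IX]) + kb * m[IK] * (vd - m[IV]) + m[IFF]


def drift(m: np.ndarray, u: np.ndarray, cfg: SOOCConfig, t: float) -> np.ndarray:
    """Deterministic part of the 9-state dynamics at trial time ``t``."""
    mc, mb, g = cfg.cup_mass, cfg.ball_mass, cfg.gravity
    alpha = cfg.uncertainty.reversion_rate
    lmean = cfg.uncertainty.mean_length
    xd, vd = cfg.desired_cup(t)
    x, v, th, om, l = m[IX], m[IV], m[ITH], m[IOM], m[IL]
    F = _applied_force(m, xd, vd, cfg.damping_ratio)
    s, c = math.sin(th), math.cos(th)
    den = mc + mb * s * s
    vdot = (mb * (l * om * om * s + g * s * c) + F) / den
    return np.array(
        [
            v,
            vdot,
            om,
            -vdot * c / l - g * s / l,
            -alpha * (l - lmean),
            m[IDFF],
            m[IDK],
            u[1],
            u[0],
        ]
    )


def jacobian(m: np.ndarray, u: np.ndarray, cfg: SOOCConfig, t: float) -> np.ndarray:
    """Analytic Jacobian of :func:`drift` with respect to the state."""
    mc, mb, g = cfg.cup_mass, cfg.ball_mass, cfg.gravity
    kb = cfg.damping_ratio
    alpha = cfg.uncertainty.reversion_rate
    xd, vd = cfg.desired_cup(t)
    x, v, th, om, l, K = m[IX], m[IV], m[ITH], m[IOM], m[IL], m[IK]
    s, c = math.sin(th), math.cos(th)
    den = mc + mb * s * s
    F = _applied_force(m, xd, vd, kb)
    num = mb * (l * om * om * s + g * s * c) + F
    vdot = num / den

    J = np.zeros((9, 9))
    J[IX, IV] = 1.0
    # dv/d*: quotient rule; F depends on x, v, K, F_ff
    dnum = np.zeros(9)
    dnum[IX] = -K
    dnum[IV] = -kb * K
    dnum[ITH] = mb * (l * om * om * c + g * (c * c - s * s))
    dnum[IOM] = 2.0 * mb * l * om * s
    dnum[IL] = mb * om * om * s
    dnum[IFF] = 1.0
    dnum[IK] = (xd - x) + kb * (vd - v)
    dden_dth = 2.0 * mb * s * c
    J[IV] = dnum / den
    J[IV, ITH] -= num * dden_dth / (den * den)
    # omega-dot = -vdot c/l - g s/l
    J[3] = -J[IV] * c / l
    J[3, ITH] += vdot * s / l - g * c / l
    J[3, IL] += vdot * c / (l * l) + g * s / (l * l)
    J[ITH, IOM] = 1.0
    J[IL, IL] = -alpha
    J[IFF, IDFF] = 1.0
    J[IK, IDK] = 1.0
    return J


def noise_matrix(cfg: SOOCConfig) -> np.ndarray:
    """G (9x1): additive OU noise enters only the length row."""
    G = np.zeros((9, 1))
    G[IL, 0] = cfg.uncertainty.ou_sd
    return G


def mean_cov_rhs(
    m: np.ndarray, P: np.ndarray, u: np.ndarray, cfg: SOOCConfig, t: float
) -> tuple[np.ndarray, np.ndarray]:
    """Coupled mean and covariance derivatives (first-order propagation)."""
    F = jacobian(m, u, cfg, t)
    G = noise_matrix(cfg)
    mdot = drift(m, u, cfg, t)
    Pdot = F @ P + P @ F.T + G @ G.T
    return mdot, Pdot


def _rk4_core_py(m0, P0, controls, per_ctrl, xd_half, vd_half, dt, mc, mb, g, kb,
                 alpha, lmean, sigma, with_cov):
    """Reference propagation loop; the numba version mirrors it exactly."""
    n = (len(xd_half) - 1) // 2 + 1
    means = np.empty((n, 9))
    covs = np.zeros((n, 9, 9))
    G2 = np.zeros((9, 9))
    G2[IL, IL] = sigma * sigma
    m = m0.copy()
    P = P0.copy()
    n_int = len(controls)

    def fjac(mm, xd, vd):
        x, v, th, om, l, K = mm[IX], mm[IV], mm[ITH], mm[IOM], mm[IL], mm[IK]
        s, c = math.sin(th), math.cos(th)
        den = mc + mb * s * s
        F = K * (xd - x) + kb * K * (vd - v) + mm[IFF]
        num = mb * (l * om * om * s + g * s * c) + F
        vdot = num / den
        d = np.zeros(9)
        d[IX] = v
        d[IV] = vdot
        d[ITH] = om
        d[IOM] = -vdot * c / l - g * s / l
        d[IL] = -alpha * (l - lmean)
        d[IFF] = mm[IDFF]
        d[IK] = mm[IDK]
        J = np.zeros((9, 9))
        J[IX, IV] = 1.0
        J[IV, IX] = -K / den
        J[IV, IV] = -kb * K / den
        J[IV, ITH] = (mb * (l * om * om * c + g * (c * c - s * s))) / den - num * (
            2.0 * mb * s * c
        ) / (den * den)
        J[IV, IOM] = 2.0 * mb * l * om * s / den
        J[IV, IL] = mb * om * om * s / den
        J[IV, IFF] = 1.0 / den
        J[IV, IK] = ((xd - x) + kb * (vd - v)) / den
        for k in range(9):
            J[IOM, k] = -J[IV, k] * c / l
        J[IOM, ITH] += vdot * s / l - g * c / l
        J[IOM, IL] += vdot * c / (l * l) + g * s / (l * l)
        J[ITH, IOM] = 1.0
        J[IL, IL] = -alpha
        J[IFF, IDFF] = 1.0
        J[IK, IDK] = 1.0
        return d, J

    for i in range(n):
        means[i] = m
        if with_cov:
            covs[i] = P
        if i == n - 1:
            break
        kc = min(i // per_ctrl, n_int - 1)
        uK, uF = controls[kc, 0], controls[kc, 1]

        def stage(mm, PP, h):
            d, J = fjac(mm, xd_half[h], vd_half[h])
            d[IDK] = uK
            d[IDFF] = uF
            if with_cov:
                Pd = J @ PP + PP @ J.T + G2
            else:
                Pd = PP
            return d, Pd

        h = 2 * i
        k1m, k1p = stage(m, P, h)
        k2m, k2p = stage(m + 0.5 * dt * k1m, P + 0.5 * dt * k1p, h + 1)
        k3m, k3p = stage(m + 0.5 * dt * k2m, P + 0.5 * dt * k2p, h + 1)
        k4m, k4p = stage(m + dt * k3m, P + dt * k3p, h + 2)
        m = m + (dt / 6.0) * (k1m + 2 * k2m + 2 * k3m + k4m)
        if with_cov:
            P = P + (dt / 6.0) * (k1p + 2 * k2p + 2 * k3p + k4p)
            P = 0.5 * (P + P.T)
        if not np.all(np.isfinite(m)):
            raise FloatingPointError("mean state diverged")
    return means, covs


if _HAVE_NUMBA:

    @njit(cache=True)
    def _rk4_core_nb(m0, P0, controls, per_ctrl, xd_half, vd_half, dt, mc, mb, g,
                     kb, alpha, lmean, sigma, with_cov):  # pragma: no cover
        n = (len(xd_half) - 1) // 2 + 1
        means = np.empty((n, 9))
        covs = np.zeros((n, 9, 9))
        G2 = np.zeros((9, 9))
        G2[4, 4] = sigma * sigma
        m = m0.copy()
        P = P0.copy()
        n_int = len(controls)
        d = np.zeros(9)
        ok = True

        for i in range(n):
            means[i] = m
            if with_cov:
                covs[i] = P
            if i == n - 1:
                break
            kc = min(i // per_ctrl, n_int - 1)
            uK = controls[kc, 0]
            uF = controls[kc, 1]

            mm = m.copy()
            PP = P.copy()
            msum = np.zeros(9)
            Psum = np.zeros((9, 9))
            for stage in range(4):
                if stage == 0:
                    h = 2 * i
                    wgt = 1.0
                elif stage == 3:
                    h = 2 * i + 2
                    wgt = 1.0
                else:
                    h = 2 * i + 1
                    wgt = 2.0
                xd = xd_half[h]
                vd = vd_half[h]
                x = mm[0]; v = mm[1]; th = mm[2]; om = mm[3]; l = mm[4]
                Fff = mm[5]; K = mm[6]
                s = math.sin(th); c = math.cos(th)
                den = mc + mb * s * s
                F = K * (xd - x) + kb * K * (vd - v) + Fff
                num = mb * (l * om * om * s + g * s * c) + F
                vdot = num / den
                d[0] = v
                d[1] = vdot
                d[2] = om
                d[3] = -vdot * c / l - g * s / l
                d[4] = -alpha * (l - lmean)
                d[5] = mm[7]
                d[6] = mm[8]
                d[7] = uF
                d[8] = uK
                if with_cov:
                    J = np.zeros((9, 9))
                    J[0, 1] = 1.0
                    J[1, 0] = -K / den
                    J[1, 1] = -kb * K / den
                    J[1, 2] = (mb * (l * om * om * c + g * (c * c - s * s))) / den - num * (
                        2.0 * mb * s * c
                    ) / (den * den)
                    J[1, 3] = 2.0 * mb * l * om * s / den
                    J[1, 4] = mb * om * om * s / den
                    J[1, 5] = 1.0 / den
                    J[1, 6] = ((xd - x) + kb * (vd - v)) / den
                    for k in range(9):
                        J[3, k] = -J[1, k] * c / l
                    J[3, 2] += vdot * s / l - g * c / l
                    J[3, 4] += vdot * c / (l * l) + g * s / (l * l)
                    J[2, 3] = 1.0
                    J[4, 4] = -alpha
                    J[5, 7] = 1.0
                    J[6, 8] = 1.0
                    Pd = J @ PP + PP @ J.T + G2
                else:
                    Pd = np.zeros((9, 9))
                msum = msum + wgt * d
                Psum = Psum + wgt * Pd
                if stage == 0 or stage == 1:
                    mm = m + 0.5 * dt * d
                    PP = P + 0.5 * dt * Pd
                elif stage == 2:
                    mm = m + dt * d
                    PP = P + dt * Pd
            m = m + (dt / 6.0) * msum
            if with_cov:
                P = P + (dt / 6.0) * Psum
                P = 0.5 * (P + P.T)
            for k in range(9):
                if not math.isfinite(m[k]):
                    ok = False
            if not ok:
                break
        return means, covs, ok


def _control_lookup(cfg: SOOCConfig, controls: np.ndarray):
    n_int = int(round(cfg.total_duration / cfg.control_dt))
    if controls.shape != (n_int, 2):
        raise ValueError(f"controls must have shape ({n_int}, 2)")

    def u_of(t: float) -> np.ndarray:
        k = min(int(t / cfg.control_dt), n_int - 1)
        return controls[k]

    return u_of


def initial_state(cfg: SOOCConfig) -> tuple[np.ndarray, np.ndarray]:
    """m0 and P0: cup at the left box, ball at rest, length at its mean with
    stationary variance, stiffness at its initial guess value."""
    m0 = np.zeros(9)
    m0[IX] = -cfg.amplitude
    m0[IL] = cfg.uncertainty.mean_length
    m0[IK] = cfg.k_init
    P0 = np.zeros((9, 9))
    P0[IL, IL] = cfg.uncertainty.length_sd**2
    return m0, P0


def propagate(
    cfg: SOOCConfig, controls: np.ndarray, with_cov: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RK4 integration of the mean (and covariance) under piecewise-constant
    pseudo-controls.

    Returns ``(time, mean (n,9), cov (n,9,9))``; ``cov`` is zeros when
    ``with_cov`` is False.  The covariance is symmetrised every step.  The
    10 ms step keeps explicit RK4 inside its stability region for the stiff
    length subsystem (eigenvalues -alpha and -2 alpha).
    """
    dt = cfg.dt
    n = int(round(cfg.total_duration / dt)) + 1
    t_grid = np.arange(n) * dt
    controls = np.asarray(controls, dtype=float)
    n_int = int(round(cfg.total_duration / cfg.control_dt))
    if controls.shape != (n_int, 2):
        raise ValueError(f"controls must have shape ({n_int}, 2)")
    per_ctrl = int(round(cfg.control_dt / dt))
    half_t = np.arange(2 * (n - 1) + 1) * (dt / 2.0)
    xd_half = np.empty(len(half_t))
    vd_half = np.empty(len(half_t))
    for i, tt in enumerate(half_t):
        xd_half[i], vd_half[i] = cfg.desired_cup(tt)
    m0, P0 = initial_state(cfg)
    u = cfg.uncertainty
    args = (
        m0, P0, controls, per_ctrl, xd_half, vd_half, dt,
        cfg.cup_mass, cfg.ball_mass, cfg.gravity, cfg.damping_ratio,
        u.reversion_rate, u.mean_length, u.ou_sd, with_cov,
    )
    if _HAVE_NUMBA:
        means, covs, ok = _rk4_core_nb(*args)
        if not ok:
            raise FloatingPointError("mean state diverged during propagation")
    else:
        means, covs = _rk4_core_py(*args)
    return t_grid, means, covs


def stage_cost(m: np.ndarray, P: np.ndarray, u: np.ndarray, t: float, cfg: SOOCConfig) -> float:
    """Running cost density at trial time ``t``.

    Tracking and variance terms are active during the rhythmic stage only;
    stiffness effort and pseudo-control effort are always on.
    """
    c = cfg.q_stiff * m[IK] ** 2 + cfg.r_control * float(u @ u)
    if t >= cfg.prep_duration:
        xd, vd = cfg.desired_cup(t)
        c += cfg.q_pos * (m[IX] - xd) ** 2 + cfg.q_vel * (m[IV] - vd) ** 2
        c += cfg.qv_pos * P[IX, IX] + cfg.qv_vel * P[IV, IV]
    return c


def prep_end_cost(m: np.ndarray, P: np.ndarray, cfg: SOOCConfig) -> float:
    """Large soft penalty pinning the end-of-preparation state.

    Pins (x, v) to (-A, 0) and (theta, omega) to (theta_target, 0), and
    penalises the cup-state variance at that instant.
    """
    w = cfg.w_prep
    err = (
        (m[IX] + cfg.amplitude) ** 2
        + m[IV] ** 2
        + (m[ITH] - cfg.theta_target) ** 2
        + m[IOM] ** 2
    )
    return w * err + cfg.qv_pos * P[IX, IX] + cfg.qv_vel * P[IV, IV]


def terminal_cost(m: np.ndarray, P: np.ndarray, cfg: SOOCConfig) -> float:
    """Terminal tracking + variance cost at the end of the rhythmic stage."""
    xd, vd = cfg.desired_cup(cfg.total_duration - 1e-12)
    return (
        cfg.q_pos * (m[IX] - xd) ** 2
        + cfg.q_vel * (m[IV] - vd) ** 2
        + cfg.qv_pos * P[IX, IX]
        + cfg.qv_vel * P[IV, IV]
    )


def trajectory_cost(
    cfg: SOOCConfig, t_grid: np.ndarray, means: np.ndarray, covs: np.ndarray,
    controls: np.ndarray,
) -> float:
    """Total cost J of a propagated trajectory (trapezoid-free Riemann sum)."""
    u_of = _control_lookup(cfg, controls)
    J = 0.0
    for i, t in enumerate(t_grid[:-1]):
        J += stage_cost(means[i], covs[i], u_of(t), t, cfg) * cfg.dt
    i_prep = int(round(cfg.prep_duration / cfg.dt))
    J += prep_end_cost(means[i_prep], covs[i_prep], cfg)
    J += terminal_cost(means[-1], covs[-1], cfg)
    return float(J)


def initial_guess(cfg: SOOCConfig) -> np.ndarray:
    """Pseudo-control initial guess.

    K-double-dot starts at zero everywhere (K held at its initial value
    ``k_init`` = 10).  The feedforward guess comes from simulating the plain
    impedance controller at the small gain K = 10 along the trial, reading
    off the force it applies, and differentiating twice; its interval means
    seed F_ff-double-dot.
    """
    n_int = int(round(cfg.total_duration / cfg.control_dt))
    dt = cfg.dt
    n = int(round(cfg.total_duration / dt)) + 1
    K0, kb = cfg.k_init, cfg.damping_ratio
    mc, mb, g = cfg.cup_mass, cfg.ball_mass, cfg.gravity
    l = cfg.uncertainty.mean_length
    x, v, th, om = -cfg.amplitude, 0.0, 0.0, 0.0
    F_series = np.empty(n)

    def deriv(x, v, th, om, tt):
        xd, vd = cfg.desired_cup(tt)
        F = K0 * (xd - x) + kb * K0 * (vd - v)
        s, c = math.sin(th), math.cos(th)
        vdot = (mb * (l * om * om * s + g * s * c) + F) / (mc + mb * s * s)
        return v, vdot, om, -vdot * c / l - g * s / l

    for i in range(n):
        tt = i * dt
        xd, vd = cfg.desired_cup(tt)
        F_series[i] = K0 * (xd - x) + kb * K0 * (vd - v)
        if i == n - 1:
            break
        k1 = deriv(x, v, th, om, tt)
        k2 = deriv(x + 0.5 * dt * k1[0], v + 0.5 * dt * k1[1],
                   th + 0.5 * dt * k1[2], om + 0.5 * dt * k1[3], tt + 0.5 * dt)
        k3 = deriv(x + 0.5 * dt * k2[0], v + 0.5 * dt * k2[1],
                   th + 0.5 * dt * k2[2], om + 0.5 * dt * k2[3], tt + 0.5 * dt)
        k4 = deriv(x + dt * k3[0], v + dt * k3[1], th + dt * k3[2], om + dt * k3[3], tt + dt)
        x += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        v += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        th += dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        om += dt / 6 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
    Fdd = np.gradient(np.gradient(F_series, dt), dt)
    guess = np.zeros((n_int, 2))
    per = int(round(cfg.control_dt / dt))
    for k in range(n_int):
        guess[k, 1] = Fdd[k * per : (k + 1) * per].mean()
    return guess


def optimize(
    cfg: SOOCConfig,
    maxiter: int = 60,
    ftol: float = 1e-6,
    enforce_nonneg_stiffness: bool = True,
) -> OptimalSolution:
    """Solve the SOOC problem by direct transcription with SLSQP.

    Decision variables are the piecewise-constant pseudo-controls
    [K-double-dot, F_ff-double-dot] on the ``control_dt`` grid; each cost
    evaluation propagates mean and covariance through the full trial.
    Non-negative stiffness is enforced as inequality constraints on K at
    the control nodes.  Non-convergence is reported, with the best iterate
    returned and flagged.
    """
    n_int = int(round(cfg.total_duration / cfg.control_dt))
    x0 = initial_guess(cfg).ravel()

    def unpack(z):
        return z.reshape(n_int, 2)

    def objective(z):
        try:
            t, m, P = propagate(cfg, unpack(z))
        except FloatingPointError:
            return 1e12
        return trajectory_cost(cfg, t, m, P, unpack(z))

    constraints = []
    if enforce_nonneg_stiffness:
        per = int(round(cfg.control_dt / cfg.dt))

        def k_nodes(z):
            try:
                _, m, _ = propagate(cfg, unpack(z), with_cov=False)
            except FloatingPointError:
                return np.full(n_int + 1, -1.0)
            return m[::per, IK]

        constraints.append({"type": "ineq", "fun": k_nodes})

    res = minimize(
        objective,
        x0,
        method="SLSQP",
        constraints=constraints,
        options={"maxiter": maxiter, "ftol": ftol},
    )
    controls = unpack(res.x)
    t, m, P = propagate(cfg, controls)
    return OptimalSolution(
        config=cfg,
        time=t,
        mean=m,
        cov=P,
        controls=controls,
        control_times=np.arange(n_int) * cfg.control_dt,
        cost=float(res.fun),
        converged=bool(res.success),
        message=str(res.message),
        n_iter=int(res.get("nit", -1)),
    )


def sweep_sooc(
    base_cfg: SOOCConfig,
    theta_targets_deg: np.ndarray,
    frequencies_hz: np.ndarray,
    maxiter: int = 40,
):
    """Optimise over a grid of desired (theta*, f) strategies.

    Returns two dicts of 2-D arrays (theta along axis 0): mean
    rhythmic-stage stiffness and mean |applied force|, with non-converged
    cells still reported (SLSQP's best iterate) but flagged in ``ok``.
    """
    th = np.asarray(theta_targets_deg, dtype=float)
    fr = np.asarray(frequencies_hz, dtype=float)
    K_map = np.full((len(th), len(fr)), np.nan)
    F_map = np.full((len(th), len(fr)), np.nan)
    ok = np.zeros((len(th), len(fr)), dtype=bool)
    for i, td in enumerate(th):
        for j, f in enumerate(fr):
            cfg = replace(base_cfg, theta_target=math.radians(td), frequency=f)
            try:
                sol = optimize(cfg, maxiter=maxiter)
            except Exception:
                continue
            K_map[i, j] = sol.mean_rhythmic_stiffness()
            i_prep = int(round(cfg.prep_duration / cfg.dt))
            F_map[i, j] = float(np.mean(np.abs(sol.applied_force()[i_prep:])))
            ok[i, j] = sol.converged
    return {"sooc_stiffness": K_map, "sooc_force": F_map, "ok": ok}


def simulate_sde_paths(
    cfg: SOOCConfig,
    controls: np.ndarray,
    n_paths: int,
    rng: np.random.Generator,
    dt: float = 1e-3,
    store_every: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo ensemble of the full nonlinear SDE.

    The mechanical states use an Euler-Maruyama step; the stiff
    Ornstein-Uhlenbeck length subsystem uses its exact Gaussian transition
    (l -> lmean + (l - lmean) e^{-alpha dt} + sqrt(var) xi) so the ensemble
    is unbiased in the length marginal even at moderate step sizes.  Used
    as the independent oracle for the mean-covariance propagation.
    Returns ``(time, states)``; only every ``store_every``-th step is kept,
    giving states of shape (n_stored, n_paths, 9).
    """
    n_steps = int(round(cfg.total_duration / dt))
    t_grid = np.arange(n_steps + 1) * dt
    u_of = _control_lookup(cfg, np.asarray(controls, dtype=float))
    mc, mb, g = cfg.cup_mass, cfg.ball_mass, cfg.gravity
    kb = cfg.damping_ratio
    alpha = cfg.uncertainty.reversion_rate
    lmean = cfg.uncertainty.mean_length

    m0, P0 = initial_state(cfg)
    X = np.tile(m0, (n_paths, 1))
    X[:, IL] += math.sqrt(P0[IL, IL]) * rng.standard_normal(n_paths)
    keep = np.arange(0, n_steps + 1, store_every)
    out = np.empty((len(keep), n_paths, 9))
    decay = math.exp(-alpha * dt)
    l_noise_sd = cfg.uncertainty.length_sd * math.sqrt(1.0 - decay * decay)
    stored = 0
    for i in range(n_steps + 1):
        if i % store_every == 0:
            out[stored] = X
            stored += 1
        if i == n_steps:
            break
        tt = t_grid[i]
        u = u_of(tt)
        xd, vd = cfg.desired_cup(tt)
        x, v = X[:, IX], X[:, IV]
        th, om, l = X[:, ITH], X[:, IOM], X[:, IL]
        F = X[:, IK] * (xd - x) + kb * X[:, IK] * (vd - v) + X[:, IFF]
        s, c = np.sin(th), np.cos(th)
        vdot = (mb * (l * om**2 * s + g * s * c) + F) / (mc + mb * s**2)
        dX = np.empty_like(X)
        dX[:, IX] = v
        dX[:, IV] = vdot
        dX[:, ITH] = om
        dX[:, IOM] = -vdot * c / l - g * s / l
        dX[:, IL] = 0.0  # exact OU transition applied below
        dX[:, IFF] = X[:, IDFF]
        dX[:, IK] = X[:, IDK]
        dX[:, IDFF] = u[1]
        dX[:, IDK] = u[0]
        X = X + dt * dX
        X[:, IL] = (
            lmean
            + (X[:, IL] - lmean) * decay
            + l_noise_sd * rng.standard_normal(n_paths)
        )
    return t_grid[keep], out
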