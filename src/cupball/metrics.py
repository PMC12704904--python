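"""Per-trial dependent measures.

Covers the full behavioural-metric pipeline: instantaneous (Hilbert) phase
and relative phase between cup and ball, circular variance as the stability
proxy, instantaneous frequency, mean absolute force (effort), log
dimensionless jerk of force (smoothness), an energy-margin risk of the ball
escaping the cup rim, and the preparation-stage timing measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from cupball.dynamics import SystemParams, Trajectory

__all__ = [
    "PhaseSeries",
    "StabilityResult",
    "RiskResult",
    "DegenerateSignalError",
    "BoundaryNotFoundError",
    "instantaneous_phase",
    "relative_phase",
    "circular_variance",
    "instantaneous_frequency",
    "mean_absolute_force",
    "log_dimensionless_jerk",
    "risk_of_escape",
    "relative_phase_variability",
    "parse_stages",
    "time_to_stable_phase",
    "preparation_duration",
]


class DegenerateSignalError(ValueError):
    """Signal has no oscillatory content (constant), so phase is undefined."""


class BoundaryNotFoundError(ValueError):
    """No preparation -> rhythmic boundary could be located."""


@dataclass
class PhaseSeries:
    """Unwrapped instantaneous phase on a uniform time grid."""

    time: np.ndarray
    phase: np.ndarray  # rad, unwrapped


@dataclass
class StabilityResult:
    """Relative phase series and its circular variance."""

    relative_phase: np.ndarray  # rad
    circular_variance: float


@dataclass
class RiskResult:
    """Energy-margin based escape risk for one trial.

    ``escape_energy`` is the ball energy at the cup rim,
    mb * g * l * (1 - cos(theta_rim)); ``margin`` is its excess over the
    instantaneous ball energy; ``risk`` is 1 minus the time-normalised
    integral of the margin, so 0 = ball resting at the bottom throughout
    and 1 = ball at rim energy throughout.
    """

    escape_energy: float
    margin: np.ndarray  # J
    risk: float


def instantaneous_phase(signal, dt: float) -> PhaseSeries:
    """Unwrapped phase of the analytic signal.

    The mean is removed before the Hilbert transform (a DC offset corrupts
    the analytic phase).  A constant signal raises
    :class:`DegenerateSignalError`.
    """
    sig = np.asarray(signal, dtype=float)
    if sig.ndim != 1 or len(sig) < 4:
        raise ValueError("signal must be 1-D with at least 4 samples")
    if not np.all(np.isfinite(sig)):
        raise ValueError("signal contains non-finite values")
    centred = sig - sig.mean()
    if np.max(np.abs(centred)) < 1e-12 * max(1.0, np.abs(sig).max()):
        raise DegenerateSignalError("constant signal has no defined phase")
    phase = np.unwrap(np.angle(hilbert(centred)))
    t = np.arange(len(sig)) * dt
    return PhaseSeries(time=t, phase=phase)


def relative_phase(cup, ball, dt: float) -> np.ndarray:
    """phi_cup - phi_ball per sample (rad); 0 = in-phase, pi = anti-phase."""
    cup = np.asarray(cup, dtype=float)
    ball = np.asarray(ball, dtype=float)
    if cup.shape != ball.shape:
        raise ValueError("cup and ball series must have equal length")
    return instantaneous_phase(cup, dt).phase - instantaneous_phase(ball, dt).phase


def circular_variance(angles) -> float:
    """1 - |mean resultant vector| of a set of angles (rad); in [0, 1]."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("circular_variance of empty input is undefined")
    cv = 1.0 - np.abs(np.exp(1j * a).mean())
    return float(min(max(cv, 0.0), 1.0))  # clamp roundoff outside [0, 1]


def _edge_trim_samples(dt: float, n: int, trim_seconds: float | None, freq_hint: float | None) -> int:
    if trim_seconds is None:
        trim_seconds = 1.0 / freq_hint if freq_hint else 0.0
    k = int(round(trim_seconds / dt))
    return min(k, max((n - 2) // 2, 0))


def relative_phase_variability(
    cup,
    ball,
    dt: float,
    freq_hint: float | None = None,
    trim_seconds: float | None = None,
) -> StabilityResult:
    """Circular variance of the cup-ball relative phase.

    The analytic signal is unreliable near the series ends, so one nominal
    period (1/``freq_hint``) is discarded at each end before the variance is
    taken; pass ``trim_seconds`` to override, or leave both unset for no
    trimming.  The returned relative-phase series is the untrimmed one.
    """
    rp = relative_phase(cup, ball, dt)
    k = _edge_trim_samples(dt, len(rp), trim_seconds, freq_hint)
    interior = rp[k : len(rp) - k] if k else rp
    return StabilityResult(relative_phase=rp, circular_variance=circular_variance(interior))


def instantaneous_frequency(signal, dt: float, trim_seconds: float | None = None,
                            freq_hint: float | None = None) -> np.ndarray:
    """Instantaneous frequency in Hz: d(unwrapped phase)/dt / (2 pi).

    Central differences; one sample is lost at each end, plus the optional
    edge trim (defaults to one nominal period when ``freq_hint`` is given).
    """
    ps = instantaneous_phase(signal, dt)
    freq = np.gradient(ps.phase, dt) / (2 * np.pi)
    k = _edge_trim_samples(dt, len(freq), trim_seconds, freq_hint)
    k = max(k, 1)
    return freq[k:-k]


def mean_absolute_force(force) -> float:
    """Arithmetic mean of |F| (N), the effort proxy."""
    f = np.asarray(force, dtype=float)
    if f.size == 0:
        raise ValueError("empty force series")
    return float(np.mean(np.abs(f)))


def log_dimensionless_jerk(force, dt: float) -> float:
    """Smoothness of an applied-force profile.

    -log( duration^3 / F_peak^2 * integral(Fddot^2 dt) ), dimensionless and
    invariant to amplitude scaling and time reversal; larger (less negative)
    = smoother.  Second derivative by central differences with one-sided
    ends; trapezoidal integral.
    """
    f = np.asarray(force, dtype=float)
    if f.size < 5:
        raise ValueError("need at least 5 samples for a second derivative")
    fpeak = np.max(np.abs(f))
    if fpeak == 0:
        raise ValueError("all-zero force: log dimensionless jerk undefined")
    fdd = np.gradient(np.gradient(f, dt), dt)
    duration = (len(f) - 1) * dt
    integral = np.trapezoid(fdd**2, dx=dt)
    return float(-math.log(duration**3 / fpeak**2 * integral))


def risk_of_escape(theta, omega, params: SystemParams, dt: float) -> RiskResult:
    """Energy-margin risk of the ball escaping beyond the cup rim.

    E_total(t) = 1/2 mb l^2 w^2 + mb g l (1 - cos theta)   (ball energy)
    E_escape   = mb g l (1 - cos theta_rim)
    Risk       = 1 - (1 / (T E_escape)) * integral(E_escape - E_total) dt
    """
    th = np.asarray(theta, dtype=float)
    om = np.asarray(omega, dtype=float)
    if th.shape != om.shape:
        raise ValueError("theta and omega must have equal length")
    mb, l, g = params.ball_mass, params.pendulum_length, params.gravity
    e_total = 0.5 * mb * l**2 * om**2 + mb * g * l * (1 - np.cos(th))
    e_escape = mb * g * l * (1 - math.cos(params.rim_angle))
    margin = e_escape - e_total
    duration = (len(th) - 1) * dt
    if duration <= 0:
        risk = float(1 - margin[0] / e_escape)
    else:
        risk = float(1 - np.trapezoid(margin, dx=dt) / (duration * e_escape))
    return RiskResult(escape_energy=e_escape, margin=margin, risk=risk)


def parse_stages(
    traj: Trajectory,
    box_center: float = 0.15,
    box_half_width: float = 0.03,
    velocity_tol: float = 1e-3,
) -> int:
    """Locate the preparation -> rhythmic boundary in a recorded trial.

    The rhythmic stage starts when the cup first enters the right target
    box (x >= ``box_center`` - ``box_half_width``); the boundary is the last
    zero of cup velocity (sign change or |v| < ``velocity_tol``) before that
    onset.  Returns the boundary sample index.
    """
    x = traj.cup_position
    v = traj.cup_velocity
    onset_candidates = np.nonzero(x >= box_center - box_half_width)[0]
    if onset_candidates.size == 0:
        raise BoundaryNotFoundError("cup never reaches the right target box")
    onset = int(onset_candidates[0])
    seg = v[: max(onset, 1)]
    near_zero = np.abs(seg) < velocity_tol
    sign_change = np.zeros_like(near_zero)
    if len(seg) > 1:
        sign_change[1:] = np.sign(seg[1:]) * np.sign(seg[:-1]) < 0
    hits = np.nonzero(near_zero | sign_change)[0]
    if hits.size == 0:
        raise BoundaryNotFoundError(
            "no cup-velocity zero crossing precedes the rhythmic onset"
        )
    return int(hits[-1])


def preparation_duration(traj: Trajectory, boundary_index: int | None = None) -> float:
    """Stage-boundary time minus trial start time (s)."""
    i = traj.stage_boundary_index if boundary_index is None else boundary_index
    return float(traj.time[i] - traj.time[0])


def time_to_stable_phase(
    traj: Trajectory,
    threshold: float = 0.1,
    min_window: float = 0.5,
    boundary_index: int | None = None,
) -> tuple[float, bool]:
    """Time from trial start until the cup-ball relative phase stabilises.

    A window with its right bound fixed at the end of the preparation stage
    grows backward one sample at a time; the circular variance of relative
    phase inside the window is computed for each left bound.  The left-bound
    time at which the variance first exceeds ``threshold`` marks the end of
    the unstable epoch: the returned time is that point minus the trial
    start.  If no window exceeds the threshold the phase is deemed stable
    from the start and (0.0, True) is returned, the flag marking the
    degenerate case.  Windows shorter than ``min_window`` seconds are not
    evaluated.

    Returns
    -------
    (time_to_stable_s, stable_from_start)
    """
    i = traj.stage_boundary_index if boundary_index is None else boundary_index
    if i < 2:
        raise ValueError("preparation stage too short to analyse")
    dt = traj.dt
    prep_cup = traj.cup_position[: i + 1]
    prep_ball = traj.ball_angle[: i + 1]
    rp = relative_phase(prep_cup, prep_ball, dt)
    nmin = max(int(round(min_window / dt)), 2)
    if len(rp) < nmin:
        raise ValueError("preparation shorter than the minimum window")
    # growing window: left bound moves backward from i - nmin + 1 toward 0
    z = np.exp(1j * rp[::-1])  # reversed: cumulative mean = growing window
    cum = np.cumsum(z) / np.arange(1, len(z) + 1)
    cv = 1.0 - np.abs(cum)  # cv[k]: window covering the last k+1 samples
    for k in range(nmin - 1, len(cv)):
        if cv[k] > threshold:
            left = len(rp) - 1 - k  # sample index of the left bound
            return float(traj.time[left] - traj.time[0]), False
    return 0.0, True
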