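"""Strategy landscapes over (initial ball angle x cup frequency).

For each cell of a grid spanning initial ball angle theta0 in [-90, 90] deg
and cup oscillation frequency f in [0.3, 1.0] Hz, a 15 s impedance-controlled
trial is forward-simulated and a scalar objective evaluated: relative-phase
variability (dynamic stability), mean absolute force (effort), log
dimensionless jerk of force (smoothness), or risk of ball escape.  Maps are
converted to probability densities and compared with 2-D histograms of
behavioural (theta0, f) choices via Kullback-Leibler divergence: the
objective with the lowest divergence best explains where choices
concentrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from cupball import metrics
from cupball.dynamics import ControllerSpec, SystemParams, simulate_batch

__all__ = [
    "StrategyGrid",
    "StrategyMap",
    "ChoiceSet",
    "COST_METRICS",
    "sweep_stability",
    "sweep_cost",
    "sweep_all",
    "map_to_density",
    "choices_histogram",
    "kl_divergence",
    "rank_objectives",
    "count_stability_branches",
]

#: Objectives computable by :func:`sweep_cost`.
COST_METRICS = ("mean_abs_force", "ldj_force", "risk")


@dataclass(frozen=True)
class StrategyGrid:
    """Uniform grid of candidate strategies.

    ``theta0`` values are cell centers in degrees, ``freq`` in Hz, both
    strictly increasing.
    """

    theta0_deg: np.ndarray = field(
        default_factory=lambda: np.linspace(-90.0, 90.0, 37)
    )
    freq_hz: np.ndarray = field(default_factory=lambda: np.linspace(0.3, 1.0, 36))

    def __post_init__(self) -> None:
        for name in ("theta0_deg", "freq_hz"):
            ax = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, ax)
            if ax.ndim != 1 or len(ax) < 2 or np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} must be strictly increasing with >= 2 nodes")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.theta0_deg), len(self.freq_hz))

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(theta0, freq) arrays of shape ``self.shape``."""
        return np.meshgrid(self.theta0_deg, self.freq_hz, indexing="ij")

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Bin edges centred on the grid nodes (for histogramming choices)."""

        def _edges(ax):
            mid = 0.5 * (ax[1:] + ax[:-1])
            first = ax[0] - (mid[0] - ax[0])
            last = ax[-1] + (ax[-1] - mid[-1])
            return np.concatenate([[first], mid, [last]])

        return _edges(self.theta0_deg), _edges(self.freq_hz)

    @classmethod
    def with_resolution(cls, n_theta: int, n_freq: int) -> "StrategyGrid":
        return cls(np.linspace(-90.0, 90.0, n_theta), np.linspace(0.3, 1.0, n_freq))


@dataclass
class StrategyMap:
    """One scalar objective evaluated on every cell of a :class:`StrategyGrid`."""

    grid: StrategyGrid
    metric: str
    values: np.ndarray  # shape grid.shape, theta0 along axis 0
    pendulum_length: float | None = None
    diverged: np.ndarray | None = None  # bool mask of cells flagged divergent

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")


@dataclass
class ChoiceSet:
    """Behavioural choices of (initial ball angle, cup frequency)."""

    theta0_deg: np.ndarray
    freq_hz: np.ndarray
    participant: np.ndarray | None = None
    protocol: np.ndarray | None = None
    pendulum_length: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta0_deg = np.asarray(self.theta0_deg, dtype=float)
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        if self.theta0_deg.shape != self.freq_hz.shape:
            raise ValueError("theta0 and freq must have equal length")


def _simulate_grid(
    params: SystemParams,
    grid: StrategyGrid,
    ctrl: ControllerSpec,
    duration: float,
    dt: float,
    omega0: float,
):
    th, fr = grid.mesh()
    return simulate_batch(
        params,
        ctrl.stiffness,
        ctrl.damping,
        ctrl.desired_amplitude,
        fr,
        np.radians(th),
        omega0=omega0,
        duration=duration,
        dt=dt,
        phase_sign=ctrl.phase_sign,
    )


def sweep_stability(
    params: SystemParams,
    grid: StrategyGrid,
    ctrl: ControllerSpec | None = None,
    duration: float = 15.0,
    dt: float = 0.01,
    omega0: float = math.radians(-4.0),
    trim_seconds: float | None = None,
) -> StrategyMap:
    """Relative-phase variability for every (theta0, f) cell.

    Each cell is a 15 s forward simulation followed by the circular variance
    of the cup-ball Hilbert relative phase.  Cells whose simulation diverges
    (ball swung over the top, non-finite states) are recorded as 1 (maximal
    variability) and flagged.
    """
    ctrl = ctrl or ControllerSpec()
    sims = _simulate_grid(params, grid, ctrl, duration, dt, omega0)
    values = np.ones(grid.shape)
    diverged = np.zeros(grid.shape, dtype=bool)
    nth, nf = grid.shape
    for i in range(nth):
        for j in range(nf):
            x = sims["x"][:, i, j]
            th = sims["theta"][:, i, j]
            if not (np.all(np.isfinite(x)) and np.all(np.isfinite(th))):
                diverged[i, j] = True
                continue
            try:
                res = metrics.relative_phase_variability(
                    x, th, dt, trim_seconds=trim_seconds
                )
                values[i, j] = res.circular_variance
            except metrics.DegenerateSignalError:
                diverged[i, j] = True
    return StrategyMap(grid, "rel_phase_var", values, params.pendulum_length, diverged)


def sweep_cost(
    params: SystemParams,
    grid: StrategyGrid,
    metric: str,
    ctrl: ControllerSpec | None = None,
    duration: float = 15.0,
    dt: float = 0.01,
    omega0: float = math.radians(-4.0),
) -> StrategyMap:
    """Same sweep, evaluating an alternative objective per cell.

    ``metric`` is one of ``mean_abs_force`` (N), ``ldj_force``
    (dimensionless) or ``risk`` (dimensionless).
    """
    if metric not in COST_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {COST_METRICS}")
    ctrl = ctrl or ControllerSpec()
    sims = _simulate_grid(params, grid, ctrl, duration, dt, omega0)
    values = np.full(grid.shape, np.nan)
    diverged = np.zeros(grid.shape, dtype=bool)
    nth, nf = grid.shape
    for i in range(nth):
        for j in range(nf):
            F = sims["force"][:, i, j]
            th = sims["theta"][:, i, j]
            om = sims["omega"][:, i, j]
            if not np.all(np.isfinite(F)):
                diverged[i, j] = True
                continue
            if metric == "mean_abs_force":
                values[i, j] = metrics.mean_absolute_force(F)
            elif metric == "ldj_force":
                values[i, j] = metrics.log_dimensionless_jerk(F, dt)
            else:
                values[i, j] = metrics.risk_of_escape(th, om, params, dt).risk
    if metric == "ldj_force":
        # smoothness: larger = smoother; negate so every map is cost-like
        values = -values
    finite_max = np.nanmax(values[~diverged]) if np.any(~diverged) else 1.0
    values[diverged | ~np.isfinite(values)] = finite_max
    return StrategyMap(grid, metric, values, params.pendulum_length, diverged)


def sweep_all(
    params: SystemParams,
    grid: StrategyGrid,
    ctrl: ControllerSpec | None = None,
    **kw,
) -> dict[str, StrategyMap]:
    """Stability plus the three alternative objective maps."""
    maps = {"rel_phase_var": sweep_stability(params, grid, ctrl, **kw)}
    for m in COST_METRICS:
        maps[m] = sweep_cost(params, grid, m, ctrl, **kw)
    return maps


def map_to_density(
    strategy_map: StrategyMap, temperature: float | None = None
) -> np.ndarray:
    """Softmin conversion of a cost-like map into a probability density.

    p(cell) proportional to exp(-value / tau); ``temperature`` tau defaults
    to the standard deviation of the map values (scale-aware, and the
    tau -> 0 limit concentrates all mass on the argmin cells).  A constant
    map yields the uniform density.
    """
    v = np.asarray(strategy_map.values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("map contains non-finite values")
    tau = float(np.std(v)) if temperature is None else float(temperature)
    if tau <= 0:
        if np.ptp(v) == 0:
            return np.full(v.shape, 1.0 / v.size)
        p = (v == v.min()).astype(float)
        return p / p.sum()
    z = -(v - v.min()) / tau
    p = np.exp(z)
    return p / p.sum()


def choices_histogram(
    choices: ChoiceSet, grid: StrategyGrid, floor: float = 1e-6
) -> np.ndarray:
    """Normalised 2-D histogram of choices on the grid's cell edges.

    Zero-count cells are floored at ``floor`` (before renormalisation) so
    that KL divergences stay finite.
    """
    th_edges, f_edges = grid.edges()
    th = np.clip(choices.theta0_deg, th_edges[0], th_edges[-1])
    fr = np.clip(choices.freq_hz, f_edges[0], f_edges[-1])
    counts, _, _ = np.histogram2d(th, fr, bins=(th_edges, f_edges))
    p = counts / counts.sum() if counts.sum() else np.full(counts.shape, 1.0)
    p = np.maximum(p, floor)
    return p / p.sum()


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """D(p || q) = sum p ln(p/q) in nats, over matching grids.

    By convention ``p`` is the behavioural histogram and ``q`` the model
    density: the divergence measures how badly the model explains where the
    data mass lies.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("densities live on different grids")
    if np.any(p < 0) or np.any(q <= 0):
        raise ValueError("p must be >= 0 and q strictly positive")
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def rank_objectives(
    choices: ChoiceSet,
    maps: dict[str, StrategyMap],
    temperature: float | None = None,
) -> dict[str, float]:
    """KL of the choice histogram against each objective's density.

    Returns a metric -> nats mapping sorted ascending; the first entry is
    the objective that best explains the choices.
    """
    if not maps:
        raise ValueError("no maps supplied")
    grid = next(iter(maps.values())).grid
    p = choices_histogram(choices, grid)
    out = {}
    for name, m in maps.items():
        if m.grid.shape != grid.shape:
            raise ValueError("all maps must share one grid")
        out[name] = kl_divergence(p, map_to_density(m, temperature))
    return dict(sorted(out.items(), key=lambda kv: kv[1]))


def count_stability_branches(
    stability_map: StrategyMap, threshold: float = 0.1
) -> int:
    """Number of connected low-variability regions (8-connectivity).

    Medium and long pendulums support two branches — in-phase at low
    frequency and anti-phase at high frequency, separated by a
    high-variability ridge near the pendulum resonance (1/2pi) sqrt(g/l).
    """
    below = stability_map.values < threshold
    _, n = ndimage.label(below, structure=np.ones((3, 3), dtype=int))
    return int(n)
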