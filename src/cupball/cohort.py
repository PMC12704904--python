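"""Synthetic participant cohort generator.

Emulates the behavioural structure the analysis pipeline assumes so the
whole pipeline — stage parsing, metrics, landscape comparison — runs end to
end without any recorded data.  A participant is a small phenomenological
model: a preferred coordination branch (in-phase, anti-phase or mixed), a
frequency preference, a softmin choice temperature over the stability
landscape, motor noise on the applied force, and a grip-force model
grip = baseline + gain * sigma_l(protocol) + coupling * |F| + noise that
encodes impedance elevation under uncertainty.  Each trial has a
preparation stage (cup jiggling while the cup-ball relative phase locks
onto the chosen branch) followed by a 15 s rhythmic stage simulated from
the plant, sampled at 120 Hz like the original recordings.

All randomness flows from one master seed through spawned per-trial
streams, so a cohort is byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cupball.dynamics import (
    ControllerSpec,
    SystemParams,
    Trajectory,
    simulate_batch,
    simulate_trial,
)
from cupball.landscapes import StrategyGrid, StrategyMap, map_to_density, sweep_stability

__all__ = [
    "ParticipantModel",
    "CohortConfig",
    "TrialRecord",
    "PROTOCOL_LENGTH_SD",
    "resonance_frequency",
    "sample_choice",
    "generate_trial",
    "generate_cohort",
]

#: Pendulum-length SD implied by each protocol (m): in the random protocol
#: the length is redrawn every trial (SD of the discrete 0.3/0.6/1.2
#: distribution); in the blocked protocol it is constant within a block.
PROTOCOL_LENGTH_SD = {"random": 0.37, "blocked": 0.1}

RECORDING_HZ = 120.0


def resonance_frequency(pendulum_length: float, cup_mass: float = 2.4,
                        ball_mass: float = 0.6, gravity: float = 9.81) -> float:
    """Coupled cart-pendulum natural frequency in Hz.

    The free system oscillates at sqrt(g/l * (mc+mb)/mc) / 2pi — the
    hanging-pendulum frequency raised by the cart-recoil factor.  It
    separates the in-phase (below) and anti-phase (above) branches.
    """
    w2 = gravity / pendulum_length * (cup_mass + ball_mass) / cup_mass
    return math.sqrt(w2) / (2 * math.pi)


@dataclass(frozen=True)
class ParticipantModel:
    """Phenomenological participant.

    ``preferred_branch`` restricts strategy sampling to the in-phase
    (f below resonance), anti-phase (above) or either region;
    ``choice_temperature`` scales the softmin over the stability map
    (0 -> always the best cell); ``grip_uncertainty_gain`` is the
    grip-force elevation per unit of pendulum-length SD (N/m).
    """

    participant_id: int
    preferred_branch: str = "mixed"  # in-phase | anti-phase | mixed
    freq_center: float = 0.5        # Hz
    freq_spread: float = 0.15       # Hz
    choice_temperature: float = 0.05
    motor_noise_sd: float = 0.3     # N
    grip_baseline: float = 8.0      # N
    grip_uncertainty_gain: float = 10.0  # N per m of length SD
    grip_force_coupling: float = 0.4     # N per N of |applied force|
    grip_noise_sd: float = 0.5      # N
    prep_skill: float = 4.0         # s, mean preparation duration
    prep_uncertainty_penalty: float = 1.5  # s added in the random protocol
    prep_jitter_sd: float = 0.8     # s

    def __post_init__(self) -> None:
        if self.preferred_branch not in ("in-phase", "anti-phase", "mixed"):
            raise ValueError("preferred_branch must be in-phase, anti-phase or mixed")
        if min(self.freq_spread, self.motor_noise_sd, self.grip_noise_sd,
               self.grip_uncertainty_gain, self.prep_jitter_sd) < 0:
            raise ValueError("spreads, noise levels and gains must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition mirroring the experimental design.

    Default: every participant completes both protocols, all three
    pendulums, 40 trials per pendulum per protocol.
    """

    n_participants: int = 12
    protocols: tuple[str, ...] = ("blocked", "random")
    pendulum_lengths: tuple[float, ...] = (0.3, 0.6, 1.2)
    trials_per_condition: int = 40
    master_seed: int = 0
    rhythmic_duration: float = 15.0
    amplitude: float = 0.15
    stiffness: float = 40.0
    damping: float = 70.0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.trials_per_condition < 1:
            raise ValueError("need at least one participant and one trial")
        unknown = set(self.protocols) - set(PROTOCOL_LENGTH_SD)
        if unknown:
            raise ValueError(f"unknown protocols: {unknown}")

    @property
    def n_trials(self) -> int:
        return (
            self.n_participants
            * len(self.protocols)
            * len(self.pendulum_lengths)
            * self.trials_per_condition
        )


@dataclass
class TrialRecord:
    """One synthetic trial: trajectory (preparation + rhythmic), grip force
    series, and ground-truth annotations for recovery tests.

    ``true_boundary_index`` is the stage boundary under the analysis
    convention (last cup-velocity zero before the cup enters the right
    target box), evaluated on the noise-free kinematics at generation
    time; ``true_prep_duration`` is the preparation duration the generator
    was asked to produce (the construction junction).  The two differ by
    the few samples it takes the cup to actually get moving: the ball's
    reaction force produces a brief backward dip at rhythm onset, so the
    last velocity zero sits slightly after the junction — exactly as it
    would in a recording.
    """

    participant_id: int
    protocol: str
    pendulum_length: float
    theta0_deg: float
    freq_hz: float
    trajectory: Trajectory
    grip_force: np.ndarray
    true_boundary_index: int
    true_prep_duration: float
    trial_id: str = ""


def _branch_mask(grid: StrategyGrid, pendulum_length: float, branch: str) -> np.ndarray:
    f_res = resonance_frequency(pendulum_length)
    _, fr = grid.mesh()
    if branch == "in-phase":
        return fr < f_res
    if branch == "anti-phase":
        return fr >= f_res
    return np.ones(grid.shape, dtype=bool)


def feasible_strategies(
    params: SystemParams, grid: StrategyGrid, ctrl: ControllerSpec
) -> np.ndarray:
    """Cells whose simulated ball stays inside the cup rim for the whole
    trial.  Participants never deliberately choose a strategy that loses
    the ball, however phase-stable its wide swing might be."""
    th, fr = grid.mesh()
    sims = simulate_batch(
        params,
        ctrl.stiffness,
        ctrl.damping,
        ctrl.desired_amplitude,
        fr,
        np.radians(th),
        phase_sign=ctrl.phase_sign,
    )
    theta = sims["theta"]
    peak = np.nanmax(np.abs(np.where(np.isfinite(theta), theta, np.inf)), axis=0)
    ok = peak < params.rim_angle
    # erode by one cell: within-cell jitter must not cross into escape
    # territory, and near resonance the boundary is sharp
    from scipy.ndimage import binary_erosion

    eroded = binary_erosion(ok, structure=np.ones((3, 3), dtype=bool))
    return eroded if eroded.any() else ok


def sample_choice(
    participant: ParticipantModel,
    pendulum_length: float,
    stability_map: StrategyMap,
    rng: np.random.Generator,
    feasible: np.ndarray | None = None,
) -> tuple[float, float]:
    """Draw one (theta0 deg, f Hz) strategy.

    Softmin over the stability map at the participant's temperature,
    multiplied by the participant's frequency preference (Gaussian),
    restricted to the preferred branch and (when given) to the
    escape-free ``feasible`` mask; the drawn cell is jittered uniformly
    within its bounds.
    """
    grid = stability_map.grid
    dens = map_to_density(stability_map, temperature=participant.choice_temperature)
    if feasible is not None:
        dens = dens * feasible
        if dens.sum() <= 0:
            dens = map_to_density(stability_map, temperature=participant.choice_temperature)
        dens = dens / dens.sum()
    mask = _branch_mask(grid, pendulum_length, participant.preferred_branch)
    _, fr = grid.mesh()
    pref = np.exp(-0.5 * ((fr - participant.freq_center) / participant.freq_spread) ** 2)
    p = dens * pref * mask
    if p.sum() <= 0:  # preference excludes the whole branch; drop the preference
        p = dens * mask
    if p.sum() <= 0:  # branch empty on this grid (e.g. anti-phase, short
        p = dens      # pendulum: resonance above the frequency range)
    p = p / p.sum()
    idx = rng.choice(p.size, p=p.ravel())
    i, j = np.unravel_index(idx, p.shape)
    th_edges, f_edges = grid.edges()
    theta = rng.uniform(th_edges[i], th_edges[i + 1])
    freq = rng.uniform(f_edges[j], f_edges[j + 1])
    return float(theta), float(freq)


def _synthesize_preparation(
    participant: ParticipantModel,
    protocol: str,
    choice: tuple[float, float],
    prep_duration: float,
    fs: float,
    amplitude: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Cup-jiggling preparation segment at sampling rate ``fs``.

    The cup oscillates with small amplitude left of the right target box;
    the ball's phase starts incoherent (random-walk phase offset) and locks
    onto the chosen branch in the second half, so the windowed
    time-to-stability procedure has a recoverable transition.  The segment
    ends at a cup-velocity zero with the ball at the chosen angle.
    """
    theta0_deg, freq = choice
    n = max(int(round(prep_duration * fs)), int(fs))  # at least 1 s
    t = np.arange(n) / fs
    f_jiggle = freq  # jiggle at the upcoming rhythmic frequency
    # phase ends exactly at a cos peak so cup velocity is ~0 at the boundary
    n_cycles = max(round(f_jiggle * t[-1]), 1.0)
    f_eff = n_cycles / t[-1]
    phase_cup = 2 * np.pi * f_eff * (t - t[-1])
    amp_ramp = 0.02 + 0.6 * amplitude * (t / t[-1]) ** 2
    x = -amplitude + amp_ramp * (np.cos(phase_cup) - 1.0) / 2.0
    # ball: relative phase noisy in the first half, locked afterwards
    half = n // 2
    drift = np.cumsum(rng.normal(0.0, 0.12, size=n))
    lock_target = 0.0 if theta0_deg < 0 else np.pi
    rel = np.empty(n)
    rel[:half] = drift[:half] + rng.uniform(0, 2 * np.pi)
    # exponential settling onto the branch phase
    tau = max(3, n // 10)
    settle = np.exp(-np.arange(n - half) / tau)
    rel[half:] = lock_target + (rel[half - 1] - lock_target) * settle
    ball_amp_deg = abs(theta0_deg) * np.clip(t / (0.5 * t[-1]), 0.2, 1.0)
    theta = ball_amp_deg * np.cos(phase_cup - rel)
    # pin the final sample to the chosen initial angle
    theta[-1] = theta0_deg
    v = np.gradient(x, 1.0 / fs)
    omega = np.gradient(np.radians(theta), 1.0 / fs)
    return {"t": t, "x": x, "v": v, "theta_deg": theta, "omega": omega}


def generate_trial(
    participant: ParticipantModel,
    protocol: str,
    pendulum_length: float,
    choice: tuple[float, float],
    rng: np.random.Generator,
    cfg: CohortConfig | None = None,
) -> TrialRecord:
    """Synthesize one trial: preparation + simulated rhythmic stage.

    The rhythmic stage is a forward simulation of the plant at the chosen
    (theta0, f) under the impedance controller, resampled from the 10 ms
    integration grid to 120 Hz, with motor noise added to the applied
    force.  Grip force is baseline + uncertainty gain * sigma_l(protocol)
    + coupling * |F| + noise, ramping up through the preparation stage.
    """
    cfg = cfg or CohortConfig()
    theta0_deg, freq = choice
    prep_duration = (
        participant.prep_skill
        + (participant.prep_uncertainty_penalty if protocol == "random" else 0.0)
        + abs(rng.normal(0.0, participant.prep_jitter_sd))
    )
    fs = RECORDING_HZ
    prep = _synthesize_preparation(
        participant, protocol, choice, prep_duration, fs, cfg.amplitude, rng
    )
    params = SystemParams(pendulum_length=pendulum_length)
    ctrl = ControllerSpec(cfg.stiffness, cfg.damping, cfg.amplitude, freq)
    sim = simulate_trial(
        params, ctrl, math.radians(theta0_deg), duration=cfg.rhythmic_duration
    )
    # resample the 10 ms simulation onto the 120 Hz recording grid
    t_r = np.arange(0.0, cfg.rhythmic_duration, 1.0 / fs)
    rx = np.interp(t_r, sim.time, sim.cup_position)
    rv = np.interp(t_r, sim.time, sim.cup_velocity)
    rth = np.degrees(np.interp(t_r, sim.time, sim.ball_angle))
    rom = np.interp(t_r, sim.time, sim.ball_angular_velocity)
    rF = np.interp(t_r, sim.time, sim.applied_force)
    rF = rF + rng.normal(0.0, participant.motor_noise_sd, size=len(rF))

    n_prep = len(prep["t"])
    time = np.arange(n_prep + len(t_r)) / fs
    x = np.concatenate([prep["x"], rx])
    v = np.concatenate([prep["v"], rv])
    th_deg = np.concatenate([prep["theta_deg"], rth])
    om = np.concatenate([prep["omega"], rom])
    # preparation force: what a hand jiggling the cup must apply (plant inverse
    # on the cup equation, ball reaction folded in), plus motor noise
    a_prep = np.gradient(prep["v"], 1.0 / fs)
    F_prep = (params.cup_mass + params.ball_mass) * a_prep + rng.normal(
        0.0, participant.motor_noise_sd, size=n_prep
    )
    F = np.concatenate([F_prep, rF])

    sigma_l = PROTOCOL_LENGTH_SD[protocol]
    grip_level = (
        participant.grip_baseline
        + participant.grip_uncertainty_gain * sigma_l
        + participant.grip_force_coupling * np.abs(F)
    )
    ramp = np.clip(time / max(prep_duration, 1e-6), 0.3, 1.0)
    grip = grip_level * ramp + rng.normal(0.0, participant.grip_noise_sd, size=len(time))

    traj = Trajectory(
        time=time,
        cup_position=x,
        cup_velocity=v,
        ball_angle=np.radians(th_deg),
        ball_angular_velocity=om,
        applied_force=F,
        stage_boundary_index=n_prep,
        params=params,
        controller=ctrl,
    )
    # annotate the boundary under the analysis convention on the clean
    # kinematics (import here: metrics does not depend on this module)
    from cupball.metrics import BoundaryNotFoundError, parse_stages

    try:
        true_boundary = parse_stages(traj)
    except BoundaryNotFoundError:
        true_boundary = n_prep
    return TrialRecord(
        participant_id=participant.participant_id,
        protocol=protocol,
        pendulum_length=pendulum_length,
        theta0_deg=theta0_deg,
        freq_hz=freq,
        trajectory=traj,
        grip_force=grip,
        true_boundary_index=true_boundary,
        true_prep_duration=float(prep["t"][-1] + 1.0 / fs),
    )


def default_participants(cfg: CohortConfig, rng: np.random.Generator) -> list[ParticipantModel]:
    """A heterogeneous roster: a mix of in-phase, anti-phase and mixed
    preferences with individual frequency centers and skills."""
    branches = ["in-phase", "anti-phase", "mixed"]
    roster = []
    for pid in range(cfg.n_participants):
        roster.append(
            ParticipantModel(
                participant_id=pid,
                preferred_branch=branches[pid % 3],
                freq_center=float(rng.uniform(0.4, 0.7)),
                freq_spread=0.15,
                choice_temperature=float(rng.uniform(0.03, 0.08)),
                motor_noise_sd=float(rng.uniform(0.2, 0.5)),
                grip_baseline=float(rng.uniform(6.0, 10.0)),
                prep_skill=float(rng.uniform(3.0, 5.0)),
            )
        )
    return roster


def generate_cohort(
    cfg: CohortConfig,
    participants: list[ParticipantModel] | None = None,
    stability_maps: dict[float, StrategyMap] | None = None,
    grid: StrategyGrid | None = None,
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Full factorial cohort: participants x protocols x pendulums x trials.

    Returns the trial records and a manifest table (one row per trial,
    ChoiceSet-compatible columns).  Stability maps may be passed in to
    avoid recomputing the sweeps; otherwise they are computed once per
    pendulum on ``grid`` (default 19 x 15).
    """
    ss = np.random.SeedSequence(cfg.master_seed)
    roster_rng = np.random.default_rng(ss.spawn(1)[0])
    participants = participants or default_participants(cfg, roster_rng)
    if len(participants) != cfg.n_participants:
        raise ValueError("roster size does not match config")
    grid = grid or StrategyGrid.with_resolution(19, 15)
    # maps and masks are computed at the cohort's own controller settings so
    # the sampled strategies behave for the trials as simulated
    ctrl = ControllerSpec(cfg.stiffness, cfg.damping, cfg.amplitude, 0.5)
    if stability_maps is None:
        stability_maps = {
            l: sweep_stability(SystemParams(pendulum_length=l), grid, ctrl)
            for l in cfg.pendulum_lengths
        }
    feasible_masks = {
        l: feasible_strategies(SystemParams(pendulum_length=l), grid, ctrl)
        for l in cfg.pendulum_lengths
    }
    records: list[TrialRecord] = []
    rows = []
    trial_streams = ss.spawn(cfg.n_trials)
    k = 0
    for part in participants:
        for protocol in cfg.protocols:
            for l in cfg.pendulum_lengths:
                for trial in range(cfg.trials_per_condition):
                    rng = np.random.default_rng(trial_streams[k])
                    k += 1
                    choice = sample_choice(
                        part, l, stability_maps[l], rng, feasible_masks[l]
                    )
                    rec = generate_trial(part, protocol, l, choice, rng, cfg)
                    rec.trial_id = (
                        f"p{part.participant_id:02d}_{protocol}_l{l:g}_t{trial:03d}"
                    )
                    records.append(rec)
                    rows.append(
                        {
                            "trial_id": rec.trial_id,
                            "participant": part.participant_id,
                            "protocol": protocol,
                            "pendulum_m": l,
                            "theta0_deg": rec.theta0_deg,
                            "freq_hz": rec.freq_hz,
                            "prep_duration_s": rec.true_prep_duration,
                        }
                    )
    return records, pd.DataFrame(rows)
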