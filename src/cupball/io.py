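"""Delimited-text formats and configuration handling.

One dialect everywhere: comma-separated, UTF-8, header row, "." decimal.
Angles are degrees in every file (radians are internal only).  Each trial
CSV has a YAML metadata sidecar (``<name>.meta.yaml``) carrying the system
parameters, controller, sampling step and stage boundary.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cupball.cohort import TrialRecord
from cupball.dynamics import ControllerSpec, SystemParams, Trajectory
from cupball.landscapes import ChoiceSet, StrategyGrid, StrategyMap

__all__ = [
    "TrialFormatError",
    "write_trial",
    "read_trial",
    "write_map",
    "read_map",
    "write_choices",
    "read_choices",
    "load_config",
    "config_hash",
]

TRIAL_COLUMNS = [
    "time_s",
    "cup_pos_m",
    "cup_vel_m_s",
    "ball_angle_deg",
    "ball_vel_deg_s",
    "applied_force_N",
]


class TrialFormatError(ValueError):
    """A trial file violates the declared format."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_trial(record: TrialRecord | Trajectory, path: str | Path) -> Path:
    """Write a trial (trajectory + optional grip) and its metadata sidecar."""
    path = Path(path)
    if isinstance(record, TrialRecord):
        traj = record.trajectory
        grip = record.grip_force
    else:
        traj, grip = record, None
    df = pd.DataFrame(
        {
            "time_s": traj.time,
            "cup_pos_m": traj.cup_position,
            "cup_vel_m_s": traj.cup_velocity,
            "ball_angle_deg": np.degrees(traj.ball_angle),
            "ball_vel_deg_s": np.degrees(traj.ball_angular_velocity),
            "applied_force_N": traj.applied_force,
        }
    )
    if grip is not None:
        df["grip_force_N"] = grip
    df.to_csv(path, index=False, float_format="%.10g")
    meta: dict = {
        "dt_s": traj.dt,
        "stage_boundary_index": int(traj.stage_boundary_index),
    }
    if traj.params is not None:
        p = traj.params
        meta["system"] = {
            "cup_mass_kg": p.cup_mass,
            "ball_mass_kg": p.ball_mass,
            "pendulum_length_m": p.pendulum_length,
            "gravity_m_s2": p.gravity,
            "rim_angle_deg": float(np.degrees(p.rim_angle)),
        }
    if traj.controller is not None:
        c = traj.controller
        meta["controller"] = {
            "stiffness_N_m": c.stiffness,
            "damping_N_s_m": c.damping,
            "desired_amplitude_m": c.desired_amplitude,
            "desired_frequency_hz": c.desired_frequency,
            "phase_sign": c.phase_sign,
        }
    if isinstance(record, TrialRecord):
        meta["trial"] = {
            "trial_id": record.trial_id,
            "participant": int(record.participant_id),
            "protocol": record.protocol,
            "pendulum_length_m": record.pendulum_length,
            "theta0_deg": record.theta0_deg,
            "freq_hz": record.freq_hz,
            "true_boundary_index": int(record.true_boundary_index),
            "true_prep_duration_s": record.true_prep_duration,
        }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_trial(path: str | Path) -> TrialRecord:
    """Read a trial CSV (+ sidecar when present); columns matched by name.

    Raises :class:`TrialFormatError` on missing columns or a non-uniform /
    non-monotone time grid.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path.name}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise TrialFormatError(f"{path.name}: need at least 2 samples")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise TrialFormatError(f"{path.name}: time column not strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise TrialFormatError(f"{path.name}: non-uniform time grid")

    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
    params = None
    if "system" in meta:
        s = meta["system"]
        params = SystemParams(
            cup_mass=s["cup_mass_kg"],
            ball_mass=s["ball_mass_kg"],
            pendulum_length=s["pendulum_length_m"],
            gravity=s["gravity_m_s2"],
            rim_angle=float(np.radians(s["rim_angle_deg"])),
        )
    ctrl = None
    if "controller" in meta:
        c = meta["controller"]
        ctrl = ControllerSpec(
            stiffness=c["stiffness_N_m"],
            damping=c["damping_N_s_m"],
            desired_amplitude=c["desired_amplitude_m"],
            desired_frequency=c["desired_frequency_hz"],
            phase_sign=c.get("phase_sign", -1),
        )
    traj = Trajectory(
        time=t,
        cup_position=df["cup_pos_m"].to_numpy(dtype=float),
        cup_velocity=df["cup_vel_m_s"].to_numpy(dtype=float),
        ball_angle=np.radians(df["ball_angle_deg"].to_numpy(dtype=float)),
        ball_angular_velocity=np.radians(df["ball_vel_deg_s"].to_numpy(dtype=float)),
        applied_force=df["applied_force_N"].to_numpy(dtype=float),
        stage_boundary_index=int(meta.get("stage_boundary_index", 0)),
        params=params,
        controller=ctrl,
    )
    grip = (
        df["grip_force_N"].to_numpy(dtype=float) if "grip_force_N" in df.columns else None
    )
    tr = meta.get("trial", {})
    return TrialRecord(
        participant_id=int(tr.get("participant", -1)),
        protocol=tr.get("protocol", "unknown"),
        pendulum_length=float(
            tr.get("pendulum_length_m",
                   params.pendulum_length if params else float("nan"))
        ),
        theta0_deg=float(tr.get("theta0_deg", float("nan"))),
        freq_hz=float(tr.get("freq_hz", float("nan"))),
        trajectory=traj,
        grip_force=grip if grip is not None else np.full(len(t), np.nan),
        true_boundary_index=int(tr.get("true_boundary_index", traj.stage_boundary_index)),
        true_prep_duration=float(tr.get("true_prep_duration_s", float("nan"))),
        trial_id=tr.get("trial_id", path.stem),
    )


def write_map(strategy_map: StrategyMap, path: str | Path) -> Path:
    """Long-form heatmap CSV: theta0_deg, freq_hz, value (+ sidecar)."""
    path = Path(path)
    th, fr = strategy_map.grid.mesh()
    df = pd.DataFrame(
        {
            "theta0_deg": th.ravel(),
            "freq_hz": fr.ravel(),
            "value": strategy_map.values.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {
        "metric": strategy_map.metric,
        "pendulum_length_m": strategy_map.pendulum_length,
        "n_theta": len(strategy_map.grid.theta0_deg),
        "n_freq": len(strategy_map.grid.freq_hz),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_map(path: str | Path) -> StrategyMap:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("theta0_deg", "freq_hz", "value"):
        if col not in df.columns:
            raise TrialFormatError(f"{path.name}: missing column {col}")
    theta = np.unique(df["theta0_deg"])
    freq = np.unique(df["freq_hz"])
    grid = StrategyGrid(theta, freq)
    piv = df.pivot_table(index="theta0_deg", columns="freq_hz", values="value")
    values = piv.reindex(index=theta, columns=freq).to_numpy()
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
    return StrategyMap(
        grid,
        meta.get("metric", "unknown"),
        values,
        meta.get("pendulum_length_m"),
    )


def write_choices(choices: ChoiceSet | pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    if isinstance(choices, ChoiceSet):
        df = pd.DataFrame(
            {
                "participant": choices.participant,
                "protocol": choices.protocol,
                "pendulum_m": choices.pendulum_length,
                "theta0_deg": choices.theta0_deg,
                "freq_hz": choices.freq_hz,
            }
        )
    else:
        df = choices
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_choices(path: str | Path) -> ChoiceSet:
    df = pd.read_csv(path)
    for col in ("theta0_deg", "freq_hz"):
        if col not in df.columns:
            raise TrialFormatError(f"{Path(path).name}: missing column {col}")
    return ChoiceSet(
        theta0_deg=df["theta0_deg"].to_numpy(dtype=float),
        freq_hz=df["freq_hz"].to_numpy(dtype=float),
        participant=df["participant"].to_numpy() if "participant" in df else None,
        protocol=df["protocol"].to_numpy() if "protocol" in df else None,
        pendulum_length=df["pendulum_m"].to_numpy(dtype=float)
        if "pendulum_m" in df
        else None,
    )


# --- configuration ---------------------------------------------------------

_CONFIG_SECTIONS = {"system", "controller", "grid", "sooc", "cohort", "pipeline", "seed"}


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration; unknown top-level sections rejected."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise TrialFormatError("config root must be a mapping")
    unknown = set(doc) - _CONFIG_SECTIONS
    if unknown:
        raise TrialFormatError(f"unknown config sections: {sorted(unknown)}")
    return doc


def config_hash(doc: dict) -> str:
    """Stable short hash of a resolved configuration (for provenance logs)."""
    blob = yaml.safe_dump(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
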