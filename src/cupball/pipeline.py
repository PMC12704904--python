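"""Per-trial analysis and the end-to-end pipeline.

``analyze_trial`` turns one trial into the row of dependent measures the
behavioural analysis uses; ``run_pipeline`` chains synthetic-cohort
generation, per-trial analysis, landscape sweeps, KL comparison and one
SOOC run per protocol into an artifact directory with a provenance record.
"""

from __future__ import annotations

import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from cupball import io, landscapes, metrics, sooc
from cupball.cohort import (
    CohortConfig,
    TrialRecord,
    generate_cohort,
)
from cupball.dynamics import SystemParams
from cupball.landscapes import ChoiceSet, StrategyGrid, sweep_all

log = logging.getLogger("cupball")

ANALYSIS_COLUMNS = [
    "trial_id",
    "protocol",
    "pendulum_m",
    "prep_duration_s",
    "time_to_stable_s",
    "init_ball_angle_deg",
    "mean_freq_hz",
    "rel_phase_var",
    "mean_abs_force_N",
    "ldj_force",
    "risk",
    "mean_grip_N",
]


def analyze_trial(record: TrialRecord) -> dict:
    """All per-trial dependent measures as one table row.

    The stage boundary is re-detected from the kinematics (the generator's
    annotation is ground truth for validation, not an input here).
    """
    traj = record.trajectory
    dt = traj.dt
    try:
        boundary = metrics.parse_stages(traj)
    except metrics.BoundaryNotFoundError:
        boundary = traj.stage_boundary_index
    prep_s = metrics.preparation_duration(traj, boundary)
    if boundary >= 2 and prep_s >= 1.0:
        tts, _stable_flag = metrics.time_to_stable_phase(traj, boundary_index=boundary)
    else:
        tts = float("nan")
    rhythm = slice(boundary, len(traj.time))
    cup = traj.cup_position[rhythm]
    ball = traj.ball_angle[rhythm]
    stab = metrics.relative_phase_variability(cup, ball, dt)
    freq = metrics.instantaneous_frequency(cup, dt, freq_hint=record.freq_hz or None)
    F = traj.applied_force[rhythm]
    risk = metrics.risk_of_escape(
        ball, traj.ball_angular_velocity[rhythm], traj.params, dt
    )
    grip = record.grip_force
    return {
        "trial_id": record.trial_id,
        "protocol": record.protocol,
        "pendulum_m": record.pendulum_length,
        "prep_duration_s": prep_s,
        "time_to_stable_s": tts,
        "init_ball_angle_deg": float(np.degrees(traj.ball_angle[boundary])),
        "mean_freq_hz": float(np.mean(freq)),
        "rel_phase_var": stab.circular_variance,
        "mean_abs_force_N": metrics.mean_absolute_force(F),
        "ldj_force": metrics.log_dimensionless_jerk(F, dt),
        "risk": risk.risk,
        "mean_grip_N": float(np.nanmean(grip)),
    }


def analyze_records(records: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([analyze_trial(r) for r in records], columns=ANALYSIS_COLUMNS)


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Protocol x pendulum means of the per-trial measures."""
    return (
        table.groupby(["protocol", "pendulum_m"])
        .agg(
            n=("trial_id", "count"),
            prep_duration_s=("prep_duration_s", "mean"),
            time_to_stable_s=("time_to_stable_s", "mean"),
            rel_phase_var=("rel_phase_var", "mean"),
            mean_abs_force_N=("mean_abs_force_N", "mean"),
            mean_grip_N=("mean_grip_N", "mean"),
        )
        .reset_index()
    )


def run_pipeline(
    out_dir: str | Path,
    cohort_cfg: CohortConfig | None = None,
    grid: StrategyGrid | None = None,
    sooc_maxiter: int = 60,
    write_trials: bool = False,
) -> Path:
    """synth -> analyze -> sweep -> compare -> sooc, with cached heatmaps.

    Produces under ``out_dir``: the cohort manifest, the per-trial metrics
    table, a cohort summary, one heatmap CSV per (metric, pendulum), a KL
    comparison table, one SOOC solution CSV per protocol, and
    ``provenance.json``.  Existing heatmap CSVs matching the grid are
    reused instead of recomputed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = cohort_cfg or CohortConfig(n_participants=3, trials_per_condition=5)
    grid = grid or StrategyGrid.with_resolution(19, 15)
    provenance: dict = {
        "master_seed": cohort_cfg.master_seed,
        "stages": {},
        "config_hash": io.config_hash(
            {
                "cohort": {
                    "n_participants": cohort_cfg.n_participants,
                    "trials_per_condition": cohort_cfg.trials_per_condition,
                    "protocols": list(cohort_cfg.protocols),
                    "pendulums": list(cohort_cfg.pendulum_lengths),
                    "master_seed": cohort_cfg.master_seed,
                },
                "grid": {"shape": list(grid.shape)},
            }
        ),
    }

    def stage(name):
        t0 = _time.time()

        def done(**extra):
            provenance["stages"][name] = {
                "seconds": round(_time.time() - t0, 2),
                **extra,
            }
            log.info("stage %s finished in %.1f s", name, _time.time() - t0)

        return done

    # sweep (first: the cohort samples choices from the stability maps);
    # maps are computed at the cohort's controller settings so the sampled
    # strategies are stable for the trials as simulated
    done = stage("sweep")
    from cupball.dynamics import ControllerSpec

    ctrl = ControllerSpec(
        cohort_cfg.stiffness, cohort_cfg.damping, cohort_cfg.amplitude, 0.5
    )
    maps_by_length: dict[float, dict] = {}
    cached = 0
    for l in cohort_cfg.pendulum_lengths:
        maps = {}
        params = SystemParams(pendulum_length=l)
        for metric in ("rel_phase_var", *landscapes.COST_METRICS):
            path = out / f"map_{metric}_l{l:g}.csv"
            if path.exists():
                m = io.read_map(path)
                if m.grid.shape == grid.shape:
                    maps[metric] = m
                    cached += 1
                    continue
            if metric == "rel_phase_var":
                m = landscapes.sweep_stability(params, grid, ctrl)
            else:
                m = landscapes.sweep_cost(params, grid, metric, ctrl)
            io.write_map(m, path)
            maps[metric] = m
        maps_by_length[l] = maps
    done(cached_maps=cached)

    # synth
    done = stage("synth")
    records, manifest = generate_cohort(
        cohort_cfg,
        stability_maps={l: m["rel_phase_var"] for l, m in maps_by_length.items()},
        grid=grid,
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    if write_trials:
        trial_dir = out / "trials"
        trial_dir.mkdir(exist_ok=True)
        for rec in records:
            io.write_trial(rec, trial_dir / f"{rec.trial_id}.csv")
    done(n_trials=len(records))

    # analyze
    done = stage("analyze")
    table = analyze_records(records)
    table.to_csv(out / "trial_metrics.csv", index=False)
    cohort_summary(table).to_csv(out / "cohort_summary.csv", index=False)
    done()

    # compare
    done = stage("compare")
    rows = []
    for l, maps in maps_by_length.items():
        sel = manifest[manifest.pendulum_m == l]
        choices = ChoiceSet(
            theta0_deg=sel.theta0_deg.to_numpy(),
            freq_hz=sel.freq_hz.to_numpy(),
        )
        kls = landscapes.rank_objectives(choices, maps)
        for metric, kl in kls.items():
            rows.append({"pendulum_m": l, "metric": metric, "kl_nats": kl})
    pd.DataFrame(rows).to_csv(out / "kl_table.csv", index=False)
    done()

    # sooc: one run per protocol at the default strategy
    done = stage("sooc")
    for protocol in cohort_cfg.protocols:
        if protocol == "random":
            unc = sooc.UncertaintySpec.random_protocol()
        else:
            unc = sooc.UncertaintySpec.blocked_protocol(0.6)
        cfg = sooc.SOOCConfig(uncertainty=unc)
        sol = sooc.optimize(cfg, maxiter=sooc_maxiter)
        df = pd.DataFrame(
            {
                "time_s": sol.time,
                **{f"m{i+1}": sol.mean[:, i] for i in range(9)},
                "stiffness_N_m": sol.stiffness,
                "feedforward_N": sol.feedforward_force,
                **{f"P{i+1}{i+1}": sol.cov[:, i, i] for i in range(9)},
            }
        )
        df.to_csv(out / f"sooc_{protocol}.csv", index=False, float_format="%.8g")
        (out / f"sooc_{protocol}_report.json").write_text(
            json.dumps(
                {
                    "converged": sol.converged,
                    "message": sol.message,
                    "iterations": sol.n_iter,
                    "cost": sol.cost,
                    "mean_rhythmic_stiffness": sol.mean_rhythmic_stiffness(),
                },
                indent=2,
            )
        )
    done()

    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out
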