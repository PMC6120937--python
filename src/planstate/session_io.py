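"""Read/write synthetic sessions as a plain-text directory.

Layout::

    <session>/
      config.yaml       # PopulationSpec + TaskConfig + generation metadata
      population.json   # ground-truth per-unit tuning parameters
      trials.csv        # one row per trial (column dictionary below)
      latent_plans.csv  # trial_id, bin_index, plan_direction, strength
      spikes.csv        # unit_id, trial_id, time_ms
      kinematics.csv    # trial_id, time_ms, x_cm, y_cm, speed_cm_s

trials.csv columns: trial_id, condition, target_dir, opposite_dir (empty
for 1-Target), cue_direction, target_on_ms, blank_on_ms, cue_on_ms,
cue_off_ms, go_ms, end_ms, choice, correct, error_type, plan_strength.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_data import (
    KinematicsTrace,
    PopulationModel,
    PopulationSpec,
    Session,
    SpikeData,
    TaskConfig,
    TrialRecord,
)


def write_session(session: Session, out_dir: str | Path) -> Path:
    """Write a session to a directory of CSV/JSON/YAML files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cfg = {
        "population_spec": dataclasses.asdict(session.population.spec),
        "task_config": dataclasses.asdict(session.task_config),
        "encoding": session.encoding,
    }
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))

    pop = session.population
    (out / "population.json").write_text(
        json.dumps(
            {
                "a": pop.a.tolist(),
                "b": pop.b.tolist(),
                "phi": pop.phi.tolist(),
                "kappa": pop.kappa.tolist(),
                "sqrt_base": pop.sqrt_base.tolist(),
                "sqrt_depth": pop.sqrt_depth.tolist(),
                "sqrt_depth_move": pop.sqrt_depth_move.tolist(),
                "phi_move": pop.phi_move.tolist(),
            },
            indent=1,
        )
    )

    rows = []
    plan_rows = []
    for t in session.trials:
        rows.append(
            {
                "trial_id": t.trial_id,
                "condition": t.condition,
                "target_dir": t.target_pair[0],
                "opposite_dir": t.target_pair[1] if len(t.target_pair) == 2 else "",
                "cue_direction": "" if t.cue_direction is None else t.cue_direction,
                "target_on_ms": t.target_on_ms,
                "blank_on_ms": t.blank_on_ms,
                "cue_on_ms": "" if t.cue_on_ms is None else t.cue_on_ms,
                "cue_off_ms": "" if t.cue_off_ms is None else t.cue_off_ms,
                "go_ms": t.go_ms,
                "end_ms": t.end_ms,
                "choice": t.choice,
                "correct": int(t.correct),
                "error_type": t.error_type,
                "plan_strength": t.plan_strength,
            }
        )
        prof = (
            t.strength_profile
            if t.strength_profile is not None
            else np.full(t.n_bins, t.plan_strength)
        )
        for k in range(t.n_bins):
            plan_rows.append(
                {
                    "trial_id": t.trial_id,
                    "bin_index": k,
                    "plan_direction": int(t.latent_plan[k]),
                    "strength": float(prof[k]),
                }
            )
    pd.DataFrame(rows).to_csv(out / "trials.csv", index=False)
    pd.DataFrame(plan_rows).to_csv(out / "latent_plans.csv", index=False)

    spike_frames = []
    for tid in session.spikes.trial_ids():
        for u, ts in enumerate(session.spikes.spikes[tid]):
            if ts.size:
                spike_frames.append(
                    pd.DataFrame(
                        {"unit_id": u, "trial_id": tid, "time_ms": np.round(ts, 6)}
                    )
                )
    pd.concat(spike_frames, ignore_index=True).to_csv(
        out / "spikes.csv", index=False
    )

    kin_frames = []
    for tid, k in session.kinematics.items():
        kin_frames.append(
            pd.DataFrame(
                {
                    "trial_id": tid,
                    "time_ms": k.t_ms,
                    "x_cm": np.round(k.position_cm[:, 0], 5),
                    "y_cm": np.round(k.position_cm[:, 1], 5),
                    "speed_cm_s": np.round(k.speed_cm_s, 5),
                }
            )
        )
    pd.concat(kin_frames, ignore_index=True).to_csv(
        out / "kinematics.csv", index=False
    )
    return out


def read_session(session_dir: str | Path) -> Session:
    """Load a session directory written by :func:`write_session`.

    Kinematic ground-truth fields that are not stored (rt_ms, move_end_ms)
    are reconstructed as NaN; the speed threshold analysis recomputes RT
    from the traces anyway.
    """
    d = Path(session_dir)
    cfg = yaml.safe_load((d / "config.yaml").read_text())
    pop_spec = PopulationSpec(**cfg["population_spec"])
    task_cfg = cfg["task_config"]
    for key in ("target_on_range_ms", "blank_range_ms", "cue_range_ms",
                "return_range_ms", "plan_strength_range",
                "one_target_strength_range"):
        task_cfg[key] = tuple(task_cfg[key])
    task_cfg["trial_mix"] = dict(task_cfg["trial_mix"])
    task_cfg["error_rates"] = {int(k): v for k, v in task_cfg["error_rates"].items()}
    task_config = TaskConfig(**task_cfg)

    pj = json.loads((d / "population.json").read_text())
    population = PopulationModel(
        a=np.array(pj["a"]),
        b=np.array(pj["b"]),
        phi=np.array(pj["phi"]),
        kappa=np.array(pj["kappa"]),
        sqrt_base=np.array(pj["sqrt_base"]),
        sqrt_depth=np.array(pj["sqrt_depth"]),
        sqrt_depth_move=np.array(pj["sqrt_depth_move"]),
        phi_move=np.array(pj["phi_move"]),
        spec=pop_spec,
    )

    trials_df = pd.read_csv(d / "trials.csv")
    plans = pd.read_csv(d / "latent_plans.csv")
    plan_by_trial = {
        tid: g.sort_values("bin_index") for tid, g in plans.groupby("trial_id")
    }
    trials = []
    for _, r in trials_df.iterrows():
        g = plan_by_trial[r.trial_id]
        pair = (
            (int(r.target_dir),)
            if pd.isna(r.opposite_dir) or r.opposite_dir == ""
            else (int(r.target_dir), int(float(r.opposite_dir)))
        )
        trials.append(
            TrialRecord(
                trial_id=int(r.trial_id),
                condition=r.condition,
                target_pair=pair,
                cue_direction=None if pd.isna(r.cue_direction) else int(r.cue_direction),
                target_on_ms=float(r.target_on_ms),
                blank_on_ms=float(r.blank_on_ms),
                cue_on_ms=None if pd.isna(r.cue_on_ms) else float(r.cue_on_ms),
                cue_off_ms=None if pd.isna(r.cue_off_ms) else float(r.cue_off_ms),
                go_ms=float(r.go_ms),
                end_ms=float(r.end_ms),
                latent_plan=g.plan_direction.to_numpy(np.int8),
                choice=int(r.choice),
                correct=bool(r.correct),
                error_type=int(r.error_type),
                plan_strength=float(r.plan_strength),
                strength_profile=g.strength.to_numpy(float),
            )
        )

    spikes_df = pd.read_csv(d / "spikes.csv")
    n_units = population.n_units
    spike_dict: dict[int, list[np.ndarray]] = {
        t.trial_id: [np.empty(0) for _ in range(n_units)] for t in trials
    }
    for (tid, uid), g in spikes_df.groupby(["trial_id", "unit_id"]):
        spike_dict[tid][uid] = np.sort(g.time_ms.to_numpy(float))
    spikes = SpikeData(unit_ids=np.arange(n_units), spikes=spike_dict)

    kin_df = pd.read_csv(d / "kinematics.csv")
    kinematics = {}
    for tid, g in kin_df.groupby("trial_id"):
        g = g.sort_values("time_ms")
        kinematics[tid] = KinematicsTrace(
            trial_id=int(tid),
            t_ms=g.time_ms.to_numpy(float),
            position_cm=g[["x_cm", "y_cm"]].to_numpy(float),
            speed_cm_s=g.speed_cm_s.to_numpy(float),
            rt_ms=np.nan,
            move_end_ms=np.nan,
        )

    return Session(
        population=population,
        trials=trials,
        spikes=spikes,
        kinematics=kinematics,
        task_config=task_config,
        encoding=cfg.get("encoding", "single"),
    )
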