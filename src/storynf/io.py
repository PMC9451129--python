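"""Serialization: TSV tables, JSON sidecars, BIDS-style session logs.

Session logs are written as BIDS-inspired events TSVs (one row per
probe and per feedback display, with onsets in seconds) plus a JSON
sidecar carrying participant, group, seed, mode, the final agent state
and the experiment config digest, so any output can be traced back to
the exact configuration that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .agent import AgentState
from .cohort import StationSpec, TemplatePair
from .decoder import StationModel
from .feedback import FeedbackEvent, PilotNorms, TimingConfig
from .session import ProbeEvent, SessionLog


# ---------------------------------------------------------------- cohorts

def save_cohort(df: pd.DataFrame, meta: dict, prefix: str | Path) -> Path:
    """Write a pattern table as <prefix>.tsv with a <prefix>.json sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return prefix.with_suffix(".tsv")


def load_cohort(prefix: str | Path) -> tuple[pd.DataFrame, dict]:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return df, meta


def templates_to_dict(templates: TemplatePair) -> dict:
    return {
        "template_cheating": templates.template_cheating.tolist(),
        "template_paranoid": templates.template_paranoid.tolist(),
        "direction": templates.direction.tolist(),
        "separation": templates.separation,
    }


def templates_from_dict(d: dict) -> TemplatePair:
    return TemplatePair(
        template_cheating=np.array(d["template_cheating"]),
        template_paranoid=np.array(d["template_paranoid"]),
        direction=np.array(d["direction"]),
        separation=float(d["separation"]),
    )


def stations_to_list(stations: list[StationSpec]) -> list[dict]:
    return [
        {
            "station_index": s.station_index,
            "start_tr": s.start_tr,
            "n_trs": s.n_trs,
            "bias": s.bias,
        }
        for s in stations
    ]


def stations_from_list(items: list[dict]) -> list[StationSpec]:
    return [StationSpec(**it) for it in items]


# ----------------------------------------------------------------- models

def save_models(models: list[StationModel], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [
        {
            "station_index": m.station_index,
            "weights": m.weights.tolist(),
            "intercept": m.intercept,
            "regularization_c": m.regularization_c,
            "training_digest": m.training_digest,
        }
        for m in models
    ]
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_models(path: str | Path) -> list[StationModel]:
    payload = json.loads(Path(path).read_text())
    return [
        StationModel(
            station_index=int(m["station_index"]),
            weights=np.array(m["weights"]),
            intercept=float(m["intercept"]),
            regularization_c=float(m["regularization_c"]),
            training_digest=m.get("training_digest", ""),
        )
        for m in payload
    ]


# ------------------------------------------------------------------ norms

def save_norms(norms: PilotNorms, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"station": range(norms.n_stations), "mu": norms.mu, "sigma": norms.sigma}
    ).to_csv(path, sep="\t", index=False)
    return path


def load_norms(path: str | Path) -> PilotNorms:
    df = pd.read_csv(path, sep="\t").sort_values("station")
    return PilotNorms(mu=df["mu"].to_numpy(), sigma=df["sigma"].to_numpy())


# ----------------------------------------------------------- session logs

def session_dir(out_dir: str | Path, participant_id: str) -> Path:
    return Path(out_dir) / participant_id / "ses-01"


def save_session_log(
    log: SessionLog,
    out_dir: str | Path,
    timing: TimingConfig | None = None,
    config_digest: str = "",
) -> Path:
    """Write one session as BIDS-style events TSV + JSON sidecar."""
    timing = timing or TimingConfig()
    d = session_dir(out_dir, log.participant_id)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in log.probes:
        rows.append(
            {
                "onset": p.onset_seconds + (p.run - 1) * timing.run_n_trs * timing.tr_seconds,
                "duration": 0.0,
                "trial_type": "probe",
                "run": p.run,
                "station": p.station_index,
                "probe_choice": p.choice,
                "p_c": "n/a", "score_c": "n/a", "score_final": "n/a",
                "score_reward": "n/a", "delivered_reward": "n/a",
                "payout": "n/a", "yoked_fallback": "n/a",
            }
        )
    for e in log.events:
        onset = (e.feedback_onset_tr + (e.run - 1) * timing.run_n_trs) * timing.tr_seconds
        rows.append(
            {
                "onset": onset,
                "duration": 0.0,
                "trial_type": "feedback",
                "run": e.run,
                "station": e.station_index,
                "probe_choice": e.probe_choice,
                "p_c": e.p_c,
                "score_c": e.score_c,
                "score_final": e.score_final,
                "score_reward": e.score_reward,
                "delivered_reward": e.delivered_reward,
                "payout": round(e.payout, 4),
                "yoked_fallback": int(e.yoked_fallback),
            }
        )
    events = pd.DataFrame(rows).sort_values(["onset", "trial_type"], kind="stable")
    tsv = d / f"{log.participant_id}_task-story_events.tsv"
    events.to_csv(tsv, sep="\t", index=False)
    fs = log.final_state
    sidecar = {
        "participant_id": log.participant_id,
        "assigned_group": log.assigned_group,
        "seed": log.seed,
        "mode": log.mode,
        "config_digest": config_digest,
        "final_state": None
        if fs is None
        else {
            "theta": fs.theta,
            "learning_rate": fs.learning_rate,
            "probe_temperature": fs.probe_temperature,
            "snr": fs.snr,
        },
        "tr_seconds": timing.tr_seconds,
        "run_n_trs": timing.run_n_trs,
    }
    (d / f"{log.participant_id}_task-story_events.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True)
    )
    return tsv


def load_session_log(events_tsv: str | Path) -> SessionLog:
    """Rebuild a SessionLog from an events TSV and its sidecar."""
    events_tsv = Path(events_tsv)
    sidecar = json.loads(events_tsv.with_suffix(".json").read_text())
    df = pd.read_csv(events_tsv, sep="\t", na_values=["n/a"])
    tr = float(sidecar.get("tr_seconds", 1.5))
    run_n_trs = int(sidecar.get("run_n_trs", 480))
    fs = sidecar.get("final_state")
    log = SessionLog(
        participant_id=sidecar["participant_id"],
        assigned_group=sidecar["assigned_group"],
        seed=int(sidecar["seed"]),
        mode=sidecar.get("mode", "live"),
        final_state=None if fs is None else AgentState(**fs),
    )
    run_len_s = None
    for _, r in df.iterrows():
        run = int(r["run"])
        if r["trial_type"] == "probe":
            log.probes.append(
                ProbeEvent(run, int(r["station"]), r["probe_choice"], float(r["onset"]))
            )
        else:
            log.events.append(
                FeedbackEvent(
                    run=run,
                    station_index=int(r["station"]),
                    p_c=float(r["p_c"]),
                    score_c=float(r["score_c"]),
                    score_final=float(r["score_final"]),
                    score_reward=float(r["score_reward"]),
                    payout=float(r["payout"]),
                    probe_choice=r["probe_choice"],
                    feedback_onset_tr=int(round(float(r["onset"]) / tr)) - (run - 1) * run_n_trs,
                    delivered_reward=float(r["delivered_reward"]),
                    yoked_fallback=bool(int(r["yoked_fallback"])),
                )
            )
    return log


def find_session_logs(out_dir: str | Path) -> list[Path]:
    return sorted(Path(out_dir).glob("sub-*/ses-01/*_events.tsv"))


# --------------------------------------------------------------- behavior

def save_behavior(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
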