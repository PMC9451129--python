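"""End-to-end pipeline: templates -> training -> decoders -> pilot norms
-> closed-loop sessions -> questionnaires -> behavioral scores -> group
analysis, all driven by one :class:`ExperimentConfig` and one seed.

In yoked mode every participant first completes a live session; each is
then re-simulated receiving the feedback of the next same-group
participant's live session (rotation within group), the control design
in which individualized feedback is replaced by a matched donor's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agent import AgentState
from .analysis import (
    ParticipantSummary,
    aggregate,
    group_ttest,
    median_split,
    pearson_r,
    summarize_participant,
)
from .behavior import BehaviorScores, score_questionnaire
from .cohort import (
    CohortConfig,
    generate_pilot_cohort,
    generate_questionnaire,
    generate_training_cohort,
    make_templates,
)
from .config import ExperimentConfig
from .decoder import train_station_models
from .feedback import compute_payout, estimate_pilot_norms
from .io import (
    save_behavior,
    save_cohort,
    save_models,
    save_norms,
    save_session_log,
    stations_to_list,
    templates_to_dict,
)
from .rngs import CHEATING, substream
from .session import SessionLog, run_session, run_yoked_session


@dataclass
class ExperimentResult:
    """In-memory results of one full simulated experiment."""

    config: ExperimentConfig
    logs: list[SessionLog]
    donor_logs: list[SessionLog] | None
    behaviors: dict[str, BehaviorScores]
    summaries: list[ParticipantSummary]
    split: dict[str, str]
    stats: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _draw_agents(config: ExperimentConfig) -> list[AgentState]:
    rng = substream(config.seed, "agent-params")
    lo_s, hi_s = config.agent.snr_range
    lo_l, hi_l = config.agent.learning_rate_range
    return [
        AgentState(
            theta=config.agent.initial_theta,
            learning_rate=float(rng.uniform(lo_l, hi_l)),
            probe_temperature=config.agent.probe_temperature,
            snr=float(rng.uniform(lo_s, hi_s)),
        )
        for _ in range(config.n_participants)
    ]


def build_assets(config: ExperimentConfig):
    """Templates, trained station models and pilot norms for a config."""
    stations = config.stations()
    templates = make_templates(
        config.n_features, config.separation, int(substream(config.seed, "templates").integers(2**31))
    )
    training = generate_training_cohort(config.training_cohort(), templates, stations)
    models = train_station_models(training, config.regularization_c)
    pilot = generate_pilot_cohort(config.pilot_cohort(), templates, stations, models)
    norms = estimate_pilot_norms(pilot, config.sd_mode)
    return stations, templates, training, models, pilot, norms


def simulate_sessions(config: ExperimentConfig, models, norms, templates, stations):
    """Run the closed-loop cohort; returns (logs, donor_logs_or_None)."""
    groups = CohortConfig(
        n_participants=config.n_participants, n_runs=config.n_runs
    ).groups()
    agents = _draw_agents(config)
    seeds = substream(config.seed, "session-seeds").integers(2**31, size=config.n_participants)

    live_logs = []
    for i, (group, state) in enumerate(zip(groups, agents)):
        pid = f"sub-{i + 1:02d}"
        live_logs.append(
            run_session(
                pid, group, state, models, norms, templates, stations,
                timing=config.timing, n_runs=config.n_runs,
                seed=int(seeds[i]), reward_cap=config.reward_cap,
            )
        )
    if config.mode == "live":
        return live_logs, None

    # yoked: donor = next same-group participant's live session
    by_group: dict[str, list[int]] = {}
    for i, g in enumerate(groups):
        by_group.setdefault(g, []).append(i)
    donor_of = {}
    for g, idxs in by_group.items():
        for k, i in enumerate(idxs):
            donor_of[i] = idxs[(k + 1) % len(idxs)]
    yoked_logs = []
    for i, (group, state) in enumerate(zip(groups, agents)):
        pid = f"sub-{i + 1:02d}"
        yoked_logs.append(
            run_yoked_session(
                pid, group, state, live_logs[donor_of[i]], models, norms,
                templates, stations, timing=config.timing,
                n_runs=config.n_runs, seed=int(seeds[i]),
                reward_cap=config.reward_cap,
            )
        )
    return yoked_logs, live_logs


def score_cohort_behavior(config: ExperimentConfig, logs: list[SessionLog]):
    """Generate and score each agent's post-scan questionnaire."""
    behaviors: dict[str, BehaviorScores] = {}
    for log in logs:
        rng = substream(log.seed, f"{log.participant_id}-questionnaire")
        resp = generate_questionnaire(log.final_state, log.assigned_group, rng)
        behaviors[log.participant_id] = score_questionnaire(resp, log.assigned_group)
    return behaviors


def analyze_cohort(
    logs: list[SessionLog],
    behaviors: dict[str, BehaviorScores],
    odd_policy: str = "extra_best",
) -> tuple[list[ParticipantSummary], dict[str, str], dict, dict[str, pd.DataFrame]]:
    """Participant summaries, median split, headline stats and tidy tables.

    Participants whose decoding accuracy is undefined (a probe label
    never chosen) are flagged in the stats and excluded from the split
    and the accuracy-based statistics, never silently dropped from the
    tables.
    """
    summaries = [summarize_participant(log, behaviors[log.participant_id]) for log in logs]
    defined = [s for s in summaries if s.accuracy_defined]
    flagged = [s.participant_id for s in summaries if not s.accuracy_defined]
    split = median_split(defined, odd_policy=odd_policy)

    acc = [s.decoding_accuracy for s in defined]
    correct_interp = [s.behavior.correct_interpretation for s in defined]
    groups = [s.assigned_group for s in summaries]
    comp = [s.behavior.comprehension for s in summaries]
    interp = [s.behavior.interpretation for s in summaries]
    ediff = [s.behavior.empathy_diff for s in summaries]

    try:
        r_acc, p_acc = pearson_r(acc, correct_interp)
    except ValueError:  # zero variance in a small or fully converged cohort
        r_acc, p_acc = float("nan"), float("nan")
    t_comp, df_comp, p_comp = group_ttest(comp, groups)
    t_int, df_int, p_int = group_ttest(
        interp, groups, tails="one", direction="greater",
        group_order=(CHEATING, "paranoid"),
    )
    t_emp, df_emp, p_emp = group_ttest(
        ediff, groups, tails="one", direction="greater",
        group_order=(CHEATING, "paranoid"),
    )
    stats = {
        "decoding_accuracy_vs_correct_interpretation": {"r": r_acc, "p": p_acc},
        "comprehension_by_group": {"t": t_comp, "df": df_comp, "p": p_comp},
        "interpretation_by_group_one_tailed": {"t": t_int, "df": df_int, "p": p_int},
        "empathy_diff_by_group_one_tailed": {"t": t_emp, "df": df_emp, "p": p_emp},
        "mean_decoding_accuracy": float(np.mean(acc)),
        "undefined_decoding_accuracy": flagged,
    }

    behavior_rows = [
        {
            "participant": s.participant_id,
            "group": s.assigned_group,
            "split": split.get(s.participant_id, "undefined"),
            "decoding_accuracy": s.decoding_accuracy,
            "comprehension": s.behavior.comprehension,
            "interpretation": s.behavior.interpretation,
            "correct_interpretation": s.behavior.correct_interpretation,
            "empathy_diff": s.behavior.empathy_diff,
            "correct_empathy": s.behavior.correct_empathy,
        }
        for s in summaries
    ]
    tables = {
        "fig2_scores": pd.DataFrame(behavior_rows),
        "fig4_feedback": aggregate(logs, by=["run", "group"]),
        "fig5_probes": aggregate(logs, by=["run", "station", "group"]),
        "fig6_decoding": pd.DataFrame(
            {"participant": [s.participant_id for s in defined],
             "decoding_accuracy": acc,
             "correct_interpretation": correct_interp}
        ),
        "fig9_split_feedback": aggregate(logs, by=["run", "split"], split=split),
    }
    return summaries, split, stats, tables


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> ExperimentResult:
    """Execute the full pipeline; optionally write all outputs to disk."""
    stations, templates, training, models, pilot, norms = build_assets(config)
    logs, donor_logs = simulate_sessions(config, models, norms, templates, stations)
    behaviors = score_cohort_behavior(config, logs)
    summaries, split, stats, tables = analyze_cohort(logs, behaviors)
    stats["total_payout_usd"] = {
        log.participant_id: round(compute_payout(log.events, config.reward_cap), 2)
        for log in logs
    }
    result = ExperimentResult(
        config=config, logs=logs, donor_logs=donor_logs, behaviors=behaviors,
        summaries=summaries, split=split, stats=stats, tables=tables,
    )
    if out_dir is not None:
        _write_outputs(result, models, norms, templates, stations, training, Path(out_dir))
    return result


def _write_outputs(result, models, norms, templates, stations, training, out_dir: Path):
    config = result.config
    digest = config.digest()
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    (out_dir / "meta.json").write_text(
        json.dumps(
            {
                "config_digest": digest,
                "seed": config.seed,
                "templates": templates_to_dict(templates),
                "stations": stations_to_list(stations),
            },
            indent=1,
        )
    )
    save_cohort(
        training,
        {"config_digest": digest, "templates": templates_to_dict(templates),
         "stations": stations_to_list(stations)},
        out_dir / "training_cohort",
    )
    save_models(models, out_dir / "models.json")
    save_norms(norms, out_dir / "pilot_norms.tsv")
    for log in result.logs:
        save_session_log(log, out_dir, config.timing, digest)
    if result.donor_logs:
        for log in result.donor_logs:
            save_session_log(log, out_dir / "donors", config.timing, digest)
    rows = [
        {"participant": pid, "config_digest": digest, **vars(b)}
        for pid, b in result.behaviors.items()
    ]
    save_behavior(rows, out_dir / "behavior.tsv")
    analysis_dir = out_dir / "analysis"
    analysis_dir.mkdir(exist_ok=True)
    for name, table in result.tables.items():
        table.to_csv(analysis_dir / f"{name}.tsv", sep="\t", index=False)
    (analysis_dir / "stats.json").write_text(
        json.dumps({"config_digest": digest, **result.stats}, indent=1, sort_keys=True)
    )
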