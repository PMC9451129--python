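"""Closed-loop session simulation.

One session = 4 runs x 7 stations.  At each station the agent declares
a lens (probe), emits a pattern at the hemodynamically shifted analysis
window, the station decoder produces p(c), the feedback engine turns it
into a thresholded reward, and the agent reinforces the declared lens
when the reward arrives (at feedback onset, station end + 4 TRs).

A yoked-control mode replays another same-group participant's feedback:
the participant still emits and is decoded normally, but the reward
shown (and paid) is the donor's value at the matched station, matched
on probe choice where possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agent import AgentState, adopted_state, agent_probe_policy, agent_update
from .cohort import StationSpec, TemplatePair, sample_station_pattern
from .decoder import StationModel, predict_cheating_probability
from .feedback import (
    DEFAULT_REWARD_CAP,
    FeedbackEvent,
    PilotNorms,
    TimingConfig,
    apply_group,
    normalize_score,
    station_timeline,
    threshold_reward,
)
from .rngs import group_sign, substream


@dataclass
class ProbeEvent:
    """The lens declared before a station, with its onset time."""

    run: int
    station_index: int
    choice: str
    onset_seconds: float


@dataclass
class SessionLog:
    """Complete record of one participant's neurofeedback training."""

    participant_id: str
    assigned_group: str
    seed: int
    events: list[FeedbackEvent] = field(default_factory=list)
    probes: list[ProbeEvent] = field(default_factory=list)
    final_state: AgentState | None = None
    mode: str = "live"


def _station_step(
    state: AgentState,
    run: int,
    station: StationSpec,
    models_by_station: dict[int, StationModel],
    norms: PilotNorms,
    templates: TemplatePair,
    timing: TimingConfig,
    rng_patterns: np.random.Generator,
    rng_probes: np.random.Generator,
):
    """Probe -> pattern -> decode -> score for one station; no agent update.

    The pattern is emitted from the *adopted* state: the agent listens
    through the lens it just declared, blended with its latent lean.
    """
    timeline = station_timeline(station, timing)
    choice = agent_probe_policy(state, rng_probes)
    listening = adopted_state(state, choice)
    pattern = sample_station_pattern(
        listening, station, templates, state.snr, rng_patterns
    )
    p_c = predict_cheating_probability(models_by_station[station.station_index], pattern)
    score_c = normalize_score(p_c, norms, station.station_index)
    return timeline, choice, p_c, score_c


def run_session(
    participant_id: str,
    assigned_group: str,
    initial_state: AgentState,
    models: list[StationModel],
    norms: PilotNorms,
    templates: TemplatePair,
    stations: list[StationSpec],
    timing: TimingConfig | None = None,
    n_runs: int = 4,
    seed: int = 0,
    reward_cap: float = DEFAULT_REWARD_CAP,
) -> SessionLog:
    """Simulate one participant's full closed-loop training.

    Group assignment is fixed across runs (double-blind: the agent only
    ever observes probe prompts and reward values).  Truncated sessions
    (n_runs < 4) are supported.  All randomness derives from ``seed``
    via named substreams, so identical seeds reproduce identical logs.
    """
    group_sign(assigned_group)  # validate label
    timing = timing or TimingConfig()
    models_by_station = {m.station_index: m for m in models}
    rng_patterns = substream(seed, f"{participant_id}-patterns")
    rng_probes = substream(seed, f"{participant_id}-probes")
    n_events = n_runs * len(stations)

    log = SessionLog(participant_id, assigned_group, seed)
    state = initial_state
    for run in range(1, n_runs + 1):
        for station in stations:
            timeline, choice, p_c, score_c = _station_step(
                state, run, station, models_by_station, norms, templates,
                timing, rng_patterns, rng_probes,
            )
            score_final = apply_group(score_c, assigned_group)
            score_reward = threshold_reward(score_final)
            log.probes.append(
                ProbeEvent(run, station.station_index, choice, timeline.probe_onset_seconds)
            )
            log.events.append(
                FeedbackEvent(
                    run=run,
                    station_index=station.station_index,
                    p_c=p_c,
                    score_c=score_c,
                    score_final=score_final,
                    score_reward=score_reward,
                    payout=score_reward * reward_cap / n_events,
                    probe_choice=choice,
                    feedback_onset_tr=timeline.feedback_onset_tr,
                )
            )
            # reward is integrated when the display appears, after the
            # 4-TR delay -- i.e. before the next station's probe
            state = agent_update(state, choice, score_reward)
    log.final_state = state
    return log


def run_yoked_session(
    participant_id: str,
    assigned_group: str,
    initial_state: AgentState,
    donor_log: SessionLog,
    models: list[StationModel],
    norms: PilotNorms,
    templates: TemplatePair,
    stations: list[StationSpec],
    timing: TimingConfig | None = None,
    n_runs: int = 4,
    seed: int = 0,
    reward_cap: float = DEFAULT_REWARD_CAP,
) -> SessionLog:
    """Simulate a session whose feedback is another participant's.

    The donor must share the assigned group.  At each station the
    delivered reward is the donor's reward for that (run, station) when
    the donor made the same probe choice; otherwise the donor's value
    is delivered anyway and the event is flagged ``yoked_fallback``.
    The participant's own p(c) and scores are still logged, so decoding
    accuracy remains computable.
    """
    if donor_log.assigned_group != assigned_group:
        raise ValueError(
            f"donor group {donor_log.assigned_group!r} does not match {assigned_group!r}"
        )
    timing = timing or TimingConfig()
    models_by_station = {m.station_index: m for m in models}
    donor_events = {(e.run, e.station_index): e for e in donor_log.events}
    rng_patterns = substream(seed, f"{participant_id}-patterns")
    rng_probes = substream(seed, f"{participant_id}-probes")
    n_events = n_runs * len(stations)

    log = SessionLog(participant_id, assigned_group, seed, mode="yoked")
    state = initial_state
    for run in range(1, n_runs + 1):
        for station in stations:
            timeline, choice, p_c, score_c = _station_step(
                state, run, station, models_by_station, norms, templates,
                timing, rng_patterns, rng_probes,
            )
            score_final = apply_group(score_c, assigned_group)
            score_reward = threshold_reward(score_final)
            donor = donor_events.get((run, station.station_index))
            if donor is None:
                raise ValueError(
                    f"donor log has no event for run {run}, station {station.station_index}"
                )
            delivered = donor.score_reward
            fallback = donor.probe_choice != choice
            log.probes.append(
                ProbeEvent(run, station.station_index, choice, timeline.probe_onset_seconds)
            )
            log.events.append(
                FeedbackEvent(
                    run=run,
                    station_index=station.station_index,
                    p_c=p_c,
                    score_c=score_c,
                    score_final=score_final,
                    score_reward=score_reward,
                    payout=delivered * reward_cap / n_events,
                    probe_choice=choice,
                    feedback_onset_tr=timeline.feedback_onset_tr,
                    delivered_reward=delivered,
                    yoked_fallback=fallback,
                )
            )
            state = agent_update(state, choice, delivered)
    log.final_state = state
    return log
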