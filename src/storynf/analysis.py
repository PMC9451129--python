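"""Participant- and group-level statistics.

*Decoding accuracy* for a participant is the difference between the
mean decoded p(c) at stations where they declared the cheating lens
and the mean p(c) where they declared paranoid, pooled over all runs.
It measures how well the decoder tracks what the participant *says*
they are doing, independent of the assigned group, and is the basis of
the best/worst median split (performed within each assigned group so
the split groups stay balanced 5+5).

Group comparisons use pooled-variance (Student) independent-samples
t-tests — df = n1 + n2 - 2, e.g. t(18) for 10 vs 10 — optionally
one-tailed; correlations are Pearson with the t-transform p-value;
station-wise families are Bonferroni-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import BehaviorScores
from .errors import UndefinedDecodingAccuracyError
from .rngs import CHEATING, PARANOID
from .session import SessionLog

BEST = "best"
WORST = "worst"


@dataclass
class ParticipantSummary:
    participant_id: str
    assigned_group: str
    decoding_accuracy: float
    accuracy_defined: bool = True
    behavior: BehaviorScores | None = None
    mean_pc_by_run: dict[int, float] = field(default_factory=dict)
    mean_reward_by_run: dict[int, float] = field(default_factory=dict)


def decoding_accuracy(log: SessionLog) -> float:
    """mean p(c) at cheating-probe stations minus mean p(c) at
    paranoid-probe stations, pooled over runs and stations.

    Raises :class:`UndefinedDecodingAccuracyError` when the participant
    never chose one of the labels (the quantity is then undefined and
    the participant must be flagged, not silently dropped).
    """
    pc_cheat = [e.p_c for e in log.events if e.probe_choice == CHEATING]
    pc_para = [e.p_c for e in log.events if e.probe_choice == PARANOID]
    if not pc_cheat or not pc_para:
        missing = CHEATING if not pc_cheat else PARANOID
        raise UndefinedDecodingAccuracyError(
            f"{log.participant_id}: probe label {missing!r} never chosen"
        )
    return float(np.mean(pc_cheat) - np.mean(pc_para))


def summarize_participant(log: SessionLog, behavior: BehaviorScores | None = None) -> ParticipantSummary:
    """Per-participant aggregates; undefined accuracy is flagged as NaN."""
    try:
        acc = decoding_accuracy(log)
        defined = True
    except UndefinedDecodingAccuracyError:
        acc, defined = float("nan"), False
    runs = sorted({e.run for e in log.events})
    return ParticipantSummary(
        participant_id=log.participant_id,
        assigned_group=log.assigned_group,
        decoding_accuracy=acc,
        accuracy_defined=defined,
        behavior=behavior,
        mean_pc_by_run={
            r: float(np.mean([e.p_c for e in log.events if e.run == r])) for r in runs
        },
        mean_reward_by_run={
            r: float(np.mean([e.score_reward for e in log.events if e.run == r])) for r in runs
        },
    )


def median_split(
    summaries: list[ParticipantSummary], odd_policy: str | None = None
) -> dict[str, str]:
    """Best/worst decoding split, performed within each assigned group.

    Participants are ranked by (decoding accuracy desc, participant_id
    asc) for a deterministic tie-break; the top half of each group is
    'best'.  Odd group sizes raise unless ``odd_policy`` is
    'extra_best' or 'extra_worst'.
    """
    if any(not s.accuracy_defined or np.isnan(s.decoding_accuracy) for s in summaries):
        raise UndefinedDecodingAccuracyError(
            "median split requires decoding accuracy for every participant"
        )
    assignment: dict[str, str] = {}
    for group in sorted({s.assigned_group for s in summaries}):
        members = sorted(
            (s for s in summaries if s.assigned_group == group),
            key=lambda s: (-s.decoding_accuracy, s.participant_id),
        )
        n = len(members)
        if n % 2 and odd_policy not in ("extra_best", "extra_worst"):
            raise ValueError(
                f"group {group!r} has odd size {n}; set odd_policy to "
                "'extra_best' or 'extra_worst'"
            )
        n_best = n // 2 + (1 if n % 2 and odd_policy == "extra_best" else 0)
        for i, s in enumerate(members):
            assignment[s.participant_id] = BEST if i < n_best else WORST
    return assignment


def group_ttest(
    values,
    group_labels,
    tails: str = "two",
    direction: str | None = None,
    group_order: tuple[str, str] | None = None,
) -> tuple[float, int, float]:
    """Pooled-variance independent-samples t-test; returns (t, df, p).

    ``direction`` ('greater'/'less') applies to the first group versus
    the second for one-tailed tests.  Groups are taken in sorted label
    order unless ``group_order`` is given.  df = n1 + n2 - 2.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = list(group_order) if group_order else sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if tails == "two":
        alternative = "two-sided"
    elif tails == "one":
        if direction not in ("greater", "less"):
            raise ValueError("one-tailed test requires direction 'greater' or 'less'")
        alternative = direction
    else:
        raise ValueError("tails must be 'one' or 'two'")
    res = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    return float(res.statistic), len(a) + len(b) - 2, float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-tailed p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("inputs must have nonzero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values, family_size: int | None = None) -> np.ndarray:
    """min(1, p * m) for a family of m tests (default: len(p_values))."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = family_size if family_size is not None else p.size
    return np.minimum(1.0, p * m)


def _events_frame(
    logs: list[SessionLog], split: dict[str, str] | None = None
) -> pd.DataFrame:
    rows = []
    for log in logs:
        for e in log.events:
            rows.append(
                {
                    "participant": log.participant_id,
                    "group": log.assigned_group,
                    "run": e.run,
                    "station": e.station_index,
                    "p_c": e.p_c,
                    "score_reward": e.score_reward,
                    "probe_correct": float(e.probe_choice == log.assigned_group),
                    "split": split.get(log.participant_id) if split else None,
                }
            )
    return pd.DataFrame(rows)


def aggregate(
    logs: list[SessionLog],
    by: list[str],
    split: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tidy mean +- sem tables for p(c), reward and probe correctness.

    ``by`` is any subset of {'run', 'station', 'group', 'split'}.  The
    unit of analysis is the participant: event-level values are first
    averaged within participant (per cell), then the cell mean and sem
    are taken across participants, so sem bars use per-group n.  Cells
    with a single participant get sem = NaN.
    """
    if not logs:
        raise ValueError("no session logs to aggregate")
    allowed = {"run", "station", "group", "split"}
    if not by or not set(by) <= allowed:
        raise ValueError(f"'by' must be a nonempty subset of {sorted(allowed)}")
    if "split" in by and split is None:
        raise ValueError("aggregating by split requires a split assignment")
    df = _events_frame(logs, split)
    per_participant = (
        df.groupby(list(by) + ["participant"], dropna=False)[
            ["p_c", "score_reward", "probe_correct"]
        ]
        .mean()
        .reset_index()
    )
    out = []
    for measure in ("p_c", "score_reward", "probe_correct"):
        g = per_participant.groupby(list(by), dropna=False)[measure]
        tab = g.agg(mean="mean", sem=lambda v: stats.sem(v) if len(v) > 1 else np.nan, n="count")
        tab = tab.reset_index()
        tab.insert(len(by), "measure", measure)
        out.append(tab)
    return pd.concat(out, ignore_index=True)
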