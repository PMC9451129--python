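"""Feedback score transformation and session timing arithmetic.

The displayed neurofeedback score rewards deviation from the pilot
cohort's "average neural interpretation trajectory" rather than the
absolute decoded state:

    score_c      = (p(c) - mu_st) / (3 * sigma_st) + 0.5, clipped to [0, 1]
    score_final  = score_c            (cheating group)
                   1 - score_c        (paranoid group)
    score_reward = score_final if score_final > 0.5 else 0

so a participant sitting exactly at the pilot mean scores 0.5 and earns
nothing, whichever group they are in.  The 3-sigma scaling maps z-scored
deviations of +-1.5 SD onto the full [0, 1] display range.

Timing: the analyzed BOLD window trails the on-screen station by the
3-TR hemodynamic lag (4.5 s at TR = 1.5 s); one further TR of analysis
time puts feedback onset 4 TRs (6 s) after station end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import N_STATIONS, StationSpec
from .errors import DegenerateNormsError, TimelineError
from .rngs import CHEATING, PARANOID, group_sign

Z_SCALE = 3.0
REWARD_THRESHOLD = 0.5
DEFAULT_REWARD_CAP = 20.0


@dataclass(frozen=True)
class PilotNorms:
    """Per-station mean and SD of pilot p(c), the normalization reference."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu, sigma = np.asarray(self.mu, float), np.asarray(self.sigma, float)
        if mu.shape != sigma.shape or mu.ndim != 1:
            raise ValueError("mu and sigma must be 1-D arrays of equal length")
        if np.any((mu < 0) | (mu > 1)):
            raise ValueError("pilot means must lie in [0, 1]")
        if np.any(sigma < 0):
            raise ValueError("pilot SDs must be nonnegative")

    @property
    def n_stations(self) -> int:
        return int(np.asarray(self.mu).size)


@dataclass(frozen=True)
class TimingConfig:
    """Timeline constants, all in TR units unless suffixed _seconds."""

    tr_seconds: float = 1.5
    hemodynamic_shift_trs: int = 3
    analysis_delay_trs: int = 1
    probe_lead_seconds: float = 4.0
    probe_to_station_seconds: float = 2.0
    run_n_trs: int = 480

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0 or self.run_n_trs <= 0:
            raise ValueError("tr_seconds and run_n_trs must be positive")
        if self.hemodynamic_shift_trs < 0 or self.analysis_delay_trs < 0:
            raise ValueError("TR delays must be nonnegative")


@dataclass
class FeedbackEvent:
    """One station's decoded, scored and rewarded outcome.

    ``score_reward`` is the participant's own thresholded score;
    ``delivered_reward`` is what was actually shown and paid (identical
    in live mode, the donor's value in yoked mode, where
    ``yoked_fallback`` marks stations whose donor made the opposite
    probe choice).
    """

    run: int
    station_index: int
    p_c: float
    score_c: float
    score_final: float
    score_reward: float
    payout: float
    probe_choice: str
    feedback_onset_tr: int
    delivered_reward: float = field(default=np.nan)
    yoked_fallback: bool = False

    def __post_init__(self) -> None:
        if np.isnan(self.delivered_reward):
            self.delivered_reward = self.score_reward


@dataclass(frozen=True)
class StationTimeline:
    """Resolved per-station timeline (TR indices inclusive)."""

    probe_onset_seconds: float
    station_window: tuple[int, int]
    analyzed_window: tuple[int, int]
    feedback_onset_tr: int


def estimate_pilot_norms(pilot_pc: pd.DataFrame, sd_mode: str = "population") -> PilotNorms:
    """Per-station mean and SD of p(c), pooled over pilot participants and runs.

    ``pilot_pc`` is long-format with columns ``station`` and ``p_c``.
    The pilot is treated as a fixed reference distribution, hence the
    population SD (ddof = 0) by default; ``sd_mode='sample'`` uses
    ddof = 1.  A station with zero SD cannot normalize anything and
    raises :class:`DegenerateNormsError`.
    """
    if sd_mode not in ("population", "sample"):
        raise ValueError("sd_mode must be 'population' or 'sample'")
    ddof = 0 if sd_mode == "population" else 1
    stations = sorted(pilot_pc["station"].unique())
    mu, sigma = [], []
    for st in stations:
        vals = pilot_pc.loc[pilot_pc["station"] == st, "p_c"].to_numpy(float)
        if vals.size < 2:
            raise ValueError(f"station {st}: need at least 2 pilot samples")
        s = float(np.std(vals, ddof=ddof))
        if s == 0.0:
            raise DegenerateNormsError(f"station {st}: pilot p(c) SD is zero")
        mu.append(float(np.mean(vals)))
        sigma.append(s)
    return PilotNorms(mu=np.array(mu), sigma=np.array(sigma))


def normalize_score(p_c: float, norms: PilotNorms, station_index: int) -> float:
    """score_c = (p(c) - mu_st) / (3 sigma_st) + 0.5, clipped to [0, 1]."""
    sigma = float(norms.sigma[station_index])
    if sigma <= 0:
        raise DegenerateNormsError(f"station {station_index}: sigma must be positive")
    raw = (p_c - float(norms.mu[station_index])) / (Z_SCALE * sigma) + 0.5
    return float(np.clip(raw, 0.0, 1.0))


def apply_group(score_c: float, group: str) -> float:
    """Flip the score for the paranoid group so 'up' always means
    'toward your assigned interpretation'."""
    sign = group_sign(group)  # validates the label
    return float(score_c) if sign > 0 else float(1.0 - score_c)


def threshold_reward(score_final: float) -> float:
    """Scores <= 0.5 earn nothing; above-threshold scores pass through."""
    return float(score_final) if score_final > REWARD_THRESHOLD else 0.0


def compute_payout(events: list[FeedbackEvent], cap: float = DEFAULT_REWARD_CAP) -> float:
    """Total bonus in USD: each station contributes delivered_reward *
    cap / n_stations, so a perfect session saturates the cap exactly."""
    if not events:
        return 0.0
    per_station = cap / len(events)
    return float(sum(e.delivered_reward * per_station for e in events))


def station_timeline(station: StationSpec, timing: TimingConfig) -> StationTimeline:
    """Resolve probe, station, analyzed and feedback times for a station.

    The analyzed window is the station window shifted by the
    hemodynamic lag; feedback appears one analysis TR after the last
    analyzed TR, i.e. station end + 4 TRs at defaults.
    """
    start, end = station.start_tr, station.end_tr
    shift = timing.hemodynamic_shift_trs
    analyzed = (start + shift, end + shift)
    feedback_onset = end + shift + timing.analysis_delay_trs
    if feedback_onset >= timing.run_n_trs:
        raise TimelineError(
            f"station {station.station_index}: analyzed/feedback window "
            f"(TR {feedback_onset}) extends past run end (TR {timing.run_n_trs - 1})"
        )
    probe_onset = start * timing.tr_seconds - timing.probe_lead_seconds
    if probe_onset < 0:
        raise TimelineError(f"station {station.station_index}: probe onset before run start")
    return StationTimeline(
        probe_onset_seconds=float(probe_onset),
        station_window=(start, end),
        analyzed_window=analyzed,
        feedback_onset_tr=int(feedback_onset),
    )
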