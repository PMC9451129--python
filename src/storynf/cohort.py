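"""Synthetic cohorts for the closed-loop pipeline.

The original experiment decoded story interpretation from ToM/DMN
voxel patterns; here all neural data are replaced by abstract
``n_features``-dimensional vectors built from two interpretation
templates.  A participant with latent lean ``theta`` emits, at a
station with stimulus bias ``b``,

    pattern = midpoint + (b + snr * theta) * (separation / 2) * u + noise

where ``u`` is the unit vector from the paranoid to the cheating
template, so patterns move monotonically toward the cheating template
as theta increases, and station biases reproduce the pilot observation
that many stations lean toward one interpretation regardless of the
listener.

Three cohorts are generated from this model:

* a labeled *training* cohort (stand-in for the prior explicit-
  instruction study; theta fixed at +-1 by assigned label),
* a *pilot* cohort of free-interpretation agents (theta drawn per
  participant) whose decoded p(c) values define the per-station
  normalization means and SDs, and
* the closed-loop agents themselves (see :mod:`storynf.session`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agent import AgentState
from .behavior import (
    COMPREHENSION_OPTIONS,
    N_COMPREHENSION,
    N_INTERPRETATION,
    QuestionnaireResponse,
)
from .rngs import CHEATING, GROUPS, PARANOID, substream

N_STATIONS = 7
TR_SECONDS = 1.5
#: Default stimulus-driven station biases, spanning strongly-paranoid to
#: strongly-cheating leans across the 7 stations.
DEFAULT_STATION_BIASES = tuple(float(b) for b in np.linspace(-0.6, 0.6, N_STATIONS))


@dataclass(frozen=True)
class TemplatePair:
    """The two interpretation-specific activity templates.

    ``direction`` is the unit vector from the paranoid to the cheating
    template; ``separation`` is the Euclidean distance between them.
    """

    template_cheating: np.ndarray
    template_paranoid: np.ndarray
    direction: np.ndarray
    separation: float

    def __post_init__(self) -> None:
        a, b = np.asarray(self.template_cheating), np.asarray(self.template_paranoid)
        if a.ndim != 1 or a.shape != b.shape or a.size < 2:
            raise ValueError("templates must be 1-D, same length, n_features >= 2")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")

    @property
    def n_features(self) -> int:
        return int(self.template_cheating.size)

    @property
    def midpoint(self) -> np.ndarray:
        return (self.template_cheating + self.template_paranoid) / 2.0


@dataclass(frozen=True)
class StationSpec:
    """One analysis window within a run.

    ``start_tr`` and ``n_trs`` are in TR units (TR = 1.5 s); station
    durations must lie in [3, 16.5] s.  ``bias`` in [-1, 1] is the
    stimulus-driven lean of the narrative at that station (+ cheating).
    """

    station_index: int
    start_tr: int
    n_trs: int
    bias: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.station_index < N_STATIONS:
            raise ValueError(f"station_index must be in 0..{N_STATIONS - 1}")
        if self.start_tr < 0 or self.n_trs < 1:
            raise ValueError("start_tr must be >= 0 and n_trs >= 1")
        if not 3.0 <= self.n_trs * TR_SECONDS <= 16.5:
            raise ValueError("station duration must lie in [3, 16.5] s")
        if not -1.0 <= self.bias <= 1.0:
            raise ValueError("bias must lie in [-1, 1]")

    @property
    def end_tr(self) -> int:
        """Last TR of the station window (inclusive)."""
        return self.start_tr + self.n_trs - 1


def default_stations(biases: tuple[float, ...] = DEFAULT_STATION_BIASES) -> list[StationSpec]:
    """Seven disjoint, ordered stations spread over a ~12 min run.

    Durations span the full 3-16.5 s range; start TRs leave room for
    probe lead-in, the 3-TR hemodynamic shift, and feedback display.
    """
    starts = (40, 100, 160, 225, 295, 365, 435)
    n_trs = (2, 4, 6, 11, 8, 5, 3)
    return [
        StationSpec(station_index=i, start_tr=s, n_trs=n, bias=float(b))
        for i, (s, n, b) in enumerate(zip(starts, n_trs, biases))
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Size, noise level and group assignment of a simulated cohort."""

    n_participants: int = 20
    n_runs: int = 4
    n_features: int = 100
    snr: float = 1.0
    seed: int = 0
    group_assignment: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_runs < 1 or self.n_features < 2:
            raise ValueError("cohort sizes must be positive (n_features >= 2)")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")
        if self.group_assignment is not None:
            if len(self.group_assignment) != self.n_participants:
                raise ValueError("group_assignment length must equal n_participants")
            if any(g not in GROUPS for g in self.group_assignment):
                raise ValueError("group labels must be 'cheating' or 'paranoid'")

    def groups(self) -> tuple[str, ...]:
        """Assigned labels; default is a balanced first-half/second-half split."""
        if self.group_assignment is not None:
            return tuple(self.group_assignment)
        half = self.n_participants // 2
        return tuple(
            CHEATING if i < half + self.n_participants % 2 else PARANOID
            for i in range(self.n_participants)
        )


def make_templates(n_features: int, separation: float, seed: int) -> TemplatePair:
    """Build the interpretation template pair.

    A seeded standard-normal base vector is split along a random unit
    direction: templates = base +- (separation/2) * direction, so their
    Euclidean distance equals ``separation`` by construction.
    """
    if not isinstance(n_features, (int, np.integer)) or n_features < 2:
        raise ValueError("n_features must be an integer >= 2")
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    rng = np.random.default_rng(seed)
    base = rng.normal(size=n_features)
    raw = rng.normal(size=n_features)
    direction = raw / np.linalg.norm(raw)
    half = (separation / 2.0) * direction
    return TemplatePair(
        template_cheating=base + half,
        template_paranoid=base - half,
        direction=direction,
        separation=float(separation),
    )


def sample_station_pattern(
    state: AgentState,
    station: StationSpec,
    templates: TemplatePair,
    snr: float,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """Draw one activity pattern for an agent at a station.

    Expectation = midpoint + (bias + snr*theta) * (separation/2) * direction,
    plus isotropic Gaussian noise; the expected projection onto the
    discriminant axis is strictly increasing in theta (slope
    snr * separation / 2).
    """
    drive = (station.bias + snr * state.theta) * (templates.separation / 2.0)
    mean = templates.midpoint + drive * templates.direction
    return mean + rng.normal(scale=noise_sd, size=templates.n_features)


def _pattern_frame(rows: list[dict], n_features: int) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    meta_cols = ["participant", "group", "run", "station"]
    feat_cols = [f"f{j}" for j in range(n_features)]
    return df[meta_cols + feat_cols]


def generate_training_cohort(
    config: CohortConfig,
    templates: TemplatePair,
    stations: list[StationSpec],
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Labeled patterns emulating the prior explicit-instruction study.

    Each participant holds their assigned interpretation throughout
    (theta fixed at +1 for cheating, -1 for paranoid); one pattern per
    participant x run x station, with columns participant, group, run,
    station, f0..f{n-1}.  Deterministic given ``config.seed``.

    Station stimulus biases are *not* applied here: under explicit
    instruction the assigned interpretation dominates the response, and
    it is precisely because the training cohort lacks the free-listening
    station biases that the pilot cohort's p(c) means come out shifted
    at biased stations — the phenomenon the pilot normalization exists
    to correct.
    """
    groups = config.groups()
    if sorted(set(groups)) != sorted(GROUPS):
        raise ValueError("training cohort must contain both groups")
    rng = substream(config.seed, "training-patterns")
    unbiased = [replace(st, bias=0.0) for st in stations]
    rows = []
    for pid, group in enumerate(groups):
        theta = 1.0 if group == CHEATING else -1.0
        state = AgentState(theta=theta, snr=config.snr)
        for run in range(1, config.n_runs + 1):
            for st in unbiased:
                pattern = sample_station_pattern(
                    state, st, templates, config.snr, rng, noise_sd=noise_sd
                )
                row = {
                    "participant": f"sub-{pid + 1:02d}",
                    "group": group,
                    "run": run,
                    "station": st.station_index,
                }
                row.update({f"f{j}": pattern[j] for j in range(pattern.size)})
                rows.append(row)
    return _pattern_frame(rows, templates.n_features)


def generate_pilot_cohort(
    config: CohortConfig,
    templates: TemplatePair,
    stations: list[StationSpec],
    models: list,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Decoded p(c) samples from free-interpretation pilot agents.

    Each pilot participant gets a latent lean theta ~ Uniform(-1, 1)
    held across runs; their patterns are scored by the trained station
    models and pooled across both conditions, giving
    n_participants x n_runs p(c) values per station (long format:
    participant, run, station, theta, p_c).
    """
    from .decoder import predict_cheating_probability

    rng_theta = substream(config.seed, "pilot-theta")
    rng_pat = substream(config.seed, "pilot-patterns")
    by_station = {m.station_index: m for m in models}
    rows = []
    for pid in range(config.n_participants):
        theta = float(rng_theta.uniform(-1.0, 1.0))
        state = AgentState(theta=theta, snr=config.snr)
        for run in range(1, config.n_runs + 1):
            for st in stations:
                pattern = sample_station_pattern(
                    state, st, templates, config.snr, rng_pat, noise_sd=noise_sd
                )
                p_c = predict_cheating_probability(by_station[st.station_index], pattern)
                rows.append(
                    {
                        "participant": f"pilot-{pid + 1:02d}",
                        "run": run,
                        "station": st.station_index,
                        "theta": theta,
                        "p_c": p_c,
                    }
                )
    return pd.DataFrame(rows)


def generate_questionnaire(
    final_state: AgentState,
    group: str,
    rng: np.random.Generator,
    p_comprehension: float = 0.9,
    empathy_noise_sd: float = 0.5,
) -> QuestionnaireResponse:
    """Post-scan answers generated from the agent's final lean.

    Interpretation items are Bernoulli with P(cheating-consistent) =
    (1 + theta) / 2, so theta = +1 gives all +1 deterministically; the
    excluded girlfriend-name item is answered correctly by everyone.
    Comprehension is correct with fixed probability independent of
    theta.  Empathy ratings shift toward Arthur (and away from Lee and
    Joanie) as theta increases, with rounding noise, clipped to [1, 5].
    """
    theta = final_state.theta
    key = [COMPREHENSION_OPTIONS[int(k)] for k in rng.integers(0, 4, size=N_COMPREHENSION)]
    answers = []
    for k in key:
        if rng.random() < p_comprehension:
            answers.append(k)
        else:
            answers.append(rng.choice([o for o in COMPREHENSION_OPTIONS if o != k]))

    p_cheat_item = (1.0 + theta) / 2.0
    interp = []
    for i in range(N_INTERPRETATION):
        if i == 5:  # excluded item: everyone answers it "correctly"
            interp.append(1)
        else:
            interp.append(1 if rng.random() < p_cheat_item else -1)

    def _rate(mean: float) -> int:
        return int(np.clip(round(mean + rng.normal(scale=empathy_noise_sd)), 1, 5))

    empathy = {
        "arthur": _rate(3.0 + 1.5 * theta),
        "lee": _rate(3.0 - 1.5 * theta),
        "joanie": _rate(3.0 - 1.0 * theta),
        "the_girl": _rate(3.0),
    }
    return QuestionnaireResponse(
        comprehension_answers=answers,
        answer_key=key,
        interpretation_answers=interp,
        empathy=empathy,
    )
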