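"""Post-scan questionnaire scoring.

Participants answer 27 comprehension questions and 12 interpretation
questions after the final run, then rate empathy (1-5) for the four
story characters.  Interpretation answers are coded +1 when consistent
with the cheating interpretation and -1 when consistent with the
paranoid interpretation; one item (the name of Lee's girlfriend, which
everyone is told beforehand) is excluded from scoring, leaving 11
scored items.  "Correct" scores sign-align interpretation and empathy
measures with the randomly assigned group by multiplying paranoid-group
scores by -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rngs import CHEATING, PARANOID, group_sign

N_COMPREHENSION = 27
N_INTERPRETATION = 12
N_SCORED_INTERPRETATION = 11
EXCLUDED_ITEM_ID = "interp_05_lee_girlfriend_name"
COMPREHENSION_OPTIONS = ("a", "b", "c", "d")
CHARACTERS = ("arthur", "lee", "joanie", "the_girl")

#: Questionnaire layout: item ids, type, coding, and the excluded flag.
#: Item text is not modeled; only the scoring structure matters here.
QUESTIONNAIRE_TEMPLATE = {
    "comprehension": [f"comp_{i:02d}" for i in range(N_COMPREHENSION)],
    "interpretation": [
        {
            "id": f"interp_{i:02d}" if i != 5 else EXCLUDED_ITEM_ID,
            "coding": "+1 cheating-consistent / -1 paranoid-consistent",
            "excluded": i == 5,
        }
        for i in range(N_INTERPRETATION)
    ],
    "empathy": list(CHARACTERS),
}


@dataclass
class QuestionnaireResponse:
    """One participant's post-scan answers.

    ``interpretation_answers`` are coded +1/-1; ``excluded`` marks items
    that never enter the interpretation score (default: item 5, the
    girlfriend-name question).  ``empathy`` maps character name to an
    integer rating in [1, 5].
    """

    comprehension_answers: list[str]
    answer_key: list[str]
    interpretation_answers: list[int]
    empathy: dict[str, int]
    excluded: list[bool] = field(default_factory=lambda: [i == 5 for i in range(N_INTERPRETATION)])

    def __post_init__(self) -> None:
        if len(self.comprehension_answers) != N_COMPREHENSION:
            raise ValueError(
                f"expected {N_COMPREHENSION} comprehension answers, "
                f"got {len(self.comprehension_answers)}"
            )
        if len(self.interpretation_answers) != N_INTERPRETATION:
            raise ValueError(
                f"expected {N_INTERPRETATION} interpretation answers, "
                f"got {len(self.interpretation_answers)}"
            )
        if len(self.excluded) != N_INTERPRETATION:
            raise ValueError("excluded flags must match interpretation items")
        if any(a not in (-1, 1) for a in self.interpretation_answers):
            raise ValueError("interpretation answers must be coded +1 or -1")
        for who, rating in self.empathy.items():
            if not (isinstance(rating, (int, np.integer)) and 1 <= rating <= 5):
                raise ValueError(f"empathy rating for {who!r} must be an integer in [1,5]")


@dataclass
class BehaviorScores:
    """Scalar behavioral summaries for one participant."""

    comprehension: float
    interpretation: float
    correct_interpretation: float
    empathy_diff: int
    correct_empathy: int


def score_interpretation(response: QuestionnaireResponse) -> float:
    """Mean of the +-1 codes over the scored (non-excluded) items.

    +1 means every scored answer was cheating-consistent, -1 means every
    scored answer was paranoid-consistent.
    """
    scored = [
        a for a, excl in zip(response.interpretation_answers, response.excluded) if not excl
    ]
    if len(scored) != N_SCORED_INTERPRETATION:
        raise ValueError(
            f"expected {N_SCORED_INTERPRETATION} scored interpretation items, got {len(scored)}"
        )
    return float(sum(scored)) / len(scored)


def correct_transform(score: float, group: str) -> float:
    """Sign-align a score with the assigned group (paranoid scores * -1)."""
    return float(score) * group_sign(group)


def empathy_difference(empathy: dict[str, int]) -> int:
    """Arthur minus Lee empathy rating (positive = cheating-leaning)."""
    try:
        return int(empathy["arthur"]) - int(empathy["lee"])
    except KeyError as exc:
        raise ValueError(f"missing empathy rating for {exc.args[0]!r}") from exc


def score_comprehension(response: QuestionnaireResponse, key: list[str] | None = None) -> float:
    """Fraction of comprehension answers matching the answer key."""
    key = response.answer_key if key is None else key
    if len(key) != len(response.comprehension_answers):
        raise ValueError("answer key length does not match comprehension answers")
    hits = sum(a == k for a, k in zip(response.comprehension_answers, key))
    return hits / len(key)


def score_questionnaire(response: QuestionnaireResponse, group: str) -> BehaviorScores:
    """All behavioral scores for one participant in one call."""
    interp = score_interpretation(response)
    ediff = empathy_difference(response.empathy)
    return BehaviorScores(
        comprehension=score_comprehension(response),
        interpretation=interp,
        correct_interpretation=correct_transform(interp, group),
        empathy_diff=ediff,
        correct_empathy=int(correct_transform(ediff, group)),
    )
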