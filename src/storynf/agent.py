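"""Simulated participant.

The real experiment offers no observable model of how listeners
integrate feedback, so the closed loop is driven by a minimal
reinforcement agent: a latent interpretation state theta in [-1, +1]
(+1 = fully cheating, -1 = fully paranoid) that (a) biases the neural
patterns the agent emits, (b) drives its probe choices through a
logistic policy, and (c) moves toward whichever lens was just rewarded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .rngs import CHEATING, PARANOID, group_sign


@dataclass(frozen=True)
class AgentState:
    """Latent participant state.

    theta
        Interpretation lean in [-1, +1]; clamped after every update.
    learning_rate
        Step size of the reward-driven theta update (0 = no learning).
    probe_temperature
        Softness of the probe policy; as it approaches 0 the agent
        deterministically reports sign(theta).
    snr
        Scales how strongly the interpretation state shifts the emitted
        patterns along the template discriminant axis (0 = patterns
        carry no interpretation signal).
    adoption
        How fully the agent adopts the lens it just declared at the
        probe: during a station the emitted lean is
        (1 - adoption) * theta + adoption * sign(choice).  Declaring a
        lens and then thinking through it is what makes probe-locked
        decoding meaningful; 0 means probes are cheap talk.
    """

    theta: float = 0.0
    learning_rate: float = 0.1
    probe_temperature: float = 0.5
    snr: float = 1.0
    adoption: float = 0.5

    def __post_init__(self) -> None:
        if not -1.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [-1, 1]")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.probe_temperature <= 0:
            raise ValueError("probe_temperature must be positive")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")
        if not 0.0 <= self.adoption <= 1.0:
            raise ValueError("adoption must lie in [0, 1]")


def adopted_state(state: AgentState, probe_choice: str) -> AgentState:
    """State the agent occupies while listening through the declared lens.

    A convex blend of the latent lean and the declared lens, so the
    emitted pattern reflects what the agent said it would do.
    """
    lean = (1.0 - state.adoption) * state.theta + state.adoption * group_sign(probe_choice)
    return replace(state, theta=float(lean))


def agent_probe_policy(state: AgentState, rng: np.random.Generator) -> str:
    """Declare a lens for the upcoming station.

    P(cheating) = logistic(theta / probe_temperature); at temperature
    near zero the choice is the sign of theta.
    """
    p_cheating = 1.0 / (1.0 + np.exp(-state.theta / state.probe_temperature))
    return CHEATING if rng.random() < p_cheating else PARANOID


def agent_update(state: AgentState, probe_choice: str, score_reward: float) -> AgentState:
    """Reinforce the lens the agent just used, proportionally to reward.

    theta <- clamp(theta + learning_rate * score_reward * sign(choice));
    a zero reward leaves theta untouched.
    """
    if not 0.0 <= score_reward <= 1.0:
        raise ValueError("score_reward must lie in [0, 1]")
    step = state.learning_rate * score_reward * group_sign(probe_choice)
    return replace(state, theta=float(np.clip(state.theta + step, -1.0, 1.0)))
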