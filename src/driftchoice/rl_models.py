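"""Delta- and decay-rule reinforcement learning with softmax choice.

Both models track a scalar expectancy E_j per option and choose through a
softmax with a single inverse temperature theta:

    delta rule:  E_{j,t} = E_{j,t-1} + delta_{j,t} * phi * (r_{j,t} - E_{j,t-1})
    decay rule:  E_{j,t} = d_RL * E_{j,t-1} + delta_{j,t} * r_{j,t}
    choice:      P(C_t = j) = exp(theta * E_j) / sum_k exp(theta * E_k)

delta_{j,t} is 1 for updated options and 0 otherwise: under partial
feedback only the chosen option is updated (the decay rule still discounts
the unchosen option's expectancy), while under full feedback both options
are updated every trial as if both outcomes had been received.  phi in
[0, 1] is a learning rate (high phi = strong recency); d_RL in [0, 1] is a
retention factor (low d_RL = strong recency).

Payoffs are divided by ``outcome_scale`` (default 500, the high payoff)
before updating so expectancies and theta are O(1); initial expectancies
default to 0.  Both settings are recorded in fit metadata so fitted theta
values stay interpretable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .task_env import (
    DYNAMIC,
    OPTIONS,
    REFERENCE,
    Condition,
    Option,
    ParticipantData,
    TrialRecord,
    other_option,
    sample_trial,
)

RULES = ("delta", "decay")


@dataclass(frozen=True)
class RLParams:
    """Parameters of one RL model instance.

    Exactly one of ``phi`` (delta rule) / ``d_rl`` (decay rule) must be
    set, matching ``rule``.
    """

    rule: str
    theta: float
    phi: Optional[float] = None
    d_rl: Optional[float] = None
    outcome_scale: float = 500.0
    e0: float = 0.0

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.rule == "delta":
            if self.phi is None or self.d_rl is not None:
                raise ValueError("delta rule requires phi (and no d_rl)")
            if not 0.0 <= self.phi <= 1.0:
                raise ValueError("phi must lie in [0, 1]")
        else:
            if self.d_rl is None or self.phi is not None:
                raise ValueError("decay rule requires d_rl (and no phi)")
            if not 0.0 <= self.d_rl <= 1.0:
                raise ValueError("d_rl must lie in [0, 1]")
        if self.outcome_scale <= 0:
            raise ValueError("outcome_scale must be positive")

    @property
    def learning_value(self) -> float:
        """The rule's learning/retention parameter (phi or d_rl)."""
        return self.phi if self.rule == "delta" else self.d_rl  # type: ignore


@dataclass
class RLState:
    """Per-option expectancies in scaled-payoff units."""

    expectancy: dict[Option, float] = field(
        default_factory=lambda: {opt: 0.0 for opt in OPTIONS}
    )

    def copy(self) -> "RLState":
        return RLState(dict(self.expectancy))


def delta_update(
    state: RLState, rewards: Mapping[Option, float], phi: float
) -> RLState:
    """Move each updated option's expectancy toward its reward by ``phi``."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    new = state.copy()
    for opt, r in rewards.items():
        if r is None:
            raise ValueError(f"missing reward for updated option {opt!r}")
        e = new.expectancy[opt]
        new.expectancy[opt] = e + phi * (r - e)
    return new


def decay_update(
    state: RLState, rewards: Mapping[Option, float], d_rl: float
) -> RLState:
    """Discount every expectancy by ``d_rl``; updated options gain their reward."""
    if not 0.0 <= d_rl <= 1.0:
        raise ValueError("d_rl must lie in [0, 1]")
    new = state.copy()
    for opt in new.expectancy:
        new.expectancy[opt] = d_rl * new.expectancy[opt]
    for opt, r in rewards.items():
        if r is None:
            raise ValueError(f"missing reward for updated option {opt!r}")
        new.expectancy[opt] += r
    return new


def softmax_prob(state: RLState, theta: float) -> dict[Option, float]:
    """Softmax choice probabilities over the options (max-subtracted)."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    opts = list(state.expectancy)
    z = np.array([theta * state.expectancy[o] for o in opts])
    z -= z.max()
    w = np.exp(z)
    w /= w.sum()
    return dict(zip(opts, w.tolist()))


def _p_dynamic(e_dyn: float, e_ref: float, theta: float) -> float:
    """P(choose dynamic) for two options — numerically stable logistic."""
    x = theta * (e_dyn - e_ref)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


def _trial_rewards(
    params: RLParams, rec: TrialRecord, full: bool
) -> dict[Option, float]:
    rewards = {rec.choice: rec.outcome_obtained / params.outcome_scale}
    if full:
        if rec.outcome_foregone is None:
            raise ValueError("full feedback requires a foregone outcome")
        rewards[other_option(rec.choice)] = (
            rec.outcome_foregone / params.outcome_scale
        )
    return rewards


def _update(state: RLState, params: RLParams, rewards: Mapping[Option, float]):
    if params.rule == "delta":
        return delta_update(state, rewards, params.phi)
    return decay_update(state, rewards, params.d_rl)


def simulate_rl(
    params: RLParams,
    condition: Condition,
    rng: np.random.Generator,
    participant_id: str = "rl-sim",
) -> ParticipantData:
    """Run one RL agent through the task.

    The per-trial choice probabilities the agent actually used are stored
    in ``ground_truth["p_dynamic"]`` so that one-step-ahead replay can be
    checked against them exactly.
    """
    state = RLState({opt: params.e0 for opt in OPTIONS})
    full = condition.feedback == "full"
    trials: list[TrialRecord] = []
    probs: list[float] = []
    for t in range(1, condition.n_trials + 1):
        p_dyn = _p_dynamic(
            state.expectancy[DYNAMIC], state.expectancy[REFERENCE], params.theta
        )
        probs.append(p_dyn)
        choice: Option = DYNAMIC if rng.random() < p_dyn else REFERENCE
        rec = sample_trial(condition, t, choice, rng)
        state = _update(state, params, _trial_rewards(params, rec, full))
        trials.append(rec)
    ground_truth = {
        "model": params.rule,
        "theta": params.theta,
        "outcome_scale": params.outcome_scale,
        "e0": params.e0,
        "p_dynamic": probs,
    }
    if params.rule == "delta":
        ground_truth["phi"] = params.phi
    else:
        ground_truth["d_rl"] = params.d_rl
    return ParticipantData(participant_id, condition, trials, ground_truth)


def predict_rl(params: RLParams, participant: ParticipantData) -> np.ndarray:
    """Deterministic one-step-ahead P(choose dynamic) for each trial.

    Replays the participant's choices and outcomes through the update rule
    and emits the softmax probability before each trial's update.
    """
    full = participant.condition.feedback == "full"
    state = RLState({opt: params.e0 for opt in OPTIONS})
    out = np.empty(participant.condition.n_trials)
    for i, rec in enumerate(participant.trials):
        out[i] = _p_dynamic(
            state.expectancy[DYNAMIC], state.expectancy[REFERENCE], params.theta
        )
        state = _update(state, params, _trial_rewards(params, rec, full))
    return out
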