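"""Dynamic binary-choice task environments.

A participant repeatedly chooses between a *dynamic* option whose
probability of paying its high outcome drifts linearly across trials, and
a *reference* option that never changes.  In the ``safe_risky`` composition
the reference option is a sure payoff (250 points); in the ``risky_risky``
composition it is a static 50/50 gamble over the same 0/500 outcomes as the
dynamic option.  Feedback is either ``partial`` (only the chosen option's
outcome is shown) or ``full`` (the foregone outcome is shown as well).

The three directions of change:

- ``static``      — p(high) = .50 on every trial;
- ``increasing``  — p(high) runs from .01 on trial 1 to 1.00 on the last trial;
- ``decreasing``  — the trial-reversed mirror of ``increasing`` (1.00 → .01).

For the default 100-trial task the increasing schedule is p(t) = .01·t and
the decreasing schedule is p(t) = 1.01 − .01·t, so the two are mirror
images: p_inc(t) + p_dec(t) = 1.01 for every t.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

Direction = Literal["static", "increasing", "decreasing"]
Feedback = Literal["partial", "full"]
Composition = Literal["safe_risky", "risky_risky"]
Option = Literal["dynamic", "reference"]

DYNAMIC: Option = "dynamic"
REFERENCE: Option = "reference"
OPTIONS: tuple[Option, Option] = (DYNAMIC, REFERENCE)

#: Labels used in exported CSVs alongside the internal option names.
OPTION_LABELS = {DYNAMIC: "risky", REFERENCE: "safe"}

DIRECTIONS = ("static", "increasing", "decreasing")
FEEDBACKS = ("partial", "full")
COMPOSITIONS = ("safe_risky", "risky_risky")

_P_START = 0.01
_P_END = 1.00
_EV_TIE_TOL = 1e-9


def other_option(option: Option) -> Option:
    """Return the option the agent did not choose."""
    return REFERENCE if option == DYNAMIC else DYNAMIC


@dataclass(frozen=True)
class Condition:
    """One cell of the direction × feedback × composition design.

    Parameters
    ----------
    direction
        How the dynamic option's high-outcome probability changes over trials.
    feedback
        ``"partial"`` shows only the chosen outcome; ``"full"`` also shows
        the foregone outcome of the unchosen option.
    n_trials
        Length of the task (default 100).
    safe_payoff, risky_high, risky_low
        Payoffs in points.
    composition
        ``"safe_risky"`` pits the dynamic gamble against a sure payoff;
        ``"risky_risky"`` replaces the sure payoff with a static 50/50
        gamble over the same high/low outcomes.
    """

    direction: Direction
    feedback: Feedback
    n_trials: int = 100
    safe_payoff: float = 250.0
    risky_high: float = 500.0
    risky_low: float = 0.0
    composition: Composition = "safe_risky"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.feedback not in FEEDBACKS:
            raise ValueError(f"unknown feedback {self.feedback!r}")
        if self.composition not in COMPOSITIONS:
            raise ValueError(f"unknown composition {self.composition!r}")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if not self.risky_high > self.risky_low:
            raise ValueError("risky_high must exceed risky_low")

    def payoff_support(self, option: Option) -> tuple[float, ...]:
        """Possible outcomes of ``option`` under this condition."""
        if option == DYNAMIC:
            return (self.risky_low, self.risky_high)
        if self.composition == "safe_risky":
            return (self.safe_payoff,)
        return (self.risky_low, self.risky_high)

    @property
    def cell(self) -> tuple[str, str, str]:
        return (self.direction, self.feedback, self.composition)


def _check_trial(condition: Condition, trial: int) -> None:
    if not 1 <= trial <= condition.n_trials:
        raise IndexError(
            f"trial {trial} outside 1..{condition.n_trials} for this condition"
        )


def p_high(condition: Condition, trial: int) -> float:
    """Probability that the dynamic option pays its high outcome on ``trial``.

    Trials are 1-based.  The increasing schedule interpolates linearly from
    .01 (trial 1) to 1.00 (last trial); decreasing is its trial-reversed
    mirror; static is .50 throughout.
    """
    _check_trial(condition, trial)
    if condition.direction == "static":
        return 0.5
    n = condition.n_trials
    if condition.direction == "increasing":
        frac = (trial - 1) / (n - 1)
    else:  # decreasing: mirror image of increasing
        frac = (n - trial) / (n - 1)
    return _P_START + (_P_END - _P_START) * frac


def reference_p_high(condition: Condition) -> float:
    """High-outcome probability of the reference option (risky_risky only)."""
    return 0.5


def expected_value(condition: Condition, trial: int, option: Option) -> float:
    """Per-trial expected value of ``option`` in points."""
    if option == DYNAMIC:
        p = p_high(condition, trial)
        return p * condition.risky_high + (1.0 - p) * condition.risky_low
    _check_trial(condition, trial)
    if condition.composition == "safe_risky":
        return condition.safe_payoff
    p = reference_p_high(condition)
    return p * condition.risky_high + (1.0 - p) * condition.risky_low


def maximizing_option(condition: Condition, trial: int) -> Optional[Option]:
    """Option with the higher per-trial expected value, or ``None`` on a tie.

    Ties occur throughout the static condition and on the single trial of a
    dynamic schedule where p(high) crosses .50 exactly.
    """
    ev_dyn = expected_value(condition, trial, DYNAMIC)
    ev_ref = expected_value(condition, trial, REFERENCE)
    if abs(ev_dyn - ev_ref) <= _EV_TIE_TOL:
        return None
    return DYNAMIC if ev_dyn > ev_ref else REFERENCE


@dataclass(frozen=True)
class TrialRecord:
    """A single observed trial.

    ``outcome_foregone`` is present iff the condition gives full feedback.
    ``p_high`` records the dynamic option's scheduled probability on the
    trial (descriptive metadata, never shown to agents).
    """

    trial: int
    choice: Option
    outcome_obtained: float
    outcome_foregone: Optional[float]
    p_high: float


def sample_trial(
    condition: Condition,
    trial: int,
    choice: Option,
    rng: np.random.Generator,
) -> TrialRecord:
    """Draw the outcome(s) of choosing ``choice`` on ``trial``.

    The dynamic option pays ``risky_high`` with probability
    :func:`p_high` and ``risky_low`` otherwise.  The reference option pays
    ``safe_payoff`` with certainty (``safe_risky``) or a 50/50 gamble
    (``risky_risky``).  Under full feedback the foregone outcome of the
    unchosen option is drawn independently and attached.
    """
    _check_trial(condition, trial)
    p = p_high(condition, trial)

    def draw(option: Option) -> float:
        if option == DYNAMIC:
            return condition.risky_high if rng.random() < p else condition.risky_low
        if condition.composition == "safe_risky":
            return condition.safe_payoff
        return (
            condition.risky_high
            if rng.random() < reference_p_high(condition)
            else condition.risky_low
        )

    obtained = draw(choice)
    foregone = draw(other_option(choice)) if condition.feedback == "full" else None
    return TrialRecord(trial, choice, obtained, foregone, p)


@dataclass
class ParticipantData:
    """Ordered trial records for one participant or simulated agent.

    ``ground_truth`` is set only for synthetic agents and holds the
    generating model label and parameters.
    """

    participant_id: str
    condition: Condition
    trials: list[TrialRecord] = field(default_factory=list)
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.trials) != self.condition.n_trials:
            raise ValueError(
                f"{self.participant_id}: expected {self.condition.n_trials} "
                f"trials, got {len(self.trials)}"
            )
        full = self.condition.feedback == "full"
        for i, rec in enumerate(self.trials, start=1):
            if rec.trial != i:
                raise ValueError(
                    f"{self.participant_id}: trial index {rec.trial} at "
                    f"position {i} (gap or duplicate)"
                )
            if full and rec.outcome_foregone is None:
                raise ValueError(
                    f"{self.participant_id}: trial {i} missing foregone "
                    "outcome under full feedback"
                )
            if not full and rec.outcome_foregone is not None:
                raise ValueError(
                    f"{self.participant_id}: trial {i} has a foregone "
                    "outcome under partial feedback"
                )

    # -- array views used by the model code -------------------------------

    def choices_dynamic(self) -> np.ndarray:
        """Boolean array: True where the dynamic option was chosen."""
        return np.array([rec.choice == DYNAMIC for rec in self.trials])

    def obtained(self) -> np.ndarray:
        return np.array([rec.outcome_obtained for rec in self.trials], dtype=float)

    def foregone(self) -> np.ndarray:
        if self.condition.feedback != "full":
            raise ValueError("foregone outcomes exist only under full feedback")
        return np.array([rec.outcome_foregone for rec in self.trials], dtype=float)


def make_participant(
    participant_id: str,
    condition: Condition,
    choices: Sequence[Option],
    obtained: Sequence[float],
    foregone: Optional[Sequence[float]] = None,
    ground_truth: Optional[dict] = None,
) -> ParticipantData:
    """Assemble a :class:`ParticipantData` from parallel sequences."""
    n = condition.n_trials
    if len(choices) != n or len(obtained) != n:
        raise ValueError("choices/obtained must have length n_trials")
    full = condition.feedback == "full"
    if full and (foregone is None or len(foregone) != n):
        raise ValueError("full feedback requires n_trials foregone outcomes")
    records = [
        TrialRecord(
            t,
            choices[t - 1],
            float(obtained[t - 1]),
            float(foregone[t - 1]) if full else None,
            p_high(condition, t),
        )
        for t in range(1, n + 1)
    ]
    return ParticipantData(participant_id, condition, records, ground_truth)
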