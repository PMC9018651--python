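import numpy as np
import pytest

from driftchoice import (
    Condition,
    DYNAMIC,
    REFERENCE,
    make_participant,
    maximizing_option,
)
from driftchoice.adaptation_analysis import period_maximizing_label


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_participant(condition, choices, pid="p0"):
    """Assemble valid trial data for a given choice sequence.

    Outcomes are filled deterministically from each option's payoff
    support (low outcome for the dynamic option) — sufficient wherever a
    test only cares about the choice sequence.
    """
    def outcome_for(option):
        return condition.payoff_support(option)[0]

    obtained = [outcome_for(c) for c in choices]
    foregone = None
    if condition.feedback == "full":
        foregone = [
            outcome_for(REFERENCE if c == DYNAMIC else DYNAMIC) for c in choices
        ]
    return make_participant(pid, condition, list(choices), obtained, foregone)


def maximizing_choices(condition):
    """Choice sequence that picks the period-labeled maximizing option."""
    n = condition.n_trials
    out = []
    for t in range(1, n + 1):
        period = "P1" if t <= n // 2 else "P2"
        label = period_maximizing_label(condition, t, period)
        out.append(label if label is not None else REFERENCE)
    return out
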