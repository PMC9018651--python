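"""Instance-based learning (IBL) model of repeated binary choice.

The model stores every observed outcome as an *instance* tagged with the
trial on which it occurred.  On each trial, each stored outcome i of each
option j receives an activation

    A_{j,i,t} = sigma * ln((1 - gamma)/gamma) + ln sum_{t_p} (t - t_p)^(-d)

where the sum runs over all previous trials t_p on which outcome i was
observed for option j, d >= 0 is a memory-decay exponent (large d = strong
recency), sigma >= 0 scales logistic retrieval noise, and gamma is a fresh
Uniform(0,1) draw per (option, outcome, trial).  Within an option the
activations are turned into retrieval probabilities by a Boltzmann rule
with temperature tau = sigma * sqrt(2), and the option's *blended value* is
the retrieval-probability-weighted mean of its outcomes.  The model
deterministically chooses the option with the higher blended value (exact
ties broken by a fair coin); all choice stochasticity comes from the
activation noise.

Under partial feedback each trial adds one instance (the obtained outcome
of the chosen option); under full feedback it adds two (the foregone
outcome of the unchosen option as well).

Cold start: each option is prepopulated with a single optimistic
pseudo-instance (``default_outcome``, by default the high payoff of 500)
at t_p = 0, which induces initial exploration and is removed permanently
once the option acquires its first real instance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

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

_SQRT2 = math.sqrt(2.0)
_INV_SQRT2 = 1.0 / _SQRT2
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class IBLParams:
    """Free parameters of the IBL model.

    ``d`` is the decay exponent (dimensionless, >= 0; higher values weight
    recent instances more), ``sigma`` the activation-noise scale (>= 0).
    ``tau`` is derived, never stored: tau = sigma * sqrt(2).
    ``default_outcome`` is the optimistic prepopulation value used before an
    option has been experienced.
    """

    d: float
    sigma: float
    default_outcome: float = 500.0

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def tau(self) -> float:
        return self.sigma * _SQRT2


class IBLMemory:
    """Instance store: per option, outcome value -> ordered occurrence trials.

    Each option starts with one pseudo-instance of ``default_outcome`` at
    t_p = 0; the pseudo-instance is deleted the first time the option
    receives a real instance.
    """

    __slots__ = ("_store", "_prepopulated", "default_outcome")

    def __init__(self, default_outcome: float = 500.0) -> None:
        self.default_outcome = float(default_outcome)
        self._store: dict[Option, dict[float, list[int]]] = {
            opt: {self.default_outcome: [0]} for opt in OPTIONS
        }
        self._prepopulated: dict[Option, bool] = {opt: True for opt in OPTIONS}

    def is_prepopulated(self, option: Option) -> bool:
        return self._prepopulated[option]

    def observe(self, option: Option, outcome: float, trial: int) -> None:
        """Record that ``outcome`` was observed for ``option`` on ``trial``."""
        outcome = float(outcome)
        if self._prepopulated[option]:
            self._store[option] = {}
            self._prepopulated[option] = False
        occ = self._store[option].setdefault(outcome, [])
        if occ and trial <= occ[-1]:
            raise ValueError("occurrence trials must be strictly increasing")
        occ.append(trial)

    def instances(self, option: Option) -> tuple[np.ndarray, list[list[int]]]:
        """Outcome values (sorted) and their occurrence-trial lists."""
        table = self._store[option]
        outcomes = sorted(table)
        return np.array(outcomes, dtype=float), [table[x] for x in outcomes]

    def occurrences(self, option: Option, outcome: float) -> list[int]:
        return list(self._store[option].get(float(outcome), []))

    def n_instances(self, option: Option) -> int:
        """Real instance count (0 while only the pseudo-instance exists)."""
        if self._prepopulated[option]:
            return 0
        return sum(len(v) for v in self._store[option].values())


def activation(
    occurrences: Sequence[int],
    t: int,
    params: IBLParams,
    gamma: float,
) -> float:
    """Activation of one outcome's instances at trial ``t``.

    ``occurrences`` are the previous trials on which the outcome was
    observed (all < t); ``gamma`` is a Uniform(0,1) variate strictly inside
    the unit interval.
    """
    if len(occurrences) == 0:
        raise ValueError("activation requires at least one stored instance")
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie strictly in (0, 1)")
    strength = 0.0
    for tp in occurrences:
        if tp >= t:
            raise ValueError("all occurrence trials must precede t")
        strength += (t - tp) ** (-params.d)
    return params.sigma * math.log((1.0 - gamma) / gamma) + math.log(strength)


def retrieval_probabilities(
    activations: Union[Mapping[float, float], np.ndarray, Sequence[float]],
    tau: float,
) -> Union[dict[float, float], np.ndarray]:
    """Boltzmann retrieval probabilities over one option's outcomes.

    Normalization runs over the outcomes of the option under consideration
    only.  ``tau = 0`` is treated as a hard argmax with exact ties broken
    uniformly.  Computed with max-subtraction for overflow safety.
    """
    if isinstance(activations, Mapping):
        keys = list(activations)
        probs = retrieval_probabilities(
            np.array([activations[k] for k in keys], dtype=float), tau
        )
        return dict(zip(keys, probs.tolist()))
    acts = np.asarray(activations, dtype=float)
    if acts.size == 0:
        raise ValueError("retrieval requires at least one outcome")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0.0:
        best = acts == acts.max()
        return best / best.sum()
    z = acts / tau
    z = z - z.max()
    w = np.exp(z)
    return w / w.sum()


def blended_value(
    probs: Union[np.ndarray, Sequence[float]],
    outcomes: Union[np.ndarray, Sequence[float]],
) -> float:
    """Retrieval-probability-weighted mean outcome of one option."""
    p = np.asarray(probs, dtype=float)
    x = np.asarray(outcomes, dtype=float)
    if p.shape != x.shape:
        raise ValueError("probs and outcomes must be aligned")
    return float(np.dot(p, x))


def ibl_choose(values: Mapping[Option, float], rng: np.random.Generator) -> Option:
    """Deterministic argmax over blended values; exact ties by a fair coin."""
    options = list(values)
    best = max(values.values())
    tied = [opt for opt in options if values[opt] == best]
    if len(tied) == 1:
        return tied[0]
    return tied[int(rng.integers(len(tied)))]


def ibl_observe(
    memory: IBLMemory,
    trial: int,
    record: TrialRecord,
    feedback: str,
) -> IBLMemory:
    """Add the trial's instance(s) to memory (two under full feedback)."""
    if record.trial != trial:
        raise ValueError("record.trial must equal trial")
    memory.observe(record.choice, record.outcome_obtained, trial)
    if feedback == "full":
        if record.outcome_foregone is None:
            raise ValueError("full feedback requires a foregone outcome")
        memory.observe(other_option(record.choice), record.outcome_foregone, trial)
    return memory


def _draw_gamma(rng: np.random.Generator) -> float:
    g = rng.random()
    while g == 0.0:  # keep the logit finite; random() excludes 1.0 already
        g = rng.random()
    return g


def _blended_values(
    memory: IBLMemory,
    t: int,
    params: IBLParams,
    rng: np.random.Generator,
) -> dict[Option, float]:
    """One stochastic evaluation of both options' blended values at trial t."""
    values: dict[Option, float] = {}
    for opt in OPTIONS:
        xs, occ = memory.instances(opt)
        acts = np.array(
            [activation(tps, t, params, _draw_gamma(rng)) for tps in occ]
        )
        probs = retrieval_probabilities(acts, params.tau)
        values[opt] = blended_value(probs, xs)
    return values


def simulate_ibl(
    params: IBLParams,
    condition: Condition,
    rng: np.random.Generator,
    participant_id: str = "ibl-sim",
) -> ParticipantData:
    """Run one IBL agent through the task, returning its full trial record."""
    memory = IBLMemory(default_outcome=params.default_outcome)
    trials: list[TrialRecord] = []
    for t in range(1, condition.n_trials + 1):
        values = _blended_values(memory, t, params, rng)
        choice = ibl_choose(values, rng)
        rec = sample_trial(condition, t, choice, rng)
        ibl_observe(memory, t, rec, condition.feedback)
        trials.append(rec)
    ground_truth = {
        "model": "ibl",
        "d": params.d,
        "sigma": params.sigma,
        "default_outcome": params.default_outcome,
    }
    return ParticipantData(participant_id, condition, trials, ground_truth)


def _yoked_events(participant: ParticipantData) -> list[list[tuple[Option, float]]]:
    """Per trial, the (option, outcome) instances the participant observed."""
    full = participant.condition.feedback == "full"
    events: list[list[tuple[Option, float]]] = []
    for rec in participant.trials:
        trial_events = [(rec.choice, float(rec.outcome_obtained))]
        if full:
            if rec.outcome_foregone is None:
                raise ValueError("full feedback requires foregone outcomes")
            trial_events.append(
                (other_option(rec.choice), float(rec.outcome_foregone))
            )
        events.append(trial_events)
    return events


def predict_ibl_grid(
    participant: ParticipantData,
    d_values: Sequence[float],
    sigma_values: Sequence[float],
    n_sims: int,
    seed: int,
    default_outcome: float = 500.0,
    clip: bool = True,
) -> np.ndarray:
    """Yoked one-step-ahead predictions over a whole (d, sigma) grid.

    Memory is rebuilt from the participant's experienced history; at each
    trial the choice the model would make is simulated ``n_sims`` times
    over fresh gamma draws, and the prediction is the fraction of
    simulations choosing the dynamic option (exact blended-value ties count
    one half).  The same gamma stream serves every grid point (common
    random numbers), which both reduces Monte-Carlo variance and makes a
    single-point evaluation with the same seed bitwise identical to the
    corresponding grid slice.

    Returns an array of shape ``(len(d_values), len(sigma_values),
    n_trials)``; probabilities are clipped to
    ``[1/(2 n_sims), 1 - 1/(2 n_sims)]`` when ``clip`` is set.
    """
    d = np.asarray(d_values, dtype=float)
    sigma = np.asarray(sigma_values, dtype=float)
    if d.ndim != 1 or sigma.ndim != 1 or d.size == 0 or sigma.size == 0:
        raise ValueError("d_values and sigma_values must be non-empty 1-D")
    if np.any(sigma <= 0):
        raise ValueError("grid evaluation requires sigma > 0 (tau > 0)")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    inv_tau = 1.0 / (sigma * _SQRT2)  # (n_s,)

    rng = np.random.default_rng(seed)
    memory = IBLMemory(default_outcome=default_outcome)
    events = _yoked_events(participant)
    n_trials = len(events)
    out = np.empty((d.size, sigma.size, n_trials))

    for t_idx, trial_events in enumerate(events):
        t = t_idx + 1
        option_values = []
        for opt in OPTIONS:
            xs, occ = memory.instances(opt)
            n_out = len(xs)
            ln_strength = np.empty((d.size, n_out))
            for i, tps in enumerate(occ):
                lags = t - np.asarray(tps, dtype=float)  # all >= 1
                ln_strength[:, i] = np.log(
                    np.power(lags[None, :], -d[:, None]).sum(axis=1)
                )
            g = rng.random((n_sims, n_out))
            while True:  # gamma must avoid exactly 0 to keep the logit finite
                zero = g == 0.0
                if not zero.any():
                    break
                g[zero] = rng.random(int(zero.sum()))
            noise = np.log((1.0 - g) / g)  # (n_sims, n_out)
            # A / tau = noise / sqrt(2) + ln_strength / tau
            z = (
                noise[None, None, :, :] * _INV_SQRT2
                + ln_strength[:, None, None, :] * inv_tau[None, :, None, None]
            )
            z -= z.max(axis=-1, keepdims=True)
            w = np.exp(z)
            option_values.append((w * xs).sum(axis=-1) / w.sum(axis=-1))
        v_dyn, v_ref = option_values
        out[:, :, t_idx] = (
            (v_dyn > v_ref).sum(axis=-1) + 0.5 * (v_dyn == v_ref).sum(axis=-1)
        ) / n_sims
        for opt, outcome in trial_events:
            memory.observe(opt, outcome, t)

    if clip:
        floor = 1.0 / (2.0 * n_sims)
        np.clip(out, floor, 1.0 - floor, out=out)
    return out


def _predict_deterministic(
    participant: ParticipantData,
    params: IBLParams,
) -> np.ndarray:
    """sigma = 0 limit: hard argmax retrieval, predictions in {0, 1/2, 1}."""
    memory = IBLMemory(default_outcome=params.default_outcome)
    events = _yoked_events(participant)
    out = np.empty(len(events))
    for t_idx, trial_events in enumerate(events):
        t = t_idx + 1
        values = {}
        for opt in OPTIONS:
            xs, occ = memory.instances(opt)
            strengths = np.array(
                [sum((t - tp) ** (-params.d) for tp in tps) for tps in occ]
            )
            best = strengths >= strengths.max() * (1.0 - _TIE_TOL)
            values[opt] = float(xs[best].mean())
        if values[DYNAMIC] > values[REFERENCE]:
            out[t_idx] = 1.0
        elif values[DYNAMIC] < values[REFERENCE]:
            out[t_idx] = 0.0
        else:
            out[t_idx] = 0.5
        for opt, outcome in trial_events:
            memory.observe(opt, outcome, t)
    return out


def predict_ibl(
    params: IBLParams,
    participant: ParticipantData,
    n_sims: int = 1000,
    seed: int = 0,
    clip: bool = True,
    mode: str = "yoked",
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Per-trial probability that the model chooses the dynamic option.

    ``mode="yoked"`` (default) rebuilds memory from the participant's own
    experienced outcomes and simulates only the would-be choice at each
    trial — the one-step-ahead prediction used for likelihoods.
    ``mode="free_running"`` instead averages the choices of ``n_sims``
    independent closed-loop simulations of the model in the participant's
    condition (outcomes resampled from the schedule, memory driven by the
    model's own choices).
    """
    if mode == "free_running":
        base = np.random.default_rng(seed) if rng is None else rng
        counts = np.zeros(participant.condition.n_trials)
        for _ in range(n_sims):
            sim = simulate_ibl(params, participant.condition, base)
            counts += sim.choices_dynamic()
        p = counts / n_sims
    elif mode == "yoked":
        if params.sigma == 0.0:
            p = _predict_deterministic(participant, params)
        else:
            p = predict_ibl_grid(
                participant,
                [params.d],
                [params.sigma],
                n_sims,
                seed,
                default_outcome=params.default_outcome,
                clip=False,
            )[0, 0]
    else:
        raise ValueError(f"unknown prediction mode {mode!r}")
    if clip:
        floor = 1.0 / (2.0 * n_sims)
        p = np.clip(p, floor, 1.0 - floor)
    return p
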