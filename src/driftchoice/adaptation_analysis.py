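"""Behavioral and model-based adaptation analyses.

Quantities derived from trial data:

- per-period **maximization rates** (P1 = first half, P2 = second half,
  last30 = final 30 trials), the fraction of choices of the higher
  expected-value option;
- an **adaptive / non-adaptive** median split on last-30-trial
  maximization within each direction x feedback cell;
- a **high / low recency** median split on the fitted IBL decay d;
- the **calibration -> test generalization** simulation: (d, sigma) pairs
  fitted in one environment are resampled and run through another
  environment, yielding per-trial maximization curves per recency group;
- per-block risky-choice summaries (blocks of 20 trials by default).

Tie conventions: the single trial of a dynamic schedule where the two
expected values tie (trial 50 in increasing, trial 51 in decreasing under
the mirror schedule) carries no per-trial maximizing option; for
period-level rates it is labeled with its own period's modal maximizing
option.  Participants exactly at a split median go to the high/adaptive
group.  Maximization is undefined in the static condition (equal expected
values throughout); those participants are excluded with a warning.
"""
from __future__ import annotations

import math
import warnings
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ibl_model import IBLParams, simulate_ibl
from .task_env import (
    DYNAMIC,
    REFERENCE,
    Condition,
    Option,
    ParticipantData,
    maximizing_option,
)

PERIODS = ("P1", "P2", "last30")

#: Median best-fitting IBL decay d reported for the partial- and
#: full-feedback cells of the original safe-vs-risky behavioral study.
EMPIRICAL_MEDIAN_D = {
    "partial": {"decreasing": 1.39, "increasing": 0.60, "static": 0.26},
    "full": {"decreasing": 0.96, "increasing": 0.71, "static": 0.24},
}

#: Representative IBL retrieval-noise level used when simulating cohorts at
#: the empirical median d values (the study reported no differences in
#: sigma across cells and printed no median for it).
EMPIRICAL_SIGMA = 0.25


def period_trials(condition: Condition, period: str) -> range:
    """1-based trial range of a period (P1 first half, P2 rest, last30)."""
    n = condition.n_trials
    if period == "P1":
        return range(1, n // 2 + 1)
    if period == "P2":
        return range(n // 2 + 1, n + 1)
    if period == "last30":
        return range(max(n - 29, 1), n + 1)
    raise ValueError(f"unknown period {period!r}")


def period_maximizing_label(
    condition: Condition, trial: int, period: str
) -> Optional[Option]:
    """Maximizing-option label used in period-level rates.

    Equal-EV trials in a dynamic schedule inherit the modal maximizing
    option of the period that contains them; static trials stay unlabeled.
    """
    label = maximizing_option(condition, trial)
    if label is not None or condition.direction == "static":
        return label
    # modal label of the period: first labeled trial inside the period
    for probe in period_trials(condition, period):
        probed = maximizing_option(condition, probe)
        if probed is not None:
            return probed
    return None


def maximization_rate(participant: ParticipantData, period: str) -> float:
    """Fraction of the period's labeled trials on which the choice maximized.

    Returns NaN (with a warning) in the static condition, where the two
    options never differ in expected value.
    """
    condition = participant.condition
    if condition.direction == "static":
        warnings.warn(
            "maximization is undefined in the static condition; returning NaN",
            stacklevel=2,
        )
        return float("nan")
    hits = 0
    total = 0
    for t in period_trials(condition, period):
        label = period_maximizing_label(condition, t, period)
        if label is None:
            continue
        total += 1
        if participant.trials[t - 1].choice == label:
            hits += 1
    if total == 0:
        return float("nan")
    return hits / total


def risky_rate(participant: ParticipantData, period: str) -> float:
    """Fraction of the period's trials on which the dynamic option was chosen."""
    trials = period_trials(participant.condition, period)
    chosen = [participant.trials[t - 1].choice == DYNAMIC for t in trials]
    return float(np.mean(chosen))


def period_summaries(cohort: Sequence[ParticipantData]) -> pd.DataFrame:
    """Tidy table of per-participant, per-period maximization and risky rates."""
    rows = []
    for p in cohort:
        for period in PERIODS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                max_rate = maximization_rate(p, period)
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "direction": p.condition.direction,
                    "feedback": p.condition.feedback,
                    "composition": p.condition.composition,
                    "period": period,
                    "maximization_rate": max_rate,
                    "risky_rate": risky_rate(p, period),
                }
            )
    return pd.DataFrame(rows)


def _median_split(values: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """High/low split at the median; at-median goes high; flags degeneracy."""
    med = float(np.median(values))
    high = values >= med
    degenerate = bool(np.all(values == values[0]))
    return high, med, degenerate


def classify_adaptation(cohort: Sequence[ParticipantData]) -> pd.DataFrame:
    """Adaptive / non-adaptive median split on last-30-trial maximization.

    The split is computed within each direction x feedback x composition
    cell; participants at or above the cell median are labeled adaptive.
    Static-condition participants are excluded (undefined maximization).
    An all-identical cell raises a warning and is flagged ``degenerate``.
    """
    dynamic = [p for p in cohort if p.condition.direction != "static"]
    n_static = len(cohort) - len(dynamic)
    if n_static:
        warnings.warn(
            f"excluded {n_static} static-condition participants from the "
            "adaptation split (maximization undefined)",
            stacklevel=2,
        )
    if not dynamic:
        raise ValueError("no dynamic-condition participants to classify")
    rows = []
    for p in dynamic:
        rows.append(
            {
                "participant_id": p.participant_id,
                "direction": p.condition.direction,
                "feedback": p.condition.feedback,
                "composition": p.condition.composition,
                "last30_maximization": maximization_rate(p, "last30"),
            }
        )
    frame = pd.DataFrame(rows)
    out = []
    for _, cell in frame.groupby(["direction", "feedback", "composition"]):
        if len(cell) < 2:
            raise ValueError("median split needs >= 2 participants per cell")
        values = cell["last30_maximization"].to_numpy()
        high, med, degenerate = _median_split(values)
        if degenerate:
            warnings.warn(
                "degenerate adaptation split: all rates identical in a cell",
                stacklevel=2,
            )
        cell = cell.copy()
        cell["adaptation"] = np.where(high, "adaptive", "non_adaptive")
        cell["cell_median"] = med
        cell["degenerate"] = degenerate
        out.append(cell)
    return pd.concat(out, ignore_index=True)


def recency_split(
    d_values: Union[Mapping[str, float], pd.Series],
) -> tuple[pd.DataFrame, dict]:
    """High / low recency median split on fitted IBL decay d for one cell.

    Returns per-participant assignments plus summary statistics (the cell
    median and the mean d of each group).  Participants at the median go
    to the high-recency group.
    """
    if isinstance(d_values, pd.Series):
        d_values = d_values.to_dict()
    if len(d_values) < 2:
        raise ValueError("median split needs >= 2 participants")
    ids = sorted(d_values)
    values = np.array([d_values[i] for i in ids], dtype=float)
    high, med, degenerate = _median_split(values)
    if degenerate:
        warnings.warn("degenerate recency split: all d values identical",
                      stacklevel=2)
    frame = pd.DataFrame(
        {
            "participant_id": ids,
            "d": values,
            "recency": np.where(high, "high", "low"),
        }
    )
    summary = {
        "median_d": med,
        "mean_high_d": float(values[high].mean()),
        "mean_low_d": float(values[~high].mean()) if (~high).any() else float("nan"),
        "degenerate": degenerate,
    }
    return frame, summary


def generalize(
    calibration: Mapping[str, Sequence[tuple[float, float]]],
    test_condition: Condition,
    n_agents: int = 1000,
    seed: int = 0,
    default_outcome: float = 500.0,
) -> pd.DataFrame:
    """Calibration -> test simulation of recency groups.

    ``calibration`` maps a group label (e.g. ``"high"`` / ``"low"``) to its
    fitted (d, sigma) pairs.  For each group, ``n_agents`` pairs are
    resampled with replacement (pairs kept intact) and an IBL agent is
    simulated per pair in the test environment.  Returns per-trial mean
    maximization and risky-choice curves with binomial Monte-Carlo SEs.
    """
    if not calibration:
        raise ValueError("calibration groups must be non-empty")
    if test_condition.direction == "static":
        raise ValueError("generalization needs a dynamic test condition")
    n = test_condition.n_trials
    labels = [
        period_maximizing_label(
            test_condition, t, "P1" if t <= n // 2 else "P2"
        )
        for t in range(1, n + 1)
    ]
    rows = []
    for g_idx, group in enumerate(sorted(calibration)):
        pairs = np.asarray(list(calibration[group]), dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] == 0:
            raise ValueError(f"group {group!r}: need a non-empty (n, 2) array "
                             "of (d, sigma) pairs")
        rng = np.random.default_rng(np.random.SeedSequence([seed, g_idx]))
        idx = rng.integers(pairs.shape[0], size=n_agents)
        risky = np.zeros((n_agents, n), dtype=bool)
        for a in range(n_agents):
            d, sigma = pairs[idx[a]]
            params = IBLParams(d=d, sigma=sigma, default_outcome=default_outcome)
            sim = simulate_ibl(params, test_condition, rng)
            risky[a] = sim.choices_dynamic()
        maximized = np.empty((n_agents, n), dtype=bool)
        for t in range(n):
            maximized[:, t] = (
                risky[:, t] if labels[t] == DYNAMIC else ~risky[:, t]
            )
        mean_max = maximized.mean(axis=0)
        mean_risky = risky.mean(axis=0)
        se = np.sqrt(mean_max * (1.0 - mean_max) / n_agents)
        for t in range(n):
            rows.append(
                {
                    "group": group,
                    "trial": t + 1,
                    "mean_maximization": mean_max[t],
                    "mean_risky": mean_risky[t],
                    "mc_se": se[t],
                    "n_agents": n_agents,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def block_summary(
    cohort: Sequence[ParticipantData], block_size: int = 20
) -> pd.DataFrame:
    """Mean dynamic-option choice per block x condition cell.

    A trailing short block (when ``block_size`` does not divide the trial
    count) is kept and flagged with a warning.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rows = []
    warned = False
    for p in cohort:
        n = p.condition.n_trials
        if n % block_size and not warned:
            warnings.warn(
                "block_size does not divide n_trials; last block is short",
                stacklevel=2,
            )
            warned = True
        risky = p.choices_dynamic()
        for b in range(math.ceil(n / block_size)):
            chunk = risky[b * block_size : (b + 1) * block_size]
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "direction": p.condition.direction,
                    "feedback": p.condition.feedback,
                    "composition": p.condition.composition,
                    "block": b + 1,
                    "risky_rate": float(chunk.mean()),
                    "n_trials": int(chunk.size),
                }
            )
    per_participant = pd.DataFrame(rows)
    summary = (
        per_participant.groupby(
            ["direction", "feedback", "composition", "block"], as_index=False
        )
        .agg(mean_risky=("risky_rate", "mean"),
             n_participants=("participant_id", "nunique"),
             n_trials=("n_trials", "first"))
    )
    return summary
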