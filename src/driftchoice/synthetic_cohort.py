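"""Synthetic participant cohorts with known ground truth.

Generates agents from the IBL or RL models (or a mixture) under the
3 (direction) x 2 (feedback) design with 100-trial sequences, so every
pipeline stage — CSV I/O, fitting, adaptation analyses — can be exercised
against known generating parameters.

Default parameter distributions are centered on the regimes seen in
empirical fits of this task family: decay d log-normal around 0.7
(truncated to (0, 5)), retrieval noise sigma uniform on (0.05, 1.5),
delta-rule phi Beta-distributed with median near 0.17, decay-rule d_RL
Beta-distributed with median near 0.83, and softmax theta log-normal
around 2 on the scaled payoffs.  A "behavioral clone" mode draws choices
from per-block risky-choice rates instead of a model, for model-agnostic
pipeline tests.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ibl_model import IBLParams, simulate_ibl
from .rl_models import RLParams, simulate_rl
from .task_env import (
    DYNAMIC,
    OPTION_LABELS,
    REFERENCE,
    Condition,
    Option,
    ParticipantData,
    TrialRecord,
    p_high,
    sample_trial,
)

GENERATORS = ("ibl", "delta", "decay", "mixture", "clone")

TRIAL_CSV_COLUMNS = [
    "participant_id",
    "direction",
    "feedback",
    "composition",
    "trial",
    "choice",
    "choice_label",
    "outcome_obtained",
    "outcome_foregone",
    "p_high",
]

GROUND_TRUTH_COLUMNS = [
    "participant_id", "model", "d", "sigma", "phi", "d_rl", "theta",
]


class TrialCSVError(ValueError):
    """Malformed trial CSV; the message names the offending row."""


@dataclass(frozen=True)
class ParameterPriors:
    """Sampling distributions for ground-truth parameters."""

    d_meanlog: float = math.log(0.7)
    d_sdlog: float = 0.8
    d_max: float = 5.0
    sigma_low: float = 0.05
    sigma_high: float = 1.5
    phi_a: float = 1.2
    phi_b: float = 4.0
    d_rl_a: float = 6.0
    d_rl_b: float = 1.4
    theta_meanlog: float = math.log(5.0)
    theta_sdlog: float = 0.5
    default_outcome: float = 500.0
    outcome_scale: float = 500.0

    def __post_init__(self) -> None:
        if not (0 < self.sigma_low < self.sigma_high):
            raise ValueError("need 0 < sigma_low < sigma_high")
        if self.d_max <= 0 or self.d_sdlog <= 0 or self.theta_sdlog <= 0:
            raise ValueError("scale hyperparameters must be positive")
        if min(self.phi_a, self.phi_b, self.d_rl_a, self.d_rl_b) <= 0:
            raise ValueError("Beta hyperparameters must be positive")


def sample_ibl_params(priors: ParameterPriors, rng: np.random.Generator) -> IBLParams:
    d = float(rng.lognormal(priors.d_meanlog, priors.d_sdlog))
    while not d < priors.d_max:  # truncate the decay prior to (0, d_max)
        d = float(rng.lognormal(priors.d_meanlog, priors.d_sdlog))
    sigma = float(rng.uniform(priors.sigma_low, priors.sigma_high))
    return IBLParams(d=d, sigma=sigma, default_outcome=priors.default_outcome)


def sample_rl_params(
    rule: str, priors: ParameterPriors, rng: np.random.Generator
) -> RLParams:
    theta = float(rng.lognormal(priors.theta_meanlog, priors.theta_sdlog))
    if rule == "delta":
        return RLParams(
            rule="delta",
            theta=theta,
            phi=float(rng.beta(priors.phi_a, priors.phi_b)),
            outcome_scale=priors.outcome_scale,
        )
    return RLParams(
        rule="decay",
        theta=theta,
        d_rl=float(rng.beta(priors.d_rl_a, priors.d_rl_b)),
        outcome_scale=priors.outcome_scale,
    )


def _default_cells() -> tuple[Condition, ...]:
    return tuple(
        Condition(direction=d, feedback=f)
        for d in ("static", "increasing", "decreasing")
        for f in ("partial", "full")
    )


@dataclass(frozen=True)
class CohortSpec:
    """Specification of one synthetic cohort.

    ``seed`` is mandatory; every participant's generator stream derives
    from it, so the same spec always reproduces the same cohort.
    ``clone_block_rates`` (behavioral-clone mode only) gives the
    per-20-trial-block probability of choosing the risky option.
    """

    seed: int
    n_per_cell: int = 72
    cells: tuple[Condition, ...] = field(default_factory=_default_cells)
    generator: str = "mixture"
    priors: ParameterPriors = field(default_factory=ParameterPriors)
    clone_block_rates: tuple[float, ...] = (0.5, 0.5, 0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if self.generator not in GENERATORS:
            raise ValueError(f"unknown generator {self.generator!r}")
        if not self.cells:
            raise ValueError("at least one design cell is required")
        if not all(0.0 <= r <= 1.0 for r in self.clone_block_rates):
            raise ValueError("clone block rates must lie in [0, 1]")


def _simulate_clone(
    spec: CohortSpec,
    condition: Condition,
    rng: np.random.Generator,
    participant_id: str,
) -> ParticipantData:
    rates = spec.clone_block_rates
    n_blocks = len(rates)
    trials = []
    for t in range(1, condition.n_trials + 1):
        block = min((t - 1) * n_blocks // condition.n_trials, n_blocks - 1)
        choice: Option = DYNAMIC if rng.random() < rates[block] else REFERENCE
        trials.append(sample_trial(condition, t, choice, rng))
    return ParticipantData(
        participant_id, condition, trials, {"model": "clone"}
    )


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[ParticipantData], pd.DataFrame]:
    """Generate the cohort and its ground-truth table.

    Each participant gets its own RNG stream spawned from ``spec.seed``,
    a sampled generating model + parameters, and a simulated 100-trial
    record in its assigned condition.
    """
    cohort: list[ParticipantData] = []
    gt_rows: list[dict] = []
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(len(spec.cells) * spec.n_per_cell)
    idx = 0
    for condition in spec.cells:
        for _ in range(spec.n_per_cell):
            rng = np.random.default_rng(streams[idx])
            pid = f"p{idx:04d}"
            model = spec.generator
            if model == "mixture":
                model = ("ibl", "delta", "decay")[int(rng.integers(3))]
            if model == "ibl":
                params = sample_ibl_params(spec.priors, rng)
                participant = simulate_ibl(params, condition, rng, pid)
            elif model in ("delta", "decay"):
                params = sample_rl_params(model, spec.priors, rng)
                participant = simulate_rl(params, condition, rng, pid)
            else:  # behavioral clone
                participant = _simulate_clone(spec, condition, rng, pid)
            gt = participant.ground_truth or {}
            gt_rows.append(
                {
                    "participant_id": pid,
                    "model": gt.get("model", model),
                    "d": gt.get("d", np.nan),
                    "sigma": gt.get("sigma", np.nan),
                    "phi": gt.get("phi", np.nan),
                    "d_rl": gt.get("d_rl", np.nan),
                    "theta": gt.get("theta", np.nan),
                }
            )
            cohort.append(participant)
            idx += 1
    return cohort, pd.DataFrame(gt_rows, columns=GROUND_TRUTH_COLUMNS)


def _format_points(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(float(value))


def write_trial_csv(cohort: Sequence[ParticipantData], path) -> None:
    """Write the long-format trial CSV (one row per participant x trial).

    Missing foregone outcomes (partial feedback) are written as empty
    fields, never 0.  Floats are written with full precision so the file
    round-trips losslessly.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIAL_CSV_COLUMNS)
        for p in cohort:
            c = p.condition
            for rec in p.trials:
                writer.writerow(
                    [
                        p.participant_id,
                        c.direction,
                        c.feedback,
                        c.composition,
                        rec.trial,
                        rec.choice,
                        OPTION_LABELS[rec.choice],
                        _format_points(rec.outcome_obtained),
                        ""
                        if rec.outcome_foregone is None
                        else _format_points(rec.outcome_foregone),
                        repr(float(rec.p_high)),
                    ]
                )


def write_ground_truth_csv(ground_truth: pd.DataFrame, path) -> None:
    ground_truth.to_csv(path, index=False)


def read_trial_csv(path) -> list[ParticipantData]:
    """Read and validate a long-format trial CSV.

    Raises :class:`TrialCSVError` naming the offending row on schema
    violations, non-contiguous trials, missing/surplus foregone outcomes,
    or outcomes outside the condition's payoff support.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TrialCSVError("empty file: header row required")
        missing = set(TRIAL_CSV_COLUMNS) - {"choice_label"} - set(reader.fieldnames)
        if missing:
            raise TrialCSVError(f"missing columns: {sorted(missing)}")
        groups: dict[str, list[tuple[int, dict]]] = {}
        order: list[str] = []
        for line, row in enumerate(reader, start=2):
            pid = row["participant_id"]
            if pid not in groups:
                groups[pid] = []
                order.append(pid)
            groups[pid].append((line, row))

    cohort = []
    for pid in order:
        rows = groups[pid]
        first_line, first = rows[0]
        try:
            condition = Condition(
                direction=first["direction"],
                feedback=first["feedback"],
                composition=first["composition"],
                n_trials=len(rows),
            )
        except ValueError as exc:
            raise TrialCSVError(f"row {first_line}: {exc}") from exc
        records = []
        for line, row in rows:
            if (row["direction"], row["feedback"], row["composition"]) != (
                condition.direction, condition.feedback, condition.composition
            ):
                raise TrialCSVError(
                    f"row {line}: condition labels change within "
                    f"participant {pid!r}"
                )
            try:
                trial = int(row["trial"])
                obtained = float(row["outcome_obtained"])
                foregone_field = row["outcome_foregone"]
                foregone = None if foregone_field == "" else float(foregone_field)
                p = float(row["p_high"])
            except (TypeError, ValueError) as exc:
                raise TrialCSVError(f"row {line}: unparseable field ({exc})")
            choice = row["choice"]
            if choice not in (DYNAMIC, REFERENCE):
                raise TrialCSVError(f"row {line}: unknown choice {choice!r}")
            if trial != len(records) + 1:
                raise TrialCSVError(
                    f"row {line}: trial {trial} out of order for {pid!r} "
                    f"(expected {len(records) + 1})"
                )
            if obtained not in condition.payoff_support(choice):
                raise TrialCSVError(
                    f"row {line}: outcome {obtained} outside the payoff "
                    f"support of the {choice} option"
                )
            full = condition.feedback == "full"
            if full and foregone is None:
                raise TrialCSVError(
                    f"row {line}: missing foregone outcome under full feedback"
                )
            if not full and foregone is not None:
                raise TrialCSVError(
                    f"row {line}: foregone outcome present under partial "
                    "feedback"
                )
            if full:
                other = REFERENCE if choice == DYNAMIC else DYNAMIC
                if foregone not in condition.payoff_support(other):
                    raise TrialCSVError(
                        f"row {line}: foregone outcome {foregone} outside "
                        f"the payoff support of the {other} option"
                    )
            records.append(TrialRecord(trial, choice, obtained, foregone, p))
        try:
            cohort.append(ParticipantData(pid, condition, records))
        except ValueError as exc:
            raise TrialCSVError(f"participant {pid!r}: {exc}") from exc
    return cohort


def read_ground_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
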