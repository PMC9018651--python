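"""Individual-level maximum-likelihood fitting.

The IBL model has a deterministic choice rule with stochastic activations,
so its per-trial choice probability has no closed form; following the
Monte-Carlo MLE approach, each candidate (d, sigma) pair is scored by
simulating the would-be choice ``n_sims`` times per trial (yoked to the
participant's experienced history) and averaging, over an exhaustive
(d, sigma) grid with common random numbers across grid points.  The full
grid is 0 < d < 5 and 0 < sigma < 3 in 0.01 steps with 1,000 predictions
per trial; the default profile uses a 0.1 step with 200 predictions, which
estimates the same surface at lower resolution.

The RL models have closed-form likelihoods and are fitted by multi-start
Nelder-Mead in an unbounded reparameterization (logit for phi / d_RL, log
for theta, with theta capped at ``theta_max``), starting from a Latin
hypercube over the natural parameter box.

Predicted probabilities are clipped to [1/(2 n_sims), 1 - 1/(2 n_sims)]
(IBL) or [1e-12, 1 - 1e-12] (RL) before the likelihood so a finite NLL
always exists.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import qmc

from .ibl_model import IBLParams, predict_ibl_grid
from .rl_models import RLParams, predict_rl
from .task_env import ParticipantData

_RL_CLIP = 1e-12

FIT_TABLE_COLUMNS = [
    "participant_id",
    "model",
    "d",
    "sigma",
    "phi",
    "d_rl",
    "theta",
    "nll",
    "n_params",
    "n_sims_or_starts",
    "seed",
]


@dataclass(frozen=True)
class GridSpec:
    """Grid-search specification for the IBL model.

    Ranges are (low, high, step) over the open intervals 0 < d < 5 and
    0 < sigma < 3; ``n_sims`` is the number of Monte-Carlo predictions per
    trial and grid point; ``seed`` drives the shared gamma stream (common
    random numbers across grid points).
    """

    d_range: tuple[float, float, float] = (0.01, 4.99, 0.1)
    sigma_range: tuple[float, float, float] = (0.01, 2.99, 0.1)
    n_sims: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for low, high, step in (self.d_range, self.sigma_range):
            if not (low > 0 and high > low and step > 0):
                raise ValueError("grid ranges require 0 < low < high, step > 0")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")

    @classmethod
    def full_profile(cls, seed: int = 0) -> "GridSpec":
        """Full-resolution profile: 0.01 steps, 1,000 predictions per trial."""
        return cls(
            d_range=(0.01, 4.99, 0.01),
            sigma_range=(0.01, 2.99, 0.01),
            n_sims=1000,
            seed=seed,
        )

    def d_values(self) -> np.ndarray:
        low, high, step = self.d_range
        return np.arange(low, high + 1e-12, step)

    def sigma_values(self) -> np.ndarray:
        low, high, step = self.sigma_range
        return np.arange(low, high + 1e-12, step)


@dataclass
class FitResult:
    """Best-fitting parameters for one participant under one model."""

    participant_id: str
    model: str  # "ibl", "delta" or "decay"
    params: dict
    nll: float
    n_params: int
    metadata: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def aic(self) -> float:
        return 2.0 * self.nll + 2.0 * self.n_params

    def bic(self, n_trials: int) -> float:
        return 2.0 * self.nll + self.n_params * math.log(n_trials)


def negative_log_likelihood(
    predictions: Sequence[float], choices_dynamic: Sequence[bool]
) -> float:
    """Bernoulli NLL (nats) of observed choices under per-trial predictions.

    ``predictions`` are P(choose dynamic); ``choices_dynamic`` is truthy
    where the dynamic option was chosen.  Predictions must already be
    clipped inside (0, 1).
    """
    p = np.asarray(predictions, dtype=float)
    c = np.asarray(choices_dynamic, dtype=float)
    if p.shape != c.shape:
        raise ValueError("predictions and choices must be aligned")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("predictions must lie strictly inside (0, 1)")
    return float(-(c * np.log(p) + (1.0 - c) * np.log1p(-p)).sum())


def fit_ibl(
    participant: ParticipantData,
    grid: GridSpec = GridSpec(),
    default_outcome: float = 500.0,
) -> FitResult:
    """Exhaustive grid search for the IBL (d, sigma) pair.

    Every grid point is evaluated with the same gamma stream (``grid.seed``),
    so refitting with the same spec is bitwise reproducible.  Ties in NLL
    are broken toward smaller d, then smaller sigma (the grid is scanned in
    d-major order and only strict improvements replace the incumbent).
    """
    d_vals = grid.d_values()
    s_vals = grid.sigma_values()
    preds = predict_ibl_grid(
        participant,
        d_vals,
        s_vals,
        grid.n_sims,
        grid.seed,
        default_outcome=default_outcome,
        clip=True,
    )
    c = participant.choices_dynamic().astype(float)
    nll = -(
        c * np.log(preds) + (1.0 - c) * np.log1p(-preds)
    ).sum(axis=-1)  # (n_d, n_s)
    flat = int(np.argmin(nll))  # first minimum in C order = smallest d, sigma
    i, j = divmod(flat, s_vals.size)
    return FitResult(
        participant_id=participant.participant_id,
        model="ibl",
        params={"d": float(d_vals[i]), "sigma": float(s_vals[j])},
        nll=float(nll[i, j]),
        n_params=2,
        metadata={
            "d_step": grid.d_range[2],
            "sigma_step": grid.sigma_range[2],
            "n_sims": grid.n_sims,
            "seed": grid.seed,
            "default_outcome": default_outcome,
            "clip_floor": 1.0 / (2.0 * grid.n_sims),
        },
    )


def _rl_nll(z: np.ndarray, participant: ParticipantData, rule: str,
            theta_max: float, outcome_scale: float, e0: float) -> float:
    learn = float(expit(z[0]))
    theta = min(float(np.exp(z[1])), theta_max)
    kwargs = {"phi": learn} if rule == "delta" else {"d_rl": learn}
    params = RLParams(
        rule=rule, theta=theta, outcome_scale=outcome_scale, e0=e0, **kwargs
    )
    p = np.clip(predict_rl(params, participant), _RL_CLIP, 1.0 - _RL_CLIP)
    return negative_log_likelihood(p, participant.choices_dynamic())


def fit_rl(
    participant: ParticipantData,
    rule: str,
    n_starts: int = 10,
    seed: int = 0,
    theta_max: float = 20.0,
    outcome_scale: float = 500.0,
    e0: float = 0.0,
) -> FitResult:
    """Multi-start Nelder-Mead MLE for a delta or decay RL model.

    ``n_starts`` start points are drawn from a Latin hypercube over the
    natural box (phi or d_RL in (0, 1), theta log-uniform in
    (0.05, 0.9 * theta_max)); each start is polished by Nelder-Mead in the
    transformed space and the lowest-NLL solution wins.
    """
    if rule not in ("delta", "decay"):
        raise ValueError(f"unknown RL rule {rule!r}")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    sampler = qmc.LatinHypercube(d=2, seed=seed)
    u = sampler.random(n_starts)
    learn0 = 0.02 + 0.96 * u[:, 0]
    log_lo, log_hi = math.log(0.05), math.log(0.9 * theta_max)
    theta0 = np.exp(log_lo + (log_hi - log_lo) * u[:, 1])

    best = None
    any_converged = False
    args = (participant, rule, theta_max, outcome_scale, e0)
    for k in range(n_starts):
        z0 = np.array([logit(learn0[k]), math.log(theta0[k])])
        res = minimize(
            _rl_nll,
            z0,
            args=args,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    learn = float(expit(best.x[0]))
    theta = min(float(np.exp(best.x[1])), theta_max)
    params = {"theta": theta}
    params["phi" if rule == "delta" else "d_rl"] = learn
    return FitResult(
        participant_id=participant.participant_id,
        model=rule,
        params=params,
        nll=float(best.fun),
        n_params=2,
        metadata={
            "n_starts": n_starts,
            "seed": seed,
            "theta_max": theta_max,
            "outcome_scale": outcome_scale,
            "e0": e0,
            "clip_floor": _RL_CLIP,
        },
        converged=any_converged,
    )


def _participant_seed(base_seed: int, index: int, model_index: int) -> int:
    ss = np.random.SeedSequence([base_seed, index, model_index])
    return int(ss.generate_state(1)[0] % (2**31))


def fit_result_row(result: FitResult) -> dict:
    """Tidy fit-table row (unused parameter cells left missing)."""
    row = {col: np.nan for col in FIT_TABLE_COLUMNS}
    row["participant_id"] = result.participant_id
    row["model"] = result.model
    row["nll"] = result.nll
    row["n_params"] = result.n_params
    for key in ("d", "sigma", "phi", "d_rl", "theta"):
        if key in result.params:
            row[key] = result.params[key]
    row["n_sims_or_starts"] = result.metadata.get(
        "n_sims", result.metadata.get("n_starts", np.nan)
    )
    row["seed"] = result.metadata.get("seed", np.nan)
    return row


def fit_cohort(
    cohort: Sequence[ParticipantData],
    models: Iterable[str] = ("ibl", "delta", "decay"),
    grid: Optional[GridSpec] = None,
    n_starts: int = 10,
    seed: int = 0,
    progress: bool = False,
) -> tuple[list[FitResult], pd.DataFrame]:
    """Fit every model to every participant; returns results and a tidy table.

    Per-participant failures are logged into the result (``converged``
    False, NLL NaN) rather than aborting the cohort.  The returned frame
    also carries the participant's condition cell (direction, feedback,
    composition) for downstream grouping.
    """
    models = list(models)
    if not models:
        raise ValueError("at least one model must be requested")
    unknown = set(models) - {"ibl", "delta", "decay"}
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    if not cohort:
        raise ValueError("cohort must be non-empty")
    results: list[FitResult] = []
    rows: list[dict] = []
    for p_idx, participant in enumerate(cohort):
        for m_idx, model in enumerate(models):
            sub_seed = _participant_seed(seed, p_idx, m_idx)
            try:
                if model == "ibl":
                    spec = grid if grid is not None else GridSpec()
                    spec = GridSpec(
                        d_range=spec.d_range,
                        sigma_range=spec.sigma_range,
                        n_sims=spec.n_sims,
                        seed=sub_seed,
                    )
                    result = fit_ibl(participant, spec)
                else:
                    result = fit_rl(
                        participant, model, n_starts=n_starts, seed=sub_seed
                    )
            except Exception as exc:  # pragma: no cover - defensive
                result = FitResult(
                    participant.participant_id,
                    model,
                    {},
                    float("nan"),
                    2,
                    metadata={"error": str(exc), "seed": sub_seed},
                    converged=False,
                )
            results.append(result)
            row = fit_result_row(result)
            row["direction"] = participant.condition.direction
            row["feedback"] = participant.condition.feedback
            row["composition"] = participant.condition.composition
            rows.append(row)
            if progress:  # pragma: no cover - console side effect
                print(
                    f"fitted {participant.participant_id} with {model}: "
                    f"nll={result.nll:.2f}"
                )
    table = pd.DataFrame(rows)
    return results, table


def parameter_medians(
    fit_table: pd.DataFrame,
    by: Sequence[str] = ("model", "direction", "feedback"),
) -> pd.DataFrame:
    """Per-cell medians of the fitted parameters (the tabulated summaries)."""
    value_cols = [c for c in ("d", "sigma", "phi", "d_rl", "theta")
                  if c in fit_table.columns]
    return (
        fit_table.groupby(list(by), dropna=False)[value_cols]
        .median()
        .reset_index()
    )
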