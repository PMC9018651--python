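# Methods

## Task environment

The environment is a two-armed bandit with one *dynamic* option (0 or 500
points) and one *reference* option (a sure 250, or in the risky-risky
composition a static 0/500 gamble at p = .50).  The dynamic option's
high-outcome probability is linear in the trial index: .50 throughout
(static), .01 → 1.00 (increasing), or the exact trial-reversed mirror
1.00 → .01 (decreasing).  For 100 trials these are p(t) = .01·t and
p(t) = 1.01 − .01·t; for other lengths the same endpoints are linearly
interpolated.  The mirror construction means the increasing schedule
crosses even odds exactly at trial 50 while the decreasing schedule
crosses at trial 51; no constant-step schedule that starts at 1.00 and
ends at .01 can put its crossing at trial 50, so the mirror (which honors
the stated endpoints and step size) is used and the crossing asymmetry is
accepted.

A per-trial *maximizing option* is defined by comparing expected values;
it is undefined on exact-tie trials and throughout the static condition.
For period-level maximization rates the single tied trial of a dynamic
schedule is labeled with its own period's modal maximizing option (trial
50 with the first period's, trial 51 with the second period's).  This
keeps the two directions exactly exchangeable: reversing a choice
sequence in time and flipping the direction swaps its two period scores,
a property the test suite asserts.

## Instance-based learning model

Activation combines power-law decay of an outcome's past occurrences with
logistic retrieval noise:

    A_{j,i,t} = σ ln((1 − γ_{j,i,t})/γ_{j,i,t}) + ln Σ_{t_p} (t − t_p)^{−d}

One γ ~ Uniform(0,1) is drawn per (option, outcome, trial) — noise is not
shared across outcomes — and γ is redrawn on an exact 0 so the log-odds
stay finite.  Retrieval probabilities are Boltzmann weights over the
*same option's* outcomes at temperature τ = σ√2 (computed with
max-subtraction); τ = 0 degenerates to a hard argmax with uniform ties.
The blended value is the retrieval-probability-weighted mean outcome, and
choice is a deterministic argmax over blended values with a fair-coin tie
break.  Under full feedback each trial stores two instances (obtained and
foregone); under partial feedback, one.

**Cold start.**  Each option is prepopulated with a single optimistic
pseudo-instance (value 500, occurrence time 0).  It is deleted the first
time the option is actually experienced.  Optimistic prepopulation makes
the very first trials exploratory, which is the conventional way to give
the model a defined first choice; the pseudo-instance value is a
configurable parameter (`default_outcome`) and is recorded in fit
metadata.

**Prediction for fitting.**  The choice rule is deterministic but the
activations are stochastic, so per-trial choice probabilities are
estimated by Monte Carlo: memory is rebuilt from the participant's own
experienced outcomes (yoked, one-step-ahead), and at each trial the
would-be choice is simulated n_sims times over fresh γ draws; the
prediction is the fraction choosing the dynamic option, with exact
blended-value ties counting one half.  A free-running variant (closed-loop
simulation scored against observed choices) is available behind a flag but
is not used for likelihoods.  Predictions are clipped to
[1/(2·n_sims), 1 − 1/(2·n_sims)] before the Bernoulli likelihood so a
single Monte-Carlo zero cannot produce an infinite deviance; the floor is
recorded in fit metadata.

## Reinforcement-learning models

Delta rule (learning rate φ ∈ [0,1]) and decay rule (retention
d_RL ∈ [0,1]; the unchosen option's expectancy is discounted every trial)
with a shared softmax inverse temperature θ ≥ 0.  Payoffs are divided by
`outcome_scale` = 500 before updating so expectancies lie in [0,1] and θ
is O(1); initial expectancies are 0 (both configurable and recorded in fit
metadata).  Under full feedback both options are updated every trial,
which makes the expectancy trajectory — and hence the predicted
probabilities — independent of the choice sequence; the suite asserts
this.  One-step-ahead probabilities are exact, no Monte Carlo needed.

## Fitting

- **IBL:** exhaustive grid over 0 < d < 5 and 0 < σ < 3.  The
  full-resolution profile (`GridSpec.full_profile()`) uses 0.01 steps and
  1,000 predictions per trial; the default profile uses 0.1 steps and 200
  predictions, which estimates the same likelihood surface at lower
  resolution and is what the bundled studies use.  All grid points share
  one γ stream (common random numbers): this reduces comparison variance
  and makes a single-point evaluation bitwise equal to its grid slice,
  which the suite asserts.  NLL ties break toward smaller d, then smaller
  σ.
- **RL:** multi-start Nelder–Mead in an unbounded space (logit for
  φ/d_RL, log for θ) from a Latin-hypercube design over φ, d_RL ∈
  (0.02, 0.98) and θ log-uniform in (0.05, 18).  θ is capped at 20:
  on unit-scaled payoffs, exp(20·ΔE) already saturates the softmax far
  beyond behavioral resolution.  The default is 10 starts (the likelihood
  surface is two-dimensional and smooth; pilot runs showed identical
  optima at 5 vs 10 starts); the full profile uses 100.
- AIC/BIC are exposed on `FitResult` for descriptive comparison only.

## Synthetic cohorts

`generate_cohort` emulates the 3 (direction) × 2 (feedback) design with
100-trial sequences and known generating parameters.  Default priors:
d ~ LogNormal(ln 0.7, 0.8) truncated to (0, 5) and σ ~ Uniform(0.05, 1.5),
spanning the range of empirical median decay estimates (0.24–1.39 across
cells); φ ~ Beta(1.2, 4) (median ≈ 0.17) and d_RL ~ Beta(6, 1.4)
(median ≈ 0.83), matching the small-updating regimes of empirical fits;
θ ~ LogNormal(ln 5, 0.5) on scaled payoffs, chosen so simulated cohorts
reproduce human-like choice consistency (mean second-period maximization
near .64 rather than near-chance responding).  A behavioral-clone mode
draws choices from per-block risky rates for model-agnostic pipeline
tests.

What the generator does **not** emulate: explicit awareness of change,
choice inertia or autocorrelation beyond what the models produce,
individual risk attitudes, dropout, or any deviation of real participants
from the three model families.  Passing recovery and replication tests
therefore validates the pipeline's internal consistency on model-generated
data, not the models' adequacy for human data.

## Bundled studies (problem sizes)

- **Parameter recovery.**  RL: 40 agents per rule, 100 trials, priors
  above, fitted with 10 starts; run in the increasing/full-feedback cell,
  where the learning-rate signal is strongest (the expectancy must chase a
  rising probability through the turning point).  IBL: 20 agents in the
  decreasing/full-feedback cell, coarse 0.25-step grid with 200
  predictions per trial.  Recovery is summarized by Spearman correlation
  between generating and recovered values.
- **Directional replication.**  500 partial-feedback IBL agents per
  direction at the empirical median decay values (d = 1.39 decreasing,
  d = 0.60 increasing) and σ = 0.25 — a representative retrieval-noise
  level, adopted because the source fits report no σ differences across
  cells and print no σ median.  The claim checked is sign-only: higher
  mean second-period maximization in the decreasing direction.
- **Recency generalization.**  60 (d, σ) pairs drawn from the priors form
  the calibration pool; a median split on d defines high/low-recency
  groups; 500 agents per group are simulated in each *full-feedback*
  dynamic test environment by resampling intact pairs.  Full feedback is
  the informative test bed here: under partial feedback the deterministic
  choice rule produces an absorbing hot-stove state in the improving
  environment (an agent whose only risky memories are zeros can never
  re-sample the risky option), so both groups floor at zero and the
  high-vs-low contrast is degenerate.  The checked property is that
  high-recency groups out-maximize low-recency groups in trials 51–100 of
  both directions.

## Numerical choices and degenerate inputs

Expected-value ties use a 1e-9 absolute tolerance.  Softmax and retrieval
weights are max-subtracted.  RL predictions are clipped at 1e-12 for the
likelihood.  Median splits send at-median values to the high/adaptive
group; an all-identical cell is flagged degenerate with a warning rather
than an error.  Static-condition participants are excluded from
maximization-based analyses (the rate is undefined), with a warning.  All
stochastic operations take an explicit seed or `numpy` Generator and are
bitwise reproducible from it.

## Known limitations

Only linear, monotone probability schedules are implemented.  The IBL
activation is the reduced form (no spreading activation or partial
matching).  The reader reconstructs conditions from the CSV's labels and
default payoffs; nonstandard payoff magnitudes do not round-trip through
the trial CSV.  Grid-search resolution bounds the precision of IBL
estimates to the grid step, and recovered d values are censored at the
grid edge (4.76 on the coarse grid) for generating values near the
truncation bound.
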