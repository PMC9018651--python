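import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from driftchoice import (
    Condition,
    DYNAMIC,
    IBLMemory,
    IBLParams,
    REFERENCE,
    TrialRecord,
    activation,
    blended_value,
    ibl_choose,
    ibl_observe,
    predict_ibl,
    predict_ibl_grid,
    retrieval_probabilities,
    simulate_ibl,
)


class TestActivation:
    @pytest.mark.parametrize("d", [0.0, 0.5, 2.0])
    def test_single_lag_one_instance_is_zero(self, d):
        assert activation([9], 10, IBLParams(d=d, sigma=0.0), 0.3) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_single_instance_decays_with_lag(self):
        params = IBLParams(d=1.0, sigma=0.0)
        assert activation([1], 5, params, 0.5) == pytest.approx(
            math.log(0.25), abs=1e-10
        )

    def test_zero_decay_counts_instances(self):
        params = IBLParams(d=0.0, sigma=0.0)
        assert activation([3, 4], 5, params, 0.5) == pytest.approx(
            math.log(2.0), abs=1e-10
        )

    def test_noise_term_uses_log_odds_of_gamma(self):
        params = IBLParams(d=0.0, sigma=2.0)
        expected = 2.0 * math.log(0.75 / 0.25)  # single lag-1 instance: ln 1 = 0
        assert activation([4], 5, params, 0.25) == pytest.approx(expected, abs=1e-10)

    def test_contract_violations(self):
        params = IBLParams(d=1.0, sigma=0.5)
        with pytest.raises(ValueError):
            activation([], 5, params, 0.5)
        with pytest.raises(ValueError):
            activation([5], 5, params, 0.5)
        for gamma in (0.0, 1.0):
            with pytest.raises(ValueError):
                activation([1], 5, params, gamma)

    def test_older_instance_loses_activation_as_d_grows(self):
        # recency monotonicity: lag-L activation strictly decreases in d
        lag_l = [
            activation([0], 8, IBLParams(d=d, sigma=0.0), 0.5)
            for d in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(b < a for a, b in zip(lag_l, lag_l[1:]))
        # at d = 0 the lag-1 and lag-L activations coincide
        assert activation([7], 8, IBLParams(d=0.0, sigma=0.0), 0.5) == pytest.approx(
            lag_l[0]
        )


class TestRetrieval:
    def test_single_outcome_is_certain(self):
        assert retrieval_probabilities({250.0: -3.7}, tau=1.0) == {250.0: 1.0}

    def test_equal_activations_split_evenly(self):
        probs = retrieval_probabilities(np.array([0.2, 0.2]), tau=0.8)
        assert probs == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_boltzmann_weights(self):
        probs = retrieval_probabilities({0.0: 0.0, 500.0: math.log(2.0)}, tau=1.0)
        assert probs[0.0] == pytest.approx(1.0 / 3.0, abs=1e-10)
        assert probs[500.0] == pytest.approx(2.0 / 3.0, abs=1e-10)

    def test_zero_tau_is_hard_argmax_with_uniform_ties(self):
        assert retrieval_probabilities(np.array([1.0, 3.0]), tau=0.0) == pytest.approx(
            [0.0, 1.0]
        )
        assert retrieval_probabilities(
            np.array([2.0, 2.0, 0.0]), tau=0.0
        ) == pytest.approx([0.5, 0.5, 0.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            retrieval_probabilities(np.array([]), tau=1.0)

    @settings(derandomize=True, max_examples=60)
    @given(
        acts=st.lists(
            st.floats(min_value=-50, max_value=50), min_size=1, max_size=6
        ),
        tau=st.floats(min_value=1e-3, max_value=10.0),
    )
    def test_always_a_simplex(self, acts, tau):
        probs = retrieval_probabilities(np.array(acts), tau)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestBlendedValue:
    def test_examples(self):
        assert blended_value([1.0], [250.0]) == pytest.approx(250.0)
        assert blended_value([0.5, 0.5], [0.0, 500.0]) == pytest.approx(250.0)
        assert blended_value([1 / 3, 2 / 3], [0.0, 500.0]) == pytest.approx(
            1000.0 / 3.0, abs=1e-10
        )

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError):
            blended_value([0.5, 0.5], [250.0])

    @settings(derandomize=True, max_examples=40)
    @given(
        weights=st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                         max_size=5),
        outcomes=st.lists(st.floats(min_value=0, max_value=500), min_size=5,
                          max_size=5),
    )
    def test_lies_within_outcome_range(self, weights, outcomes):
        w = np.array(weights)
        x = np.array(outcomes[: len(w)])
        probs = w / w.sum()
        v = blended_value(probs, x)
        assert x.min() - 1e-9 <= v <= x.max() + 1e-9


def test_choose_strict_argmax(rng):
    assert ibl_choose({DYNAMIC: 300.0, REFERENCE: 250.0}, rng) == DYNAMIC
    assert ibl_choose({DYNAMIC: 0.0, REFERENCE: 250.0}, rng) == REFERENCE


def test_choose_breaks_ties_fairly(rng):
    picks = [
        ibl_choose({DYNAMIC: 250.0, REFERENCE: 250.0}, rng) for _ in range(10_000)
    ]
    assert np.mean([p == DYNAMIC for p in picks]) == pytest.approx(0.5, abs=0.02)


class TestMemory:
    def test_prepopulation_removed_on_first_real_instance(self):
        mem = IBLMemory(default_outcome=500.0)
        assert mem.is_prepopulated(DYNAMIC)
        assert mem.occurrences(DYNAMIC, 500.0) == [0]
        mem.observe(DYNAMIC, 0.0, 3)
        assert not mem.is_prepopulated(DYNAMIC)
        assert mem.occurrences(DYNAMIC, 500.0) == []
        assert mem.occurrences(DYNAMIC, 0.0) == [3]
        assert mem.is_prepopulated(REFERENCE)  # untouched option keeps its seed

    def test_partial_observe_adds_one_instance(self):
        mem = IBLMemory()
        rec = TrialRecord(7, DYNAMIC, 500.0, None, 0.3)
        ibl_observe(mem, 7, rec, "partial")
        assert mem.occurrences(DYNAMIC, 500.0) == [7]
        assert mem.is_prepopulated(REFERENCE)

    def test_full_observe_adds_both_instances(self):
        mem = IBLMemory()
        rec = TrialRecord(7, DYNAMIC, 500.0, 250.0, 0.3)
        ibl_observe(mem, 7, rec, "full")
        assert mem.occurrences(DYNAMIC, 500.0) == [7]
        assert mem.occurrences(REFERENCE, 250.0) == [7]

    def test_full_observe_requires_foregone(self):
        mem = IBLMemory()
        rec = TrialRecord(7, DYNAMIC, 500.0, None, 0.3)
        with pytest.raises(ValueError):
            ibl_observe(mem, 7, rec, "full")

    def test_occurrences_strictly_increasing(self):
        mem = IBLMemory()
        mem.observe(DYNAMIC, 0.0, 3)
        with pytest.raises(ValueError):
            mem.observe(DYNAMIC, 0.0, 3)


def test_blended_values_match_hand_evaluated_equations():
    """Brute-force oracle: fixed memory and gammas, direct formula."""
    d, sigma = 0.7, 0.4
    tau = sigma * math.sqrt(2.0)
    t = 6
    store = {  # outcome -> occurrence trials for the dynamic option
        0.0: [2, 3],
        500.0: [5],
    }
    gammas = {0.0: 0.31, 500.0: 0.62}
    # independent evaluation, written out term by term
    acts = {}
    for outcome, tps in store.items():
        strength = sum((t - tp) ** (-d) for tp in tps)
        acts[outcome] = sigma * math.log(
            (1 - gammas[outcome]) / gammas[outcome]
        ) + math.log(strength)
    w0 = math.exp(acts[0.0] / tau)
    w500 = math.exp(acts[500.0] / tau)
    expected_v = (w0 * 0.0 + w500 * 500.0) / (w0 + w500)

    params = IBLParams(d=d, sigma=sigma)
    model_acts = {
        outcome: activation(tps, t, params, gammas[outcome])
        for outcome, tps in store.items()
    }
    probs = retrieval_probabilities(model_acts, params.tau)
    got = blended_value(
        [probs[0.0], probs[500.0]], [0.0, 500.0]
    )
    assert got == pytest.approx(expected_v, abs=1e-10)


class TestSimulate:
    def test_reproducible_from_seed(self):
        cond = Condition("static", "partial")
        params = IBLParams(d=0.5, sigma=0.0)
        a = simulate_ibl(params, cond, np.random.default_rng(7))
        b = simulate_ibl(params, cond, np.random.default_rng(7))
        assert a.trials == b.trials

    def test_instance_counts_by_feedback(self):
        params = IBLParams(d=1.0, sigma=0.3)
        for feedback, per_trial in (("partial", 1), ("full", 2)):
            cond = Condition("static", feedback, n_trials=40)
            rng = np.random.default_rng(3)
            sim = simulate_ibl(params, cond, rng)
            mem = IBLMemory()
            for t, rec in enumerate(sim.trials, start=1):
                ibl_observe(mem, t, rec, feedback)
            total = mem.n_instances(DYNAMIC) + mem.n_instances(REFERENCE)
            if feedback == "partial":
                assert total == 40
            else:
                assert total == 80

    def test_optimistic_prepopulation_forces_early_exploration(self):
        params = IBLParams(d=1.0, sigma=0.25, default_outcome=500.0)
        cond = Condition("static", "partial")
        rng = np.random.default_rng(11)
        tried_both = 0
        n_agents = 300
        for _ in range(n_agents):
            sim = simulate_ibl(params, cond, rng)
            first3 = {rec.choice for rec in sim.trials[:3]}
            tried_both += len(first3) == 2
        assert tried_both / n_agents > 0.8

    def test_strong_recency_tracks_falling_probability(self):
        params = IBLParams(d=10.0, sigma=0.25)
        cond = Condition("decreasing", "full")
        rng = np.random.default_rng(29)
        early, late = [], []
        for _ in range(500):
            risky = simulate_ibl(params, cond, rng).choices_dynamic()
            early.append(risky[:30].mean())
            late.append(risky[70:].mean())
        assert np.mean(late) < np.mean(early)


class TestPredict:
    def test_first_trial_is_symmetric_under_prepopulation(self):
        cond = Condition("static", "partial")
        sim = simulate_ibl(IBLParams(d=1.0, sigma=0.3), cond,
                           np.random.default_rng(5))
        p = predict_ibl(IBLParams(d=1.0, sigma=0.3), sim, n_sims=1000, seed=9)
        assert p[0] == pytest.approx(0.5, abs=0.03)

    def test_zero_noise_predictions_are_degenerate(self):
        cond = Condition("decreasing", "full")
        sim = simulate_ibl(IBLParams(d=1.0, sigma=0.5), cond,
                           np.random.default_rng(5))
        p = predict_ibl(IBLParams(d=1.0, sigma=0.0), sim, n_sims=100, clip=False)
        assert set(np.unique(p)).issubset({0.0, 0.5, 1.0})

    def test_grid_slice_bitwise_matches_single_evaluation(self):
        cond = Condition("increasing", "full")
        sim = simulate_ibl(IBLParams(d=1.2, sigma=0.4), cond,
                           np.random.default_rng(2))
        grid = predict_ibl_grid(sim, [0.5, 1.2], [0.4, 0.9], 150, seed=77)
        single = predict_ibl(IBLParams(d=1.2, sigma=0.4), sim, n_sims=150,
                             seed=77)
        assert np.array_equal(grid[1, 0], single)

    def test_predictions_stable_in_n_sims(self):
        cond = Condition("decreasing", "partial")
        sim = simulate_ibl(IBLParams(d=1.0, sigma=0.4), cond,
                           np.random.default_rng(3))
        params = IBLParams(d=1.0, sigma=0.4)
        p_small = predict_ibl(params, sim, n_sims=100, seed=1)
        p_large = predict_ibl(params, sim, n_sims=10_000, seed=2)
        rms = np.sqrt(np.mean((p_small - p_large) ** 2))
        assert rms < 0.06  # ~ 1/(2 sqrt(100)) Monte-Carlo error

    def test_clipping_floor(self):
        cond = Condition("static", "partial", n_trials=10)
        sim = simulate_ibl(IBLParams(d=1.0, sigma=0.2), cond,
                           np.random.default_rng(4))
        p = predict_ibl(IBLParams(d=1.0, sigma=0.2), sim, n_sims=50, seed=0)
        assert p.min() >= 1.0 / 100 and p.max() <= 1.0 - 1.0 / 100

    def test_free_running_mode_runs(self):
        cond = Condition("static", "partial", n_trials=20)
        sim = simulate_ibl(IBLParams(d=1.0, sigma=0.3), cond,
                           np.random.default_rng(6))
        p = predict_ibl(IBLParams(d=1.0, sigma=0.3), sim, n_sims=50, seed=8,
                        mode="free_running")
        assert p.shape == (20,)
        assert np.all((p >= 0.01) & (p <= 0.99))
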