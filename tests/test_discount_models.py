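"""Hyperbolic curve fits and softmax trial-level MLE."""

import math

import numpy as np
import pandas as pd
import pytest

from socdisc.discount_models import (fit_hyperbolic, fit_mle,
                                     hyperbolic_value,
                                     trial_negative_loglik)
from socdisc.modelfree import DiscountProfile
from socdisc.simulate import AgentParams, choice_probability
DISTANCES = np.array([1, 2, 3, 5, 10, 20, 50, 100], dtype=float)


def _profile(V, k, noise=None, rng=None):
    v = V / (1.0 + k * DISTANCES)
    if noise is not None:
        v = v + rng.normal(0, noise, v.shape)
    return DiscountProfile("p", DISTANCES, v + 130.0, [])


class TestHyperbolicValue:
    def test_zero_distance_returns_intercept(self):
        assert hyperbolic_value(170.0, 0.2, 0) == pytest.approx(170.0)

    def test_zero_rate_is_flat(self):
        out = hyperbolic_value(170.0, 0.0, DISTANCES)
        assert np.allclose(out, 170.0)

    def test_direct_substitution(self):
        assert hyperbolic_value(170.0, 0.05, 20) == pytest.approx(85.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            hyperbolic_value(-1.0, 0.1, 1)


class TestFitHyperbolic:
    def test_noiseless_recovery(self):
        fit = fit_hyperbolic(_profile(150.0, 0.08))
        assert fit.k == pytest.approx(0.08, rel=1e-3)
        assert fit.V == pytest.approx(150.0, rel=1e-3)
        assert fit.log_k == pytest.approx(math.log(fit.k))
        assert fit.converged

    def test_flat_profile_pins_k_and_flags(self):
        prof = DiscountProfile("p", DISTANCES, np.full(8, 80.0) + 130.0, [])
        fit = fit_hyperbolic(prof)
        assert fit.k == pytest.approx(1e-6)
        assert not fit.converged
        assert fit.notes == "k_at_lower_bound"

    def test_noisy_recovery_median_within_ten_percent(self):
        rng = np.random.default_rng(8)
        ks = []
        for _ in range(1000):
            fit = fit_hyperbolic(_profile(150.0, 0.10, noise=10.0, rng=rng))
            ks.append(fit.k)
        assert abs(np.median(ks) / 0.10 - 1.0) < 0.10

    def test_too_few_points_rejected(self):
        prof = DiscountProfile("p", DISTANCES[:2], np.array([260.0, 200.0]),
                               [])
        with pytest.raises(ValueError):
            fit_hyperbolic(prof)


class TestTrialNegativeLoglik:
    def test_equal_values_give_log_two(self):
        # indifferent trial: A = 130 + V/(1+kD)
        nll = trial_negative_loglik(0.1, 170.0, 0.05, [10.0], [215.0], [1])
        assert nll == pytest.approx(math.log(2.0), rel=1e-12)

    def test_additive_over_concatenation(self):
        rng = np.random.default_rng(0)
        D = rng.choice(DISTANCES, 20)
        A = rng.choice(np.arange(130.0, 291, 20), 20)
        y = rng.integers(0, 2, 20)
        total = trial_negative_loglik(0.2, 200.0, 0.04, D, A, y)
        parts = (trial_negative_loglik(0.2, 200.0, 0.04, D[:7], A[:7], y[:7])
                 + trial_negative_loglik(0.2, 200.0, 0.04, D[7:], A[7:],
                                         y[7:]))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_worked_single_trial(self):
        # p(selfish) = 1/(1+e^-3.75) = 0.977023
        nll = trial_negative_loglik(0.1, 170.0, 0.05, [10.0], [290.0], [1])
        assert nll == pytest.approx(-math.log(0.977023), abs=1e-6)

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            trial_negative_loglik(0.1, 170.0, 0.05, [], [], [])

    def test_extreme_values_do_not_overflow(self):
        nll = trial_negative_loglik(1e-6, 1000.0, 10.0, [1.0], [290.0], [0])
        assert np.isfinite(nll)


def _trials_df(agent, design, rng, rts=None):
    rows = []
    for d in design.distances:
        for a in design.selfish_amounts:
            p = choice_probability(agent, d, a, design.generous_amount)
            rows.append({"participant_id": "p1", "distance": d,
                         "selfish_amount": a,
                         "choice": "selfish" if rng.random() < p
                         else "generous",
                         "rt": 1.0})
    df = pd.DataFrame(rows)
    if rts is not None:
        df.loc[:len(rts) - 1, "rt"] = rts
    return df


class TestFitMLE:
    def test_rt_filter_counts(self, design):
        rng = np.random.default_rng(2)
        agent = AgentParams(k=0.2, V=250.0, sigma=0.05)
        df = _trials_df(agent, design, rng,
                        rts=[0.1, 0.2, 0.25, 0.29, 0.15])
        fit = fit_mle(df, design)
        assert fit.n_trials_used == 67

    def test_too_few_trials_rejected(self, design):
        rng = np.random.default_rng(2)
        agent = AgentParams(k=0.2, V=250.0, sigma=0.05)
        df = _trials_df(agent, design, rng).head(10)
        with pytest.raises(ValueError, match="scored trials"):
            fit_mle(df, design)

    def test_order_invariance(self, design):
        rng = np.random.default_rng(3)
        agent = AgentParams(k=0.2, V=250.0, sigma=0.05)
        df = _trials_df(agent, design, rng)
        fit_a = fit_mle(df, design)
        fit_b = fit_mle(df.sample(frac=1.0, random_state=1), design)
        # identical up to floating-point summation order in the NLL
        assert fit_a.k == pytest.approx(fit_b.k, rel=1e-4)
        assert fit_a.V == pytest.approx(fit_b.V, rel=1e-4)

    def test_coin_flip_data_flagged_weakly_identified(self, design):
        rng = np.random.default_rng(4)
        agent = AgentParams(k=0.2, V=250.0, sigma=0.0)
        df = _trials_df(agent, design, rng)
        fit = fit_mle(df, design)
        assert fit.sigma < 5e-3
        assert fit.notes == "weakly_identified"

    def test_cohort_recovery_of_log_k(self, mle_recovery):
        truth, fits = mle_recovery
        log_ks = [f.log_k for f in fits]
        assert abs(np.median(log_ks) - math.log(truth.k)) < 0.15

    def test_cohort_recovery_of_v_and_sigma(self, mle_recovery):
        truth, fits = mle_recovery
        assert abs(np.median([f.V for f in fits]) / truth.V - 1.0) < 0.15
        assert abs(np.median([f.sigma for f in fits]) / truth.sigma
                   - 1.0) < 0.15

    def test_nll_at_truth_beats_perturbed_in_expectation(self, design):
        # consistency: across simulated datasets, the generating parameters
        # have lower NLL than perturbed ones on average
        rng = np.random.default_rng(12)
        truth = AgentParams(k=0.2, V=250.0, sigma=0.05)
        wins = 0
        n_rep = 40
        for _ in range(n_rep):
            df = _trials_df(truth, design, rng)
            D = df["distance"].to_numpy(float)
            A = df["selfish_amount"].to_numpy(float)
            y = (df["choice"] == "selfish").to_numpy()
            at_truth = trial_negative_loglik(truth.k, truth.V, truth.sigma,
                                             D, A, y)
            perturbed = trial_negative_loglik(truth.k * 2.5, truth.V * 0.6,
                                              truth.sigma, D, A, y)
            wins += at_truth <= perturbed
        assert wins > 0.8 * n_rep
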