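"""Task grid, softmax choice rule and the diffusion trial generator."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from socdisc.simulate import (AgentParams, DDMParams, CohortTruth,
                              analytic_upper_probability, choice_probability,
                              default_truth, simulate_cohort,
                              simulate_ddm_trial, simulate_ddm_trials,
                              simulate_participant)
from socdisc.task import TaskDesign, build_trial_grid


class TestTrialGrid:
    def test_default_design_has_72_unique_pairs(self, design):
        grid = build_trial_grid(design)
        assert len(grid) == 72
        assert len(set(grid)) == 72

    def test_degenerate_single_cell_grid(self):
        d = TaskDesign(distances=[1], selfish_amounts=[130.0])
        assert build_trial_grid(d) == [(1, 130.0)]

    @given(nd=st.integers(1, 8), na=st.integers(1, 9))
    def test_grid_is_bijection_onto_product(self, nd, na):
        d = TaskDesign(distances=list(range(1, nd + 1)),
                       selfish_amounts=[130.0 + 20 * i for i in range(na)])
        grid = build_trial_grid(d)
        assert sorted(set(grid)) == sorted(
            (x, a) for x in d.distances for a in d.selfish_amounts)

    def test_randomized_order_is_blocked_by_distance(self, design):
        grid = build_trial_grid(design, np.random.default_rng(3))
        # all 9 amounts of a distance appear contiguously
        dists = [d for d, _ in grid]
        changes = sum(a != b for a, b in zip(dists, dists[1:]))
        assert changes == len(design.distances) - 1

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            TaskDesign(distances=[])
        with pytest.raises(ValueError):
            TaskDesign(distances=[3, 2, 1])
        with pytest.raises(ValueError):
            TaskDesign(selfish_amounts=[100.0, 120.0])  # below generous
        with pytest.raises(ValueError):
            TaskDesign(rt_floor=7.0)

    def test_payout_arithmetic(self, design):
        assert design.min_payout == pytest.approx(111.5)
        assert design.payout(290.0) == pytest.approx(119.5)


class TestChoiceProbability:
    def test_equal_subjective_values_give_half(self):
        agent = AgentParams(k=0.1, V=170.0, sigma=0.05)
        amount = 130.0 + 170.0 / (1 + 0.1 * 10)
        assert choice_probability(agent, 10, amount) == pytest.approx(0.5)

    def test_zero_temperature_is_coin_flip(self):
        agent = AgentParams(k=0.3, V=80.0, sigma=0.0)
        for amount in (130.0, 210.0, 290.0):
            assert choice_probability(agent, 5, amount) == 0.5

    def test_worked_value(self):
        # sigma*(A - (130 + V/(1+kD))) = 0.05*(290-215) = 3.75
        agent = AgentParams(k=0.1, V=170.0, sigma=0.05)
        p = choice_probability(agent, 10, 290.0)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-3.75)), rel=1e-12)
        assert p == pytest.approx(0.977023, abs=1e-6)

    @given(a1=st.floats(130, 289), a2=st.floats(130.5, 290))
    def test_strictly_increasing_in_amount(self, a1, a2):
        if a1 >= a2:
            a1, a2 = a2, a1 + 0.5
        agent = AgentParams(k=0.15, V=170.0, sigma=0.05)
        assert (choice_probability(agent, 10, a2)
                > choice_probability(agent, 10, a1))

    @given(v1=st.floats(0, 400), v2=st.floats(1, 401))
    def test_strictly_decreasing_in_generosity(self, v1, v2):
        if v1 >= v2:
            v1, v2 = v2 - 1, v1 + 1
        lo = choice_probability(AgentParams(0.15, v2, 0.05), 10, 250.0)
        hi = choice_probability(AgentParams(0.15, v1, 0.05), 10, 250.0)
        assert lo < hi


class TestSimulateParticipant:
    AGENT = AgentParams(k=0.15, V=170.0, sigma=0.05)

    def test_requires_seed(self, design):
        with pytest.raises(ValueError, match="seed"):
            simulate_participant(self.AGENT, None, design, None)

    def test_deterministic_under_seed(self, design):
        a = simulate_participant(self.AGENT, None, design, 123)
        b = simulate_participant(self.AGENT, None, design, 123)
        assert a == b

    def test_one_record_per_grid_pair(self, design):
        recs = simulate_participant(self.AGENT, None, design, 5)
        assert len(recs) == 72
        assert len({(r.distance, r.selfish_amount) for r in recs}) == 72

    def test_near_deterministic_agent_follows_value_threshold(self, design):
        agent = AgentParams(k=0.15, V=170.0, sigma=50.0)
        recs = simulate_participant(agent, None, design, 7)
        ok = n = 0
        for r in recs:
            threshold = 130.0 + 170.0 / (1 + 0.15 * r.distance)
            if abs(r.selfish_amount - threshold) < 1e-9:
                continue  # exact indifference stays a coin flip at any sigma
            n += 1
            expect = "selfish" if r.selfish_amount > threshold else "generous"
            ok += r.choice == expect
        assert ok >= 0.99 * n

    def test_choice_frequency_matches_probability(self, design):
        # one trial repeated: binomial check at 3 standard errors
        agent = AgentParams(k=0.1, V=170.0, sigma=0.02)
        p = choice_probability(agent, 20, 230.0)
        d1 = TaskDesign(distances=[20], selfish_amounts=[230.0])
        rng = np.random.default_rng(11)
        n = 10_000
        hits = sum(simulate_participant(agent, None, d1, rng)[0].choice
                   == "selfish" for _ in range(n))
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se


class TestDiffusionSimulator:
    def test_rt_exceeds_non_decision_time(self):
        ddm = DDMParams(alpha=1.2, beta=0.5, delta=0.5, tau=0.25)
        _, rt = simulate_ddm_trial(ddm, 3)
        assert rt > ddm.tau

    def test_requires_positive_step(self):
        ddm = DDMParams(alpha=1.2, beta=0.5, delta=0.5, tau=0.25)
        with pytest.raises(ValueError):
            simulate_ddm_trials(ddm, 10, np.random.default_rng(0), dt=0.0)

    def test_zero_drift_symmetric_start_is_fair(self):
        ddm = DDMParams(alpha=1.5, beta=0.5, delta=0.0, tau=0.2)
        up, _ = simulate_ddm_trials(ddm, 20_000, np.random.default_rng(1))
        assert abs(up.mean() - 0.5) < 3 * 0.5 / math.sqrt(20_000)

    @pytest.mark.parametrize("alpha,beta,delta", [
        (2.0, 0.3, 1.0), (1.0, 0.5, 0.5), (1.5, 0.7, -0.8)])
    def test_hitting_probability_matches_closed_form(self, alpha, beta, delta):
        ddm = DDMParams(alpha=alpha, beta=beta, delta=delta, tau=0.2)
        p = analytic_upper_probability(ddm)
        n = 20_000
        up, _ = simulate_ddm_trials(ddm, n, np.random.default_rng(9))
        assert abs(up.mean() - p) < 3 * math.sqrt(p * (1 - p) / n)


class TestSimulateCohort:
    def test_counts_and_cells(self, design):
        truth = default_truth(n_per_cell=10, seed=1,
                              fast_guess_rate=0.0, skip_rate=0.0,
                              with_ddm=False)
        ds = simulate_cohort(truth, design)
        assert len(ds.participants) == 40
        cells = ds.participant_cells().groupby(["sex", "condition"]).size()
        assert (cells == 10).all()
        assert len(ds.trials) == 40 * 72

    def test_requires_seed(self, design):
        truth = default_truth(n_per_cell=2, seed=None)
        with pytest.raises(ValueError, match="seed"):
            simulate_cohort(truth, design)

    def test_zero_dispersion_gives_exchangeable_participants(self, design):
        disp = {k: 0.0 for k in
                ("k", "V", "sigma", "alpha", "beta", "delta", "tau")}
        truth = default_truth(n_per_cell=3, seed=2, fast_guess_rate=0.0,
                              skip_rate=0.0, dispersion=disp)
        ds = simulate_cohort(truth, design)
        tp = ds.truth_params
        for col in ("k", "V", "sigma", "alpha", "beta", "delta", "tau"):
            assert tp[col].nunique() == 1

    def test_fast_guess_rate_within_binomial_bounds(self, design):
        rate = 0.05
        truth = default_truth(n_per_cell=10, seed=3, fast_guess_rate=rate,
                              skip_rate=0.0, with_ddm=False)
        ds = simulate_cohort(truth, design)
        scored = ds.trials[ds.trials["choice"] != "skipped"]
        n = len(ds.trials)
        fast = (scored["rt"] < design.rt_floor).sum()
        se = math.sqrt(rate * (1 - rate) / n)
        assert abs(fast / n - rate) < 3 * se

    def test_invalid_truth_rejected(self):
        with pytest.raises(ValueError):
            default_truth(n_per_cell=0, seed=1)
        truth = default_truth(n_per_cell=2, seed=1)
        with pytest.raises(ValueError):
            CohortTruth(n_per_cell=2, cell_agent=truth.cell_agent,
                        cell_ddm=None, fast_guess_rate=1.5, seed=1)
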