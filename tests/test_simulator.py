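"""Trial simulation in foveal and peripheral environments."""

import numpy as np
import pytest

import cdac
from cdac.simulator import CENTER_FIXATION, PeripheralModel, TrialRecord


@pytest.fixture(scope="module")
def peripheral():
    return PeripheralModel((0.62, 0.6, 0.55, 0.5))


class TestScoreTrial:
    @pytest.mark.parametrize(
        "seconds,switches,correct,expected",
        [
            (2.0, 1, True, 100.0),
            (0.0, 0, True, 150.0),
            (8.0, 0, False, -50.0),
            (4.0, 2, True, 50.0),
        ],
    )
    def test_point_formula(self, seconds, switches, correct, expected):
        assert cdac.score_trial(seconds, switches, correct) == expected

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            cdac.score_trial(-1.0, 0, True)


class TestPeripheralModel:
    def test_tier_assignment(self, peripheral):
        b1, b2, b3, b4 = peripheral.betas
        r = peripheral.component_reliability
        assert r[0, 0] == b1 and r[0, 1] == b4 and r[0, 2] == b4  # direct
        assert r[3, 0] == b2 and r[3, 1] == b2 and r[3, 2] == b4  # midpoint l12
        assert r[5, 0] == b2 and r[5, 2] == b2 and r[5, 1] == b4  # midpoint l13
        assert np.all(r[CENTER_FIXATION] == b3)  # center sees all three

    def test_tier_ordering_enforced(self):
        with pytest.raises(ValueError):
            PeripheralModel((0.6, 0.62, 0.55, 0.5))
        with pytest.raises(ValueError):
            PeripheralModel((0.62, 0.6, 0.55, 0.45))

    def test_likelihoods_normalize(self, peripheral):
        L = peripheral.likelihood_table()
        assert L.shape == (3, 7, 8)
        assert np.allclose(L.sum(axis=2), 1.0)

    def test_center_components_all_beta3(self, peripheral):
        """At the center, every component is a tier-3 Bernoulli (favoring 1
        at the target, 0 at distractors)."""
        b3 = peripheral.betas[2]
        q = peripheral.component_success(1, CENTER_FIXATION)
        assert np.allclose(q, [1 - b3, b3, 1 - b3])


class TestSampleObservation:
    def test_deterministic_at_beta_one(self):
        model = cdac.ObservationModel(3, 1.0)
        rng = np.random.default_rng(0)
        assert all(cdac.sample_observation(1, 1, model, rng) == 1 for _ in range(20))
        assert all(cdac.sample_observation(1, 0, model, rng) == 0 for _ in range(20))

    def test_empirical_rate_matches_beta(self, model9):
        rng = np.random.default_rng(42)
        n = 100_000
        draws = [cdac.sample_observation(0, 0, model9, rng) for _ in range(n)]
        se = np.sqrt(0.9 * 0.1 / n)
        assert abs(np.mean(draws) - 0.9) < 3 * se

    def test_peripheral_outcome_distribution(self, peripheral):
        """Observed outcome frequencies at the center match the product-
        Bernoulli likelihood row."""
        rng = np.random.default_rng(7)
        n = 20_000
        draws = np.array(
            [cdac.sample_observation(2, CENTER_FIXATION, peripheral, rng) for _ in range(n)]
        )
        freq = np.bincount(draws, minlength=8) / n
        expect = peripheral.likelihood_table()[2, CENTER_FIXATION]
        se = np.sqrt(expect * (1 - expect) / n)
        assert np.all(np.abs(freq - expect) < 4 * np.maximum(se, 1e-4))

    def test_invalid_indices_rejected(self, model9):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            cdac.sample_observation(5, 0, model9, rng)


class TestTrialRecord:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            TrialRecord(
                true_target=0, prior=np.ones(3) / 3, fixations=[0, 1],
                observations=[1], declared=0, correct=True, steps=1,
                switches=1, behavioral_cost=0.0, initial_fixation=0,
            )
        with pytest.raises(ValueError):
            TrialRecord(
                true_target=0, prior=np.ones(3) / 3, fixations=[0, 1],
                observations=[1, 0], declared=0, correct=True, steps=2,
                switches=0, behavioral_cost=0.0, initial_fixation=0,
            )


@pytest.fixture(scope="module")
def noiseless_policy():
    grid = cdac.build_belief_grid(3, 40)
    model = cdac.ObservationModel(3, 1.0)
    _, pol = cdac.solve_cdac(
        model, cdac.CostParams(0.01, 0.01), grid, declare_rule="current"
    )
    return pol, model


class TestSimulateTrial:

    def test_noiseless_single_step(self, noiseless_policy):
        pol, model = noiseless_policy
        t = cdac.simulate_trial(
            pol, model, cdac.CostParams(0.01, 0.01), np.ones(3) / 3,
            true_target=1, initial_fixation=1, rng=np.random.default_rng(0),
        )
        assert t.steps == 1 and t.correct and t.switches == 0
        assert t.declared == 1
        assert t.behavioral_cost == pytest.approx(0.01)

    def test_noiseless_always_correct(self, noiseless_policy):
        pol, model = noiseless_policy
        costs = cdac.CostParams(0.01, 0.01)
        trials = cdac.run_experiment(
            pol, model, costs, np.ones(3) / 3, 100, np.ones(3) / 3,
            seed=3, initial_fixation="uniform",
        )
        assert all(t.correct for t in trials)

    def test_deterministic_replay(self, grid3, model9, solved_cs1):
        _, pol = solved_cs1
        costs = cdac.CostParams(0.1, 0.1)
        records = [
            cdac.simulate_trial(
                pol, model9, costs, np.ones(3) / 3, 2, 0,
                np.random.default_rng(99),
            )
            for _ in range(2)
        ]
        assert records[0].fixations == records[1].fixations
        assert records[0].observations == records[1].observations
        assert records[0].behavioral_cost == records[1].behavioral_cost

    def test_cost_decomposition_holds(self, model9, solved_cs1):
        _, pol = solved_cs1
        costs = cdac.CostParams(0.1, 0.1)
        rng = np.random.default_rng(5)
        for seed in range(10):
            t = cdac.simulate_trial(
                pol, model9, costs, np.ones(3) / 3, int(rng.integers(3)), 0,
                np.random.default_rng(seed),
            )
            expect = costs.c * t.steps + costs.cs * t.switches + (not t.correct)
            assert t.behavioral_cost == pytest.approx(expect)

    def test_declare_current_declares_final_fixation(self, model68, grid3_fine):
        _, pol = cdac.solve_cdac(
            model68, cdac.CostParams(0.005, 0.1), grid3_fine, declare_rule="current"
        )
        costs = cdac.CostParams(0.005, 0.1)
        for seed in range(10):
            t = cdac.simulate_trial(
                pol, model68, costs, np.array([1, 3, 9]) / 13.0, 2, 2,
                np.random.default_rng(seed),
            )
            assert not t.truncated
            assert t.declared == t.fixations[-1]

    def test_step_cap_truncates_as_error(self, model9, solved_cs1):
        _, pol = solved_cs1
        always_continue = lambda p, cur, rng: cdac.Action("fixate", 0)
        t = cdac.simulate_trial(
            always_continue, model9, cdac.CostParams(0.1), np.ones(3) / 3,
            0, 0, np.random.default_rng(0), max_steps=25,
        )
        assert t.truncated and not t.correct and t.steps == 25
        assert t.declared == -1

    def test_beats_random_baseline(self, model68, grid3_fine):
        costs = cdac.CostParams(0.005, 0.1)
        prior = np.array([9, 3, 1]) / 13.0
        _, pol = cdac.solve_cdac(
            model68, costs, grid3_fine, declare_rule="current"
        )
        rand = cdac.RandomPolicy(
            n_fixations=3, k=3, threshold=cdac.theorem1_threshold(0.68, 0.005)
        )
        n = 1500
        t_c = cdac.run_experiment(pol, model68, costs, prior, n, prior, seed=21)
        t_r = cdac.run_experiment(rand, model68, costs, prior, n, prior, seed=21)
        cost_c = np.mean([t.behavioral_cost for t in t_c])
        cost_r = np.mean([t.behavioral_cost for t in t_r])
        assert cost_c <= cost_r


class TestRunExperiment:
    def test_zero_trials(self, model9, solved_cs1):
        out = cdac.run_experiment(
            solved_cs1[1], model9, cdac.CostParams(0.1, 0.1),
            np.ones(3) / 3, 0, np.ones(3) / 3, seed=0,
        )
        assert out == []

    def test_target_frequencies_match_distribution(self, model9, solved_cs1):
        dist = np.array([1, 3, 9]) / 13.0
        trials = cdac.run_experiment(
            solved_cs1[1], model9, cdac.CostParams(0.1, 0.1), dist, 5000, dist,
            seed=17,
        )
        freq = np.bincount([t.true_target for t in trials], minlength=3) / 5000
        se = np.sqrt(dist * (1 - dist) / 5000)
        assert np.all(np.abs(freq - dist) < 3.5 * se)

    def test_different_master_seeds_differ(self, model9, solved_cs1):
        kw = dict(
            policy=solved_cs1[1], model=model9, costs=cdac.CostParams(0.1, 0.1),
            prior=np.ones(3) / 3, n_trials=50, target_distribution=np.ones(3) / 3,
        )
        a = cdac.run_experiment(seed=1, **kw)
        b = cdac.run_experiment(seed=2, **kw)
        assert [t.observations for t in a] != [t.observations for t in b]

    def test_same_seed_reproduces(self, model9, solved_cs1):
        kw = dict(
            policy=solved_cs1[1], model=model9, costs=cdac.CostParams(0.1, 0.1),
            prior=np.ones(3) / 3, n_trials=50, target_distribution=np.ones(3) / 3,
        )
        a = cdac.run_experiment(seed=4, **kw)
        b = cdac.run_experiment(seed=4, **kw)
        assert [t.observations for t in a] == [t.observations for t in b]

    def test_peripheral_rollout_from_center(self, peripheral, grid3):
        costs = cdac.CostParams(0.05, 0.005)
        _, pol = cdac.solve_cdac(peripheral, costs, grid3)
        trials = cdac.run_experiment(
            pol, peripheral, costs, np.ones(3) / 3, 200, np.ones(3) / 3,
            seed=9, initial_fixation=CENTER_FIXATION,
        )
        assert all(t.fixations[0] == CENTER_FIXATION for t in trials)
        assert all(0 <= t.declared < 3 for t in trials)
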