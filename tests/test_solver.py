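"""Exact C-DAC solver: cost model, value iteration, policy, stopping bound."""

import numpy as np
import pytest

import cdac
from cdac.inference import GridDynamics, build_belief_grid
from cdac.solver import Action, ThresholdSaturationError, _stop_values


class TestStopCost:
    def test_certain_belief(self):
        assert cdac.stop_cost([1.0, 0.0, 0.0], 0) == 0.0

    def test_uniform(self):
        for i in range(3):
            assert cdac.stop_cost(np.ones(3) / 3, i) == pytest.approx(2 / 3)

    def test_biased_prior(self):
        assert cdac.stop_cost(np.array([9, 3, 1]) / 13.0, 0) == pytest.approx(4 / 13)

    def test_invalid_index(self):
        with pytest.raises(ValueError):
            cdac.stop_cost(np.ones(3) / 3, 5)


class TestContinuationValue:
    def test_absorbing_corner_costs_one_step(self, grid3, model9):
        costs = cdac.CostParams(0.1, 0.1)
        V = cdac.ValueFunction(grid3, _stop_values(grid3, model9, "any"))
        val = cdac.continuation_value([1.0, 0.0, 0.0], 0, 0, V, costs, model9, grid3)
        assert val == pytest.approx(costs.c)

    def test_uninformative_beta_adds_costs_only(self, grid3):
        model = cdac.ObservationModel(3, 0.5)
        costs = cdac.CostParams(0.07, 0.03)
        V = cdac.ValueFunction(grid3, _stop_values(grid3, model, "any"))
        p = np.array([0.4, 0.35, 0.25])
        stay = cdac.continuation_value(p, 0, 0, V, costs, model, grid3)
        switch = cdac.continuation_value(p, 0, 1, V, costs, model, grid3)
        base = 1.0 - p.max()
        assert stay == pytest.approx(costs.c + base, abs=1e-9)
        assert switch == pytest.approx(costs.c + costs.cs + base, abs=1e-9)

    def test_two_location_hand_value(self):
        # from (0.5, 0.5) one observation at beta=0.9 yields (0.9,0.1) or
        # (0.1,0.9) each with probability 1/2; with V = stopping cost the
        # continuation is c + E[1 - max posterior] = c + 0.1
        grid = build_belief_grid(2, 100)
        model = cdac.ObservationModel(2, 0.9)
        costs = cdac.CostParams(0.1, 0.0)
        V = cdac.ValueFunction(grid, _stop_values(grid, model, "any"))
        val = cdac.continuation_value([0.5, 0.5], 0, 0, V, costs, model, grid)
        assert val == pytest.approx(0.1 + 0.1, abs=1e-9)


class TestSolveCdac:
    def test_corner_beliefs_declare_with_zero_value(self, solved_cs1, grid3):
        V, pol = solved_cs1
        for loc in range(3):
            corner = np.zeros(3)
            corner[loc] = 1.0
            gi = grid3.nearest_index(corner)
            assert np.allclose(V.values[gi], 0.0)
            for fix in range(3):
                a = Action.decode(pol.actions[gi, fix], 3)
                assert a.is_declare and a.index == loc

    def test_no_switch_cost_value_fixation_independent(self, solved_cs0):
        V, _ = solved_cs0
        assert np.abs(V.values - V.values[:, [0]]).max() < 1e-9

    def test_value_never_worse_than_stopping(self, solved_cs1, grid3):
        V, _ = solved_cs1
        stop = 1.0 - grid3.points.max(axis=1)
        assert np.all(V.values <= stop[:, None] + 1e-12)
        assert np.all(V.values >= -1e-12)

    def test_sweeps_monotone_from_stop_init(self, grid3, model9, dyn3):
        """Each Bellman sweep from the stopping-cost start is pointwise non-increasing."""
        costs = cdac.CostParams(0.1, 0.1)
        stop = _stop_values(grid3, model9, "any")
        V = stop.copy()
        for _ in range(5):
            EV = np.stack(
                [dyn3.expected_value(V[:, j], j) for j in range(3)], axis=1
            )
            Vnew = np.empty_like(V)
            for i in range(3):
                sw = costs.c + np.where(np.arange(3) == i, 0.0, costs.cs)
                Vnew[:, i] = np.minimum(stop[:, i], (EV + sw[None, :]).min(axis=1))
            assert np.all(Vnew <= V + 1e-14)
            V = Vnew

    def test_permutation_equivariance(self, grid3, model9, solved_cs1):
        """Relabeling locations permutes values and policies consistently.

        For the coordinate relabeling (sigma p)[j] = p[pi[j]], the symmetric
        environment gives V(sigma p, j) = V(p, pi[j]) and the corresponding
        action with its location indices mapped through pi.
        """
        V, pol = solved_cs1
        pi = np.array([2, 0, 1])
        inv = np.argsort(pi)  # the relabeling rho: old location -> new label
        pidx = grid3.indices_of(grid3.counts[:, pi])  # index of rho(p)
        assert np.abs(V.values[pidx] - V.values[:, pi]).max() < 1e-12
        # policy equivariance holds up to exact argmin ties (symmetric points,
        # and boundary points where the remaining two locations are equally
        # informative): wherever the relabeled action differs, the two
        # actions' Q-factors must coincide to numerical precision
        acts_sigma = pol.actions[pidx][:, inv]  # action at (rho p, rho i)
        # map the sigma-world action back to original labels (via rho^-1 = pi)
        back = np.where(
            acts_sigma < 3, pi[np.minimum(acts_sigma, 2)], 3 + pi[acts_sigma % 3]
        )
        costs = cdac.CostParams(0.1, 0.1)
        dyn = cdac.GridDynamics(grid3, model9)
        EV = np.stack([dyn.expected_value(V.values[:, j], j) for j in range(3)], axis=1)

        def q_of(g, i, code):
            if code < 3:
                return 1.0 - grid3.points[g, code]
            j = code - 3
            return costs.c + (costs.cs if j != i else 0.0) + EV[g, j]

        n_true_mismatch = 0
        for g, i in zip(*np.nonzero(back != pol.actions)):
            qa = q_of(g, i, int(back[g, i]))
            qb = q_of(g, i, int(pol.actions[g, i]))
            if abs(qa - qb) > 1e-10:
                n_true_mismatch += 1
        assert n_true_mismatch == 0

    def test_declare_current_restricts_declarations(self, grid3, model9):
        _, pol = cdac.solve_cdac(
            model9, cdac.CostParams(0.1, 0.1), grid3, declare_rule="current"
        )
        for fix in range(3):
            codes = pol.actions[:, fix]
            declared = codes[codes < 3]
            assert np.all(declared == fix)

    def test_non_convergence_raises(self, grid3, model9):
        with pytest.raises(cdac.solver.ConvergenceError):
            cdac.solve_cdac(model9, cdac.CostParams(0.001), grid3, tol=1e-12, max_iter=2)


class TestTheorem1Threshold:
    @pytest.mark.parametrize(
        "beta,c,expected",
        [(0.9, 0.1, 0.8859), (0.68, 0.005, 0.9905)],
    )
    def test_quadratic_roots(self, beta, c, expected):
        p = cdac.theorem1_threshold(beta, c)
        assert p == pytest.approx(expected, abs=5e-5)
        # verify by substitution into the defining equation
        lhs = p * (2 * beta - 1) * (1 - p)
        rhs = c * (beta * p + (1 - beta) * (1 - p))
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_zero_cost_limit(self):
        assert cdac.theorem1_threshold(0.9, 1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_saturation(self):
        with pytest.raises(ThresholdSaturationError):
            cdac.theorem1_threshold(0.55, 0.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cdac.theorem1_threshold(0.4, 0.1)
        with pytest.raises(ValueError):
            cdac.theorem1_threshold(0.9, -0.1)


class TestStoppingRegion:
    def test_corners_always_included(self, solved_cs1, grid3):
        _, pol = solved_cs1
        corners = grid3.points.max(axis=1) == 1.0
        for fix in range(3):
            assert cdac.stopping_region(pol, fix)[corners].all()

    def test_region_grows_with_switch_cost(self, solved_cs0, solved_cs1):
        for fix in range(3):
            r0 = cdac.stopping_region(solved_cs0[1], fix)
            r1 = cdac.stopping_region(solved_cs1[1], fix)
            assert not (r0 & ~r1).any()
            assert r1.sum() > r0.sum()

    def test_theorem1_inner_bound(self, solved_cs0, grid3):
        _, pol = solved_cs0
        p_star = cdac.theorem1_threshold(0.9, 0.1)
        above = (grid3.points > p_star).any(axis=1)
        for fix in range(3):
            assert not (above & ~cdac.stopping_region(pol, fix)).any()

    def test_stay_never_becomes_switch(self, solved_cs0, solved_cs1):
        """Adding switch cost converts 'stay' only into 'stay' or 'declare'."""
        for fix in range(3):
            stay0 = solved_cs0[1].actions[:, fix] == 3 + fix
            stay1 = solved_cs1[1].actions[:, fix] == 3 + fix
            stop1 = cdac.stopping_region(solved_cs1[1], fix)
            assert not (stay0 & ~(stay1 | stop1)).any()
            assert stay1.sum() + stop1.sum() > stay0.sum()


class TestPolicyExport:
    def test_csv_round_trip_bit_exact(self, solved_cs1, tmp_path):
        from cdac.io import load_policy, save_policy

        V, pol = solved_cs1
        path = tmp_path / "policy.csv"
        save_policy(path, pol, V)
        pol2, V2 = load_policy(path)
        assert np.array_equal(pol.actions, pol2.actions)
        assert np.array_equal(V.values, V2.values)  # bit-exact
        assert pol2.meta["family"] == "cdac"
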