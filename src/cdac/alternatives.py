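"""Comparator policies: Infomax, the myopic one-step rule, and a random baseline.

Infomax chooses fixations to minimize expected cumulative future posterior
entropy.  It has no intrinsic stopping action; here it stops once the maximum
posterior exceeds a confidence threshold, by default the cost-sensitive bound
from :func:`cdac.solver.theorem1_threshold` (a provable inner bound of the
optimal stopping region when the switch cost is zero).

The myopic rule evaluates the C-DAC objective exactly one step ahead,
treating the next action as the last non-terminal one.  Because the belief is
a martingale, the expected maximum-posterior term collapses to the current
maximum posterior, which makes the myopic rule systematically eager to stop —
it overestimates the stopping region relative to the exact solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .inference import BeliefGrid, GridDynamics, as_belief, predictive
from .solver import Action, ConvergenceError, CostParams, DeclareRule, Policy

__all__ = [
    "solve_infomax",
    "myopic_action",
    "myopic_policy",
    "RandomPolicy",
    "CalibrationError",
    "calibrate_threshold",
]


def solve_infomax(model, grid: BeliefGrid, stop_threshold: float,
                  horizon: int | str = "converged", tol: float = 1e-6,
                  max_iter: int = 2000,
                  dynamics: GridDynamics | None = None) -> tuple[np.ndarray, Policy]:
    """Backward induction for the cumulative-posterior-entropy objective.

    Beliefs with ``max_i p_i >= stop_threshold`` are absorbing with zero
    future entropy cost; elsewhere

        V_I(p) = min_j  E_x[ H(p'_{x,j}) + V_I(p'_{x,j}) ].

    ``horizon="converged"`` iterates to a sup-norm fixed point; an integer
    horizon performs exactly that many backward steps (for sensitivity
    checks).  The value and policy are independent of the current fixation —
    the returned :class:`Policy` table repeats one column per fixation.
    Declarations go to the argmax-posterior location.
    """
    if not (0.5 < stop_threshold <= 1.0):
        raise ValueError("stop_threshold must lie in (0.5, 1]")
    dyn = dynamics if dynamics is not None else GridDynamics(grid, model)
    F, X = dyn.n_fixations, dyn.n_outcomes
    stopped = grid.points.max(axis=1) >= stop_threshold
    V = np.zeros(grid.size)
    n_steps = max_iter if horizon == "converged" else int(horizon)
    residual = math.inf
    for _ in range(n_steps):
        Q = np.empty((grid.size, F))
        for j in range(F):
            ev = np.zeros(grid.size)
            for x in range(X):
                ev += dyn.pred[:, j, x] * (
                    dyn.post_entropy[:, j, x] + dyn.ops[(j, x)] @ V
                )
            Q[:, j] = ev
        Vnew = Q.min(axis=1)
        Vnew[stopped] = 0.0
        residual = float(np.max(np.abs(Vnew - V)))
        V = Vnew
        if horizon == "converged" and residual < tol:
            break
    else:
        if horizon == "converged":
            raise ConvergenceError(
                f"Infomax backward induction did not converge in {max_iter} steps",
                residual,
            )

    # greedy fixation (lowest index on ties); declare argmax posterior when stopped
    Qfinal = np.empty((grid.size, F))
    for j in range(F):
        ev = np.zeros(grid.size)
        for x in range(X):
            ev += dyn.pred[:, j, x] * (dyn.post_entropy[:, j, x] + dyn.ops[(j, x)] @ V)
        Qfinal[:, j] = ev
    # lowest fixation index wins ties (within float tolerance, so exactly
    # symmetric beliefs resolve deterministically)
    fix_choice = np.argmax(Qfinal <= Qfinal.min(axis=1)[:, None] + 1e-12, axis=1)
    col = np.where(stopped, grid.points.argmax(axis=1), grid.k + fix_choice)
    actions = np.repeat(col[:, None], F, axis=1)
    meta = {
        "family": "infomax",
        "stop_threshold": stop_threshold,
        "horizon": horizon,
        "grid_n": grid.n,
        "k": grid.k,
        "tol": tol,
        "residual": residual,
        "model": model.kind,
    }
    return V, Policy(grid, actions, meta)


def myopic_action(p, current: int, model, costs: CostParams,
                  declare_rule: DeclareRule = "any") -> Action:
    """One-step-lookahead C-DAC action at belief ``p`` while fixating ``current``.

    Evaluates ``min( stop, min_j ( c + cs 1{j != current} + min_l (1 - E[p'_l]) ) )``
    with the expectation over the predictive distribution of one observation
    at ``j`` (computed by explicit outcome summation).  Under
    ``declare_rule="current"`` the post-observation declaration ``l`` is
    restricted to the new fixation ``j`` and stopping now declares ``current``.
    Tie-break: stop beats continue; among continuations the current fixation
    wins, then the lowest index.
    """
    p = as_belief(p)
    L = model.likelihood_table()
    k, F, X = L.shape
    if declare_rule == "any":
        stop_val = 1.0 - p.max()
        stop_act = Action("declare", int(p.argmax()))
    else:
        loc = model.fixation_location(current)
        stop_val = 1.0 - p[loc]
        stop_act = Action("declare", loc)

    best_val, best_act = stop_val, stop_act
    order = [current] + [j for j in range(F) if j != current]
    for j in order:
        pred = p @ L[:, j, :]  # (X,)
        exp_post = np.zeros(k)
        for x in range(X):
            if pred[x] > 0:
                post = (L[:, j, x] * p) / pred[x]
                exp_post += pred[x] * post
        if declare_rule == "any":
            future_stop = float(1.0 - exp_post.max())
        else:
            future_stop = float(1.0 - exp_post[model.fixation_location(j)])
        val = costs.c + (costs.cs if j != current else 0.0) + future_stop
        if val < best_val - 1e-15:
            best_val, best_act = val, Action("fixate", j)
    return best_act


def myopic_policy(model, grid: BeliefGrid, costs: CostParams,
                  declare_rule: DeclareRule = "any") -> Policy:
    """Myopic action table on the full grid (vectorized one-step lookahead)."""
    L = model.likelihood_table()
    k, F, X = L.shape
    P = grid.points
    pred = np.einsum("gi,ifx->gfx", P, L)
    actions = np.empty((grid.size, F), dtype=np.int64)
    # expected posterior after one observation at j equals the prior
    # (martingale), but compute it by explicit summation as specified
    exp_post = np.zeros((grid.size, F, k))
    for j in range(F):
        for x in range(X):
            post = P * L[:, j, x][None, :]
            norm = pred[:, j, x]
            safe = norm > 0
            post[safe] /= norm[safe, None]
            post[~safe] = P[~safe]
            exp_post[:, j, :] += norm[:, None] * post
    for i in range(F):
        if declare_rule == "any":
            stop_val = 1.0 - P.max(axis=1)
            stop_code = P.argmax(axis=1)
        else:
            loc = model.fixation_location(i)
            stop_val = 1.0 - P[:, loc]
            stop_code = np.full(grid.size, loc)
        best_val, best_code = stop_val.copy(), stop_code.copy()
        order = [i] + [j for j in range(F) if j != i]
        for j in order:
            if declare_rule == "any":
                future_stop = 1.0 - exp_post[:, j, :].max(axis=1)
            else:
                future_stop = 1.0 - exp_post[:, j, model.fixation_location(j)]
            val = costs.c + (costs.cs if j != i else 0.0) + future_stop
            better = val < best_val - 1e-15
            best_val = np.where(better, val, best_val)
            best_code = np.where(better, k + j, best_code)
        actions[:, i] = best_code
    meta = {
        "family": "myopic",
        "declare_rule": declare_rule,
        "c": costs.c,
        "cs": costs.cs,
        "grid_n": grid.n,
        "k": grid.k,
        "model": model.kind,
    }
    return Policy(grid, actions, meta)


@dataclass
class RandomPolicy:
    """Uniform-random fixation baseline: fixate uniformly until the maximum
    posterior exceeds ``threshold``, then declare the argmax location.

    Stands in for greedy maximum-a-posteriori search, which behaves close to
    randomly on this small task.
    """

    n_fixations: int
    k: int
    threshold: float = 0.9

    def action(self, p, current: int, rng: np.random.Generator) -> Action:
        p = as_belief(p, self.k)
        if p.max() >= self.threshold:
            return Action("declare", int(p.argmax()))
        return Action("fixate", int(rng.integers(self.n_fixations)))

    # simulator protocol
    def __call__(self, p, current: int, rng: np.random.Generator) -> Action:
        return self.action(p, current, rng)


class CalibrationError(RuntimeError):
    """Threshold calibration could not bracket the target accuracy."""


def calibrate_threshold(policy_builder, simulate_accuracy, target_accuracy: float,
                        tol: float = 0.01, bracket: tuple[float, float] = (0.55, 0.999),
                        max_iter: int = 30) -> tuple[float, float]:
    """Bisection on a stopping threshold until simulated accuracy matches a target.

    ``policy_builder(threshold)`` must return a policy and
    ``simulate_accuracy(policy)`` its accuracy estimate; the caller should use
    common random numbers (a fixed seed inside ``simulate_accuracy``) so that
    accuracy is monotone in the threshold up to simulation noise.  Returns
    ``(threshold, achieved_accuracy)``.
    """
    lo, hi = bracket
    acc_lo = simulate_accuracy(policy_builder(lo))
    acc_hi = simulate_accuracy(policy_builder(hi))
    if not (acc_lo - tol <= target_accuracy <= acc_hi + tol):
        raise CalibrationError(
            f"target accuracy {target_accuracy:.3f} outside bracket accuracies "
            f"[{acc_lo:.3f}, {acc_hi:.3f}]"
        )
    mid, acc = (lo + hi) / 2.0, (acc_lo + acc_hi) / 2.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        acc = simulate_accuracy(policy_builder(mid))
        if abs(acc - target_accuracy) <= tol:
            return mid, acc
        if acc < target_accuracy:
            lo = mid
        else:
            hi = mid
    return mid, acc
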