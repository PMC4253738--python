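"""Exact C-DAC solver: behavioral cost model, Bellman backups, and the stopping bound.

C-DAC (Context-Dependent Active Controller) chooses fixations and a stopping
time to minimize the expected behavioral cost

    L = c E[steps] + c_s E[switches] + P(wrong declaration),

with the error cost normalized to 1.  The problem is a belief MDP: states are
posterior beliefs over target location plus the current fixation, actions are
Declare(i) or Fixate(j).  The optimal policy is stationary and is computed by
value iteration on the discretized belief simplex, initialized at the stopping
cost, with expectations over the binary observation taken exactly and
off-lattice posteriors evaluated by barycentric interpolation.

Two declaration conventions are supported:

- ``declare_rule="any"``: the observer may declare any location (the literal
  Bellman stop term ``min_i (1 - p_i)``);
- ``declare_rule="current"``: only the currently fixated location may be
  declared (the gaze-contingent human task, where the response selects the
  last viewed patch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .inference import BeliefGrid, GridDynamics, as_belief, bayes_update, interpolate, predictive

__all__ = [
    "CostParams",
    "Action",
    "ValueFunction",
    "Policy",
    "ConvergenceError",
    "ThresholdSaturationError",
    "stop_cost",
    "continuation_value",
    "solve_cdac",
    "theorem1_threshold",
    "stopping_region",
]

DeclareRule = Literal["any", "current"]


class ConvergenceError(RuntimeError):
    """Value iteration failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last residual {residual:.3e})")
        self.residual = residual


class ThresholdSaturationError(ValueError):
    """The stopping-threshold equation has no root in (0, 1)."""


@dataclass(frozen=True)
class CostParams:
    """Behavioral cost coefficients: c per observation step, cs per fixation switch.

    The cost of a wrong declaration is fixed at 1 (units are normalized so
    that one error equals one cost unit).
    """

    c: float
    cs: float = 0.0

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("time cost c must be positive")
        if self.cs < 0:
            raise ValueError("switch cost cs must be non-negative")


@dataclass(frozen=True)
class Action:
    """Declare(i) or Fixate(j).  Encoded as ints: 0..k-1 declare, k..k+F-1 fixate."""

    kind: Literal["declare", "fixate"]
    index: int

    def encode(self, k: int) -> int:
        return self.index if self.kind == "declare" else k + self.index

    @staticmethod
    def decode(code: int, k: int) -> "Action":
        if code < 0:
            raise ValueError(f"invalid action code {code}")
        if code < k:
            return Action("declare", code)
        return Action("fixate", code - k)

    @property
    def is_declare(self) -> bool:
        return self.kind == "declare"


@dataclass
class ValueFunction:
    """Expected-cost table over (grid point, current fixation)."""

    grid: BeliefGrid
    values: np.ndarray  # (G, F)

    def __call__(self, p, fixation: int) -> float:
        return interpolate(self.values[:, fixation], p, self.grid)


@dataclass
class Policy:
    """Deterministic action table over (grid point, current fixation)."""

    grid: BeliefGrid
    actions: np.ndarray  # (G, F) int codes
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.grid.k

    def action_at(self, p, fixation: int) -> Action:
        """Action at the grid point nearest to belief ``p`` (actions are categorical)."""
        g = self.grid.nearest_index(p)
        return Action.decode(int(self.actions[g, fixation]), self.k)


def stop_cost(p, i: int) -> float:
    """Expected cost of stopping now and declaring location ``i``: 1 - p_i.

    Sunk time and switch costs are omitted (the policy is stationary, so only
    the incremental cost matters for the decision).
    """
    p = as_belief(p)
    if not (0 <= i < p.size):
        raise ValueError(f"invalid location index {i}")
    return float(1.0 - p[i])


def continuation_value(p, current: int, j: int, V: ValueFunction, costs: CostParams,
                       model, grid: BeliefGrid) -> float:
    """Expected cost of observing once at fixation ``j`` and then acting optimally.

    Implements ``c + cs 1{j != current} + E_x[ V(p', j) ]`` with the
    expectation over the predictive distribution of the next observation and
    ``V`` interpolated at the exact Bayes posteriors.
    """
    p = as_belief(p, grid.k)
    val = costs.c + (costs.cs if j != current else 0.0)
    pred = predictive(p, j, model)
    for x in np.nonzero(pred > 0)[0]:
        post = bayes_update(p, int(x), j, model)
        val += pred[x] * interpolate(V.values[:, j], post, grid)
    return float(val)


def _stop_values(grid: BeliefGrid, model, declare_rule: DeclareRule) -> np.ndarray:
    """Stopping cost at each (grid point, fixation): (G, F)."""
    F = model.likelihood_table().shape[1]
    if declare_rule == "any":
        s = 1.0 - grid.points.max(axis=1)
        return np.repeat(s[:, None], F, axis=1)
    if declare_rule == "current":
        if not model.fixations_are_locations:
            raise ValueError("declare_rule='current' requires fixations at candidate locations")
        cols = [1.0 - grid.points[:, model.fixation_location(j)] for j in range(F)]
        return np.stack(cols, axis=1)
    raise ValueError(f"unknown declare_rule {declare_rule!r}")


def solve_cdac(model, costs: CostParams, grid: BeliefGrid, tol: float = 1e-6,
               declare_rule: DeclareRule = "any", max_iter: int = 500,
               dynamics: GridDynamics | None = None) -> tuple[ValueFunction, Policy]:
    """Value iteration for the C-DAC belief MDP on the grid.

    The value function is initialized at the stopping cost and Bellman sweeps
    are applied until the sup-norm change drops below ``tol``; from that
    initialization each sweep is pointwise non-increasing.  Returns the
    converged :class:`ValueFunction` and the greedy :class:`Policy`.

    Tie-breaking in the policy argmin is deterministic: Declare beats Fixate;
    among Declares the lowest location index wins; among Fixates the current
    location wins, then the lowest index.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    dyn = dynamics if dynamics is not None else GridDynamics(grid, model)
    F = dyn.n_fixations
    stop = _stop_values(grid, model, declare_rule)
    V = stop.copy()
    sweeps = 0
    residual = math.inf
    for sweeps in range(1, max_iter + 1):
        EV = np.stack([dyn.expected_value(V[:, j], j) for j in range(F)], axis=1)  # (G, F)
        Vnew = np.empty_like(V)
        for i in range(F):
            switch = costs.c + np.where(np.arange(F) == i, 0.0, costs.cs)  # (F,)
            cont = (EV + switch[None, :]).min(axis=1)
            Vnew[:, i] = np.minimum(stop[:, i], cont)
        residual = float(np.max(np.abs(Vnew - V)))
        V = Vnew
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"value iteration did not converge in {max_iter} sweeps", residual
        )

    actions = _greedy_actions(V, stop, dyn, costs, declare_rule)
    meta = {
        "family": "cdac",
        "declare_rule": declare_rule,
        "c": costs.c,
        "cs": costs.cs,
        "grid_n": grid.n,
        "k": grid.k,
        "tol": tol,
        "iterations": sweeps,
        "residual": residual,
        "model": model.kind,
    }
    return ValueFunction(grid, V), Policy(grid, actions, meta)


def _greedy_actions(V: np.ndarray, stop: np.ndarray, dyn: GridDynamics,
                    costs: CostParams, declare_rule: DeclareRule) -> np.ndarray:
    """Argmin actions with the documented tie-break, vectorized over the grid."""
    EV = np.stack(
        [dyn.expected_value(V[:, j], j) for j in range(dyn.n_fixations)], axis=1
    )
    return greedy_actions(EV, dyn.grid, dyn.model, costs, declare_rule)


def greedy_actions(EV: np.ndarray, grid: BeliefGrid, model, costs: CostParams,
                   declare_rule: DeclareRule) -> np.ndarray:
    """Greedy action table from per-fixation continuation expectations ``EV`` (G, F).

    ``EV[:, j]`` is ``E_x[V(p', j)]`` at each grid point; the time and switch
    costs are added here.  Tie-break: Declare beats Fixate, lowest declare
    index, current fixation first among fixates, then lowest index.
    """
    G, k = grid.size, grid.k
    F = EV.shape[1]
    actions = np.empty((G, F), dtype=np.int64)
    declare_q = 1.0 - grid.points  # (G, k), cost of declaring each location
    for i in range(F):
        cols = []  # Q-values in tie-break priority order
        codes = []
        if declare_rule == "any":
            for l in range(k):
                cols.append(declare_q[:, l])
                codes.append(l)
        else:
            loc = model.fixation_location(i)
            cols.append(declare_q[:, loc])
            codes.append(loc)
        order = [i] + [j for j in range(F) if j != i]  # current fixation first
        for j in order:
            cols.append(costs.c + (costs.cs if j != i else 0.0) + EV[:, j])
            codes.append(k + j)
        Q = np.stack(cols, axis=1)
        # first column within 1e-12 of the row minimum wins: ties (including
        # float-level asymmetries at symmetric beliefs) resolve by priority
        best = np.argmax(Q <= Q.min(axis=1)[:, None] + 1e-12, axis=1)
        actions[:, i] = np.asarray(codes)[best]
    return actions


def theorem1_threshold(beta: float, c: float) -> float:
    """Belief threshold above which stopping and declaring is provably optimal.

    Solves ``p (2b-1)(1-p) = c (b p + (1-b)(1-p))`` for its larger root in
    (0, 1) — equivalently ``(2b-1) p^2 - (2b-1)(1-c) p + c(1-b) = 0``.  Above
    this confidence, the expected one-step belief improvement from any further
    observation is worth less than the time cost ``c`` of collecting it.
    """
    if not (0.5 < beta < 1.0):
        raise ValueError("beta must lie in (0.5, 1)")
    if c <= 0:
        raise ValueError("c must be positive")
    a = 2.0 * beta - 1.0
    b_coef = -a * (1.0 - c)
    c_coef = c * (1.0 - beta)
    disc = b_coef * b_coef - 4.0 * a * c_coef
    if disc < 0:
        raise ThresholdSaturationError(
            f"no real stopping threshold for beta={beta}, c={c}"
        )
    p_star = (-b_coef + math.sqrt(disc)) / (2.0 * a)
    if not (0.0 < p_star < 1.0):
        raise ThresholdSaturationError(
            f"stopping threshold {p_star:.4f} falls outside (0, 1)"
        )
    return p_star


def stopping_region(policy: Policy, fixation: int) -> np.ndarray:
    """Boolean mask over grid points where the policy declares at this fixation."""
    codes = policy.actions[:, fixation]
    return codes < policy.k
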