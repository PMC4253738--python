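"""Stochastic rollout of decision policies in foveal and peripheral search tasks.

A trial places a target at one of ``k`` locations; the simulated observer
starts from a prior belief and an initial fixation, draws one observation per
time step at the fixated location (or, with peripheral vision, a multi-
component observation about several locations at once), updates its belief by
Bayes' rule, and consults the policy until it declares.  Each trial is logged
as a :class:`TrialRecord` carrying the realized behavioral cost
``c * steps + cs * switches + 1{wrong}``.

Within-trial beliefs are tracked exactly (no gridding); policy lookups map
the belief to the nearest grid point, since actions are categorical and the
grid is fine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import DegenerateUpdateError, as_belief
from .solver import Action, CostParams, Policy

__all__ = [
    "PeripheralModel",
    "TrialRecord",
    "sample_observation",
    "simulate_trial",
    "run_experiment",
    "score_trial",
]

#: fixation labels for the three-location peripheral-vision task
PERIPHERAL_FIXATIONS = ("l1", "l2", "l3", "l12", "l23", "l13", "l123")
CENTER_FIXATION = 6  # index of l123


class PeripheralModel:
    """Three-location task with graded peripheral vision and 7 fixation spots.

    Fixations are the three stimulus locations, the three midpoints between
    pairs, and the center of the triangle.  Each observation is a 3-component
    binary vector, one component per stimulus, generated by independent
    Bernoulli draws favoring 1 at the target and 0 at distractors.  Component
    reliability depends on the distance of the stimulus from the fixated
    spot, through four tiers 1 > beta1 > beta2 > beta3 > beta4 >= 0.5:
    direct fixation -> beta1; nearer pair from a midpoint -> beta2; all three
    from the center -> beta3; any far-off stimulus -> beta4.

    Outcomes are encoded as integers 0..7 with bit ``i`` holding component
    ``x_i``.
    """

    kind = "peripheral"
    k = 3

    def __init__(self, betas):
        b1, b2, b3, b4 = (float(b) for b in betas)
        if not (1.0 > b1 > b2 > b3 > b4 >= 0.5):
            raise ValueError("need 1 > beta1 > beta2 > beta3 > beta4 >= 0.5")
        self.betas = (b1, b2, b3, b4)
        # tier[j, i] = reliability of component i when fixating spot j
        near = {3: (0, 1), 4: (1, 2), 5: (0, 2)}  # midpoints l12, l23, l13
        tier = np.full((7, 3), b4)
        for j in range(3):
            tier[j, j] = b1
        for j, pair in near.items():
            tier[j, list(pair)] = b2
        tier[CENTER_FIXATION, :] = b3
        self.component_reliability = tier
        self._table: np.ndarray | None = None

    @property
    def n_fixations(self) -> int:
        return 7

    @property
    def n_outcomes(self) -> int:
        return 8

    @property
    def fixations_are_locations(self) -> bool:
        return False

    def fixation_location(self, j: int) -> int:
        if j < 3:
            return j
        raise ValueError(f"fixation {PERIPHERAL_FIXATIONS[j]} is not a candidate location")

    def component_success(self, s: int, j: int) -> np.ndarray:
        """P(x_i = 1) for each component i, given target ``s`` and fixation ``j``."""
        r = self.component_reliability[j]
        return np.where(np.arange(3) == s, r, 1.0 - r)

    def likelihood_table(self) -> np.ndarray:
        """L[s, j, o] over the 8 encoded outcomes, product of 3 Bernoullis."""
        if self._table is None:
            L = np.empty((3, 7, 8))
            bits = ((np.arange(8)[:, None] >> np.arange(3)[None, :]) & 1).astype(float)
            for s in range(3):
                for j in range(7):
                    q = self.component_success(s, j)  # (3,)
                    comp = q[None, :] ** bits * (1 - q[None, :]) ** (1 - bits)
                    L[s, j, :] = comp.prod(axis=1)
            self._table = L
        return self._table

    def __repr__(self) -> str:  # pragma: no cover
        return f"PeripheralModel(betas={self.betas})"


def sample_observation(s: int, fixation: int, model, rng: np.random.Generator) -> int:
    """Draw one (encoded) observation given the true target and fixation."""
    L = model.likelihood_table()
    if not (0 <= s < L.shape[0] and 0 <= fixation < L.shape[1]):
        raise ValueError("invalid target or fixation index")
    probs = L[s, fixation, :]
    return int(rng.choice(L.shape[2], p=probs))


def score_trial(seconds: float, switches: int, correct: bool) -> float:
    """Point score of one experimental trial.

    100 minus 12.5 per second of response time, minus 25 per fixation
    switch, plus 50 for a correct final response or minus 50 otherwise.
    """
    if seconds < 0:
        raise ValueError("seconds must be non-negative")
    return 100.0 - 12.5 * seconds - 25.0 * switches + (50.0 if correct else -50.0)


@dataclass
class TrialRecord:
    """One simulated search trial."""

    true_target: int
    prior: np.ndarray
    fixations: list[int]  # fixation at which each observation was taken
    observations: list[int]
    declared: int  # -1 if truncated at the step cap
    correct: bool
    steps: int
    switches: int
    behavioral_cost: float
    initial_fixation: int
    truncated: bool = False
    seed: int | None = None
    condition: str = ""
    trial_id: int = 0

    def __post_init__(self):
        if self.steps != len(self.observations) or self.steps != len(self.fixations):
            raise ValueError("steps must equal the number of observations")
        n_sw = sum(a != b for a, b in zip(self.fixations, self.fixations[1:]))
        if self.fixations and self.fixations[0] != self.initial_fixation:
            raise ValueError("first observation must occur at the initial fixation")
        if n_sw != self.switches:
            raise ValueError("switch count inconsistent with fixation sequence")

    def first_fixation_duration(self) -> int:
        """Consecutive observations at the first fixation before the first switch or stop."""
        if not self.fixations:
            return 0
        first = self.fixations[0]
        d = 0
        for f in self.fixations:
            if f != first:
                break
            d += 1
        return d


def _policy_callable(policy):
    if isinstance(policy, Policy):
        return lambda p, cur, rng: policy.action_at(p, cur)
    if callable(policy):
        return policy
    raise TypeError("policy must be a grid Policy or a callable (p, current, rng) -> Action")


def simulate_trial(policy, model, costs: CostParams, prior, true_target: int,
                   initial_fixation: int, rng: np.random.Generator,
                   max_steps: int = 10_000, seed: int | None = None,
                   condition: str = "", trial_id: int = 0) -> TrialRecord:
    """Roll out one trial of ``policy`` and return its :class:`TrialRecord`.

    Per step: draw one observation at the current fixation, update the belief
    by Bayes' rule, and consult the policy; a Fixate action moves (or keeps)
    the fixation for the next observation, a Declare action terminates.  The
    first observation is always taken at ``initial_fixation`` (the saccade
    there has already been committed), so every trial has at least one step.
    Hitting ``max_steps`` flags the trial as truncated, which counts as an
    error declaration.
    """
    act = _policy_callable(policy)
    p = as_belief(prior, model.likelihood_table().shape[0])
    L = model.likelihood_table()
    current = int(initial_fixation)
    fixations: list[int] = []
    observations: list[int] = []
    switches = 0
    declared, truncated = -1, False
    while True:
        if len(observations) >= max_steps:
            truncated = True
            break
        x = sample_observation(true_target, current, model, rng)
        fixations.append(current)
        observations.append(x)
        lik = L[:, current, x]
        post = lik * p
        norm = post.sum()
        if norm <= 0:
            raise DegenerateUpdateError("observation impossible under current belief")
        p = post / norm
        a = act(p, current, rng)
        if a.is_declare:
            declared = a.index
            break
        j = a.index
        if j != current:
            switches += 1
            current = j
    steps = len(observations)
    correct = (declared == true_target) and not truncated
    cost = costs.c * steps + costs.cs * switches + (0.0 if correct else 1.0)
    return TrialRecord(
        true_target=int(true_target), prior=np.asarray(prior, dtype=float),
        fixations=fixations, observations=observations, declared=declared,
        correct=bool(correct), steps=steps, switches=switches,
        behavioral_cost=cost, initial_fixation=int(initial_fixation),
        truncated=truncated, seed=seed, condition=condition, trial_id=trial_id,
    )


def run_experiment(policy, model, costs: CostParams, prior, n_trials: int,
                   target_distribution, seed: int,
                   initial_fixation: int | str = "matched",
                   values=None, max_steps: int = 10_000,
                   condition: str = "") -> list[TrialRecord]:
    """Simulate ``n_trials`` i.i.d. trials with per-trial seeds derived from ``seed``.

    Targets are drawn from ``target_distribution``.  ``initial_fixation`` is
    an explicit fixation index, or one of:

    - ``"matched"``: drawn from the target distribution (probability
      matching, emulating human first-fixation statistics);
    - ``"uniform"``: uniform over fixation spots;
    - ``"best"``: argmin of the supplied value table ``values`` (shape
      (G, F)) at the prior.

    Per-trial randomness comes from independent child seeds of ``seed``, so
    results are order-independent and reproducible trial by trial.
    """
    target_distribution = as_belief(target_distribution)
    F = model.likelihood_table().shape[1]
    if initial_fixation == "best":
        if values is None:
            raise ValueError("initial_fixation='best' requires the value table")
        from .inference import interpolate  # local import avoids cycle at module load

    children = np.random.SeedSequence(seed).spawn(n_trials)
    trials = []
    for t, child in enumerate(children):
        rng = np.random.default_rng(child)
        target = int(rng.choice(len(target_distribution), p=target_distribution))
        if isinstance(initial_fixation, (int, np.integer)):
            fix0 = int(initial_fixation)
        elif initial_fixation == "matched":
            fix0 = int(rng.choice(len(target_distribution), p=target_distribution))
        elif initial_fixation == "uniform":
            fix0 = int(rng.integers(F))
        elif initial_fixation == "best":
            vals = [interpolate(values[:, i], prior, policy.grid) for i in range(F)]
            fix0 = int(np.argmin(vals))
        else:
            raise ValueError(f"unknown initial_fixation mode {initial_fixation!r}")
        trials.append(
            simulate_trial(
                policy, model, costs, prior, target, fix0, rng,
                max_steps=max_steps, seed=int(child.entropy) & 0x7FFFFFFF,
                condition=condition, trial_id=t,
            )
        )
    return trials
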