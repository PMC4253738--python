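"""Bayesian belief updating over target location, and the discretized belief simplex.

The observer searches for a target among ``k`` candidate locations. While
fixating location ``j`` it receives binary observations whose distribution
depends on whether the fixated location holds the target: a fixated target
emits 1 with probability ``beta`` (the observation reliability,
0.5 < beta <= 1), a fixated distractor emits 1 with probability ``1 - beta``.
Beliefs are posterior probability vectors over locations, updated by Bayes'
rule after every observation.

All solvers in this package operate on a uniform discretization of the belief
simplex (the composition lattice ``{m/n : m in Z^k_{>=0}, sum m = n}``), with
off-lattice beliefs handled by barycentric interpolation, which is exact for
affine functions of the belief.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ObservationModel",
    "BeliefGrid",
    "GridDynamics",
    "DegenerateUpdateError",
    "as_belief",
    "likelihood",
    "bayes_update",
    "predictive",
    "entropy",
    "build_belief_grid",
    "interpolate",
    "simplex_interp_weights",
]

_BELIEF_TOL = 1e-9


class DegenerateUpdateError(ValueError):
    """Raised when an observation has zero predictive probability under the prior."""


def as_belief(p, k: int | None = None) -> np.ndarray:
    """Validate and return ``p`` as a belief vector (1-D float array summing to 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("belief must be a 1-D probability vector")
    if k is not None and p.size != k:
        raise ValueError(f"belief has {p.size} entries, expected {k}")
    if np.any(p < -_BELIEF_TOL) or np.any(p > 1 + _BELIEF_TOL):
        raise ValueError("belief entries must lie in [0, 1]")
    if abs(p.sum() - 1.0) > _BELIEF_TOL:
        raise ValueError("belief entries must sum to 1")
    return p


class ObservationModel:
    """Foveal (gaze-contingent) observation model with binary observations.

    Parameters
    ----------
    k : int
        Number of candidate target locations (>= 2).
    beta : float
        Reliability of a fixated observation, in (0.5, 1].  A fixated target
        emits 1 with probability ``beta``; a fixated distractor emits 1 with
        probability ``1 - beta``.  ``beta = 0.5`` would be uninformative and
        is excluded, except that the solvers tolerate it for limit tests.
    """

    kind = "foveal"

    def __init__(self, k: int, beta: float):
        if k < 2:
            raise ValueError("need at least two candidate locations")
        if not (0.5 <= beta <= 1.0):
            raise ValueError("beta must lie in [0.5, 1]")
        self.k = int(k)
        self.beta = float(beta)
        self._table: np.ndarray | None = None

    # fixations coincide with candidate locations in the foveal task
    @property
    def n_fixations(self) -> int:
        return self.k

    @property
    def n_outcomes(self) -> int:
        return 2

    @property
    def fixations_are_locations(self) -> bool:
        return True

    def fixation_location(self, j: int) -> int:
        """Candidate location directly fixated by fixation index ``j``."""
        return j

    def likelihood_table(self) -> np.ndarray:
        """Return ``L[i, j, x] = P(x | target=i, fixation=j)``, shape (k, k, 2)."""
        if self._table is None:
            b = self.beta
            L = np.empty((self.k, self.k, 2))
            L[:, :, 1] = 1.0 - b
            L[:, :, 0] = b
            idx = np.arange(self.k)
            L[idx, idx, 1] = b
            L[idx, idx, 0] = 1.0 - b
            self._table = L
        return self._table

    def __repr__(self) -> str:  # pragma: no cover
        return f"ObservationModel(k={self.k}, beta={self.beta})"


def likelihood(i: int, j: int, x: int, model) -> float:
    """P(observation ``x`` | target at ``i``, fixation ``j``).

    For the foveal model this is ``beta^x (1-beta)^(1-x)`` when ``i == j`` and
    ``(1-beta)^x beta^(1-x)`` otherwise.  Peripheral models supply their own
    product-Bernoulli table; ``x`` then encodes the multi-component outcome.
    """
    L = model.likelihood_table()
    if not (0 <= i < L.shape[0]):
        raise ValueError(f"invalid location index {i}")
    if not (0 <= j < L.shape[1]):
        raise ValueError(f"invalid fixation index {j}")
    if not (isinstance(x, (int, np.integer)) and 0 <= x < L.shape[2]):
        raise ValueError(f"invalid observation {x!r}")
    return float(L[i, j, x])


def predictive(p, j: int, model) -> np.ndarray:
    """Marginal distribution of the next observation at fixation ``j``: P(x) = sum_i p_i f_{i,j}(x)."""
    p = as_belief(p, model.likelihood_table().shape[0])
    return p @ model.likelihood_table()[:, j, :]


def bayes_update(p, x: int, j: int, model) -> np.ndarray:
    """Posterior belief after observing ``x`` at fixation ``j``: p'_i ∝ f_{i,j}(x) p_i."""
    p = as_belief(p, model.likelihood_table().shape[0])
    lik = model.likelihood_table()[:, j, x]
    post = lik * p
    norm = post.sum()
    if norm <= 0.0:
        raise DegenerateUpdateError(
            f"observation x={x} at fixation {j} has zero predictive probability"
        )
    return post / norm


def entropy(p) -> float:
    """Shannon entropy of a belief in nats, with 0·log 0 := 0."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass(frozen=True)
class BeliefGrid:
    """Uniform composition-lattice discretization of the (k-1)-simplex.

    ``counts`` enumerates all non-negative integer vectors summing to ``n``
    in lexicographic order; ``points = counts / n`` are the grid beliefs.
    """

    k: int
    n: int
    counts: np.ndarray  # (G, k) int
    points: np.ndarray  # (G, k) float
    _lookup: np.ndarray | dict = field(repr=False)

    @property
    def size(self) -> int:
        return self.counts.shape[0]

    def index_of(self, counts) -> int:
        """Flat index of an integer grid coordinate vector."""
        counts = np.asarray(counts, dtype=int)
        key = counts[:-1]
        if isinstance(self._lookup, dict):
            idx = self._lookup.get(tuple(int(c) for c in key), -1)
        else:
            idx = int(self._lookup[tuple(key)])
        if idx < 0:
            raise KeyError(f"{counts} is not a grid point")
        return idx

    def indices_of(self, counts: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`index_of` for an (m, k) integer array."""
        counts = np.asarray(counts, dtype=int)
        if isinstance(self._lookup, dict):
            return np.fromiter(
                (self._lookup[tuple(row)] for row in counts[:, :-1].tolist()),
                dtype=np.int64,
                count=counts.shape[0],
            )
        return self._lookup[tuple(counts[:, :-1].T)]

    def nearest_index(self, p) -> int:
        """Index of the lattice point nearest to belief ``p`` (largest-remainder rounding)."""
        p = as_belief(p, self.k)
        u = p * self.n
        c = np.floor(u).astype(int)
        rem = u - c
        short = self.n - int(c.sum())
        if short > 0:
            # distribute the deficit to the largest remainders
            for i in np.argsort(-rem)[:short]:
                c[i] += 1
        return self.index_of(c)


def build_belief_grid(k: int, n: int, max_points: int = 5_000_000) -> BeliefGrid:
    """Enumerate the composition lattice of resolution ``n`` over ``k`` locations.

    The lattice has C(n+k-1, k-1) points (e.g. 20301 for k=3, n=200).  A cap
    guards against accidentally requesting an astronomically large grid.
    """
    if k < 2 or n < 1:
        raise ValueError("need k >= 2 and n >= 1")
    n_points = math.comb(n + k - 1, k - 1)
    if n_points > max_points:
        raise ValueError(
            f"grid would have {n_points} points, exceeding the cap {max_points}"
        )

    def compositions(total: int, parts: int):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    counts = np.array(list(compositions(n, k)), dtype=int)
    points = counts / float(n)
    if (n + 1) ** (k - 1) <= max_points:
        lookup = np.full((n + 1,) * (k - 1), -1, dtype=np.int64)
        lookup[tuple(counts[:, :-1].T)] = np.arange(n_points)
    else:  # pragma: no cover - very large k/n combinations
        lookup = {tuple(row): i for i, row in enumerate(counts[:, :-1].tolist())}
    return BeliefGrid(k=k, n=n, counts=counts, points=points, _lookup=lookup)


def simplex_interp_weights(points: np.ndarray, grid: BeliefGrid):
    """Barycentric (simplicial) interpolation weights on the composition lattice.

    For each belief in ``points`` (shape (m, k)), returns vertex indices
    (m, k) and convex weights (m, k) such that the belief is the weighted
    combination of the vertex grid points of the Kuhn simplex containing it.
    Exact at lattice points and for affine functions of the belief.

    The construction works in cumulative coordinates ``t_i = sum_{l<=i} n p_l``,
    where the lattice becomes the monotone integer lattice and the standard
    Kuhn (sorted-fractional-parts) triangulation applies; ties are broken
    toward the higher coordinate so every vertex stays inside the simplex.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    m, k = P.shape
    if k != grid.k:
        raise ValueError("points dimensionality does not match grid")
    if np.any(P < -1e-9) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-7):
        raise ValueError("points must lie on the probability simplex")
    n = grid.n
    d = k - 1

    t = np.cumsum(P * n, axis=1)[:, :d]
    t = np.clip(t, 0.0, float(n))
    base = np.minimum(np.floor(t), n - 1).astype(int)
    g = t - base  # fractional parts in [0, 1]

    # sort fractional parts descending; ties prefer the higher coordinate index
    order = np.lexsort((-np.broadcast_to(np.arange(d), (m, d)), -g), axis=1)
    g_sorted = np.take_along_axis(g, order, axis=1)

    weights = np.empty((m, k))
    weights[:, 0] = 1.0 - g_sorted[:, 0]
    if d > 1:
        weights[:, 1:d] = g_sorted[:, :-1] - g_sorted[:, 1:]
    weights[:, d] = g_sorted[:, -1]

    # vertices in cumulative coordinates: start at base, increment coords in order
    T = np.repeat(base[:, None, :], k, axis=1)  # (m, k vertices, d)
    rows = np.arange(m)[:, None]
    for v in range(1, k):
        T[:, v, :] = T[:, v - 1, :]
        T[rows[:, 0], v, order[:, v - 1]] += 1

    # back to occupation counts c_1 = T_1, c_i = T_i - T_{i-1}, c_k = n - T_d
    counts = np.empty((m, k, k), dtype=int)
    counts[:, :, 0] = T[:, :, 0]
    if d > 1:
        counts[:, :, 1:d] = np.diff(T, axis=2)
    counts[:, :, d] = n - T[:, :, d - 1]

    # zero-weight vertices may fall outside the simplex after tie-breaking;
    # remap them to the base vertex (their weight does not contribute)
    bad = counts.min(axis=2) < 0
    if bad.any():
        if np.any(bad & (weights > 1e-9)):
            raise AssertionError("interpolation produced an invalid weighted vertex")
        b_pt, b_v = np.nonzero(bad)
        counts[b_pt, b_v, :] = counts[b_pt, 0, :]

    idx = grid.indices_of(counts.reshape(m * k, k)).reshape(m, k)
    return idx, weights


def interpolate(values, p, grid: BeliefGrid) -> float:
    """Barycentric interpolation of a grid value field at belief ``p``."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.size,):
        raise ValueError("values must be defined on every grid point")
    p = as_belief(p, grid.k)
    idx, w = simplex_interp_weights(p[None, :], grid)
    return float((values[idx] * w).sum())


def interpolation_operator(points: np.ndarray, grid: BeliefGrid) -> sp.csr_matrix:
    """Sparse (m, G) operator mapping grid value fields to values at ``points``."""
    idx, w = simplex_interp_weights(points, grid)
    m, k = idx.shape
    rows = np.repeat(np.arange(m), k)
    return sp.csr_matrix(
        (w.ravel(), (rows, idx.ravel())), shape=(m, grid.size)
    )


class GridDynamics:
    """Precomputed one-step belief dynamics on a grid, shared by all solvers.

    For every fixation ``j`` and observation outcome ``x`` this caches the
    predictive probability at each grid point, a sparse operator realizing
    ``V -> E-interpolated V`` at the exact Bayes posteriors of all grid
    points, and the posterior entropies (needed by the Infomax objective).
    """

    def __init__(self, grid: BeliefGrid, model):
        self.grid = grid
        self.model = model
        L = model.likelihood_table()  # (k, F, X)
        k, F, X = L.shape
        if k != grid.k:
            raise ValueError("model and grid disagree on the number of locations")
        P = grid.points
        self.n_fixations = F
        self.n_outcomes = X
        self.pred = np.einsum("gi,ifx->gfx", P, L)  # (G, F, X)
        self.ops: dict[tuple[int, int], sp.csr_matrix] = {}
        self.post_entropy = np.zeros((grid.size, F, X))
        for j in range(F):
            for x in range(X):
                post = P * L[:, j, x][None, :]
                norm = self.pred[:, j, x]
                safe = norm > 0
                post[safe] /= norm[safe, None]
                post[~safe] = P[~safe]  # zero predictive mass: weight never used
                self.ops[(j, x)] = interpolation_operator(post, grid)
                with np.errstate(divide="ignore", invalid="ignore"):
                    plogp = np.where(post > 0, post * np.log(post), 0.0)
                self.post_entropy[:, j, x] = -plogp.sum(axis=1)

    def expected_value(self, V_col: np.ndarray, j: int) -> np.ndarray:
        """E_x[ V(p'_x, j) ] at every grid point, for fixation ``j``."""
        ev = np.zeros(self.grid.size)
        for x in range(self.n_outcomes):
            ev += self.pred[:, j, x] * (self.ops[(j, x)] @ V_col)
        return ev
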