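# Methods

## Model

Search over `k` candidate locations is cast as a belief MDP.  The hidden
state is the target location `s`; the observable state is the posterior
belief `p_t` (a point on the probability simplex) together with the current
fixation.  Observations are binary and conditionally i.i.d. given `(s,
fixation)`: a fixated target emits 1 with probability `β ∈ (0.5, 1]`, a
fixated distractor with `1 − β`.  In the peripheral-vision variant the
fixation set has seven elements (the three stimulus locations, the three
pairwise midpoints, and the center) and each observation is a 3-component
binary vector whose component reliabilities follow four tiers
`1 > β₁ > β₂ > β₃ > β₄ ≥ 0.5`: direct fixation → β₁, the near pair from a
midpoint → β₂, all three from the center → β₃, anything far → β₄.
Components favor 1 at the target and 0 at distractors.

The behavioral cost of a trial is `c·steps + c_s·switches + 1{wrong}`; the
error cost is normalized to 1, so `c` and `c_s` are expressed in units of
one error.  The controller minimizes its expectation.  Because continuing
forever accumulates unbounded time cost while stopping costs at most 1, the
optimal policy is stationary with a finite effective horizon, and sunk
costs drop out of the decision — the solver works with the incremental
(stationary) form of the stopping and continuation values.

Two declaration conventions are supported and kept explicit throughout
(`declare_rule`): `"any"` — the Bellman stop term is `min_i (1 − pᵢ)`, the
literal optimal-control formulation, default for solver work and for the
peripheral task (where fixations need not be candidate locations); and
`"current"` — only the fixated location can be declared, matching the
gaze-contingent human task in which the response key selects the last
viewed patch.  Behavioral simulations of the foveal task use `"current"`.

## Numerics

**Grid.**  The simplex is discretized as the composition lattice
`{m/n : m ∈ Z^k_{≥0}, Σm = n}` with `n = 200` by default (201 points per
edge, 20 301 points at `k = 3`).  A cap guards against accidental
`C(n+k−1, k−1)` blow-ups.

**Interpolation.**  Off-lattice beliefs are evaluated by simplicial
(barycentric) interpolation.  Working in cumulative coordinates
`t_i = Σ_{l≤i} n·p_l` maps the lattice to the monotone integer lattice,
where the Kuhn (sorted-fractional-parts) triangulation applies; ties in the
fractional parts are broken toward the higher coordinate so every vertex of
the containing cell stays on the simplex.  The scheme is exact at lattice
points and reproduces affine functions to machine precision (property
tested).  Nearest-neighbor lookup is used only for *actions* during
simulation, since actions are categorical and the grid is fine.

**Value iteration.**  Initialized at the stopping cost, which makes every
sweep pointwise non-increasing (tested).  Expectations over the binary (or
8-outcome peripheral) observation alphabet are exact sums; the posterior of
every grid point under every (fixation, outcome) pair is precomputed once
as a sparse interpolation operator, so one sweep is a handful of sparse
matrix-vector products.  Convergence: sup-norm change `< 1e-6`, max 500
sweeps (the slowest configuration used, `c = 0.005`, needs ≈ 130).
Outcomes with zero predictive probability (possible at `β = 1`) contribute
nothing and their undefined posteriors are never touched.

**Tie-breaking.**  The greedy policy resolves ties deterministically —
Declare beats Fixate, lower declare index first, current fixation first
among fixates, then lower index — using a `1e-12` tolerance on Q-values so
that exactly symmetric beliefs (where float summation order would otherwise
pick arbitrarily) resolve by the documented priority.  Policy permutation
equivariance therefore holds exactly up to genuine Q-ties, which occur at
symmetric beliefs and on simplex edges (with one location ruled out, the
remaining two are equally informative); the tests verify that wherever a
relabeled policy disagrees, the two actions' Q-factors coincide to 1e-10.

**Infomax.**  Backward induction on
`V_I(p) = min_j E_x[H(p′) + V_I(p′)]` with beliefs above the stopping
threshold absorbing at zero future cost; the entropy of the next posterior
accrues on the transition into the stopped set.  The formulation makes the
value and policy independent of the current fixation by construction.  A
finite-horizon variant exists for sensitivity checks.  The default
threshold is the closed-form stopping bound `p*(β, c)`, the larger root of
`(2β−1)p² − (2β−1)(1−c)p + c(1−β) = 0`; an accuracy-matching calibration
(bisection under common random numbers) is provided as an alternative.

**Myopic rule.**  Implemented literally as a one-step lookahead with the
minimum over declarations outside the expectation.  Because the belief is a
martingale, the expected post-observation stop cost equals the current one,
with two consequences that the tests pin down: under `declare_rule="any"`
the rule always stops immediately (its stopping region is the whole
simplex, a strict overestimate of the exact region), and under
`"current"` it never re-fixates the current location and stops iff no other
location's belief exceeds the current one by more than `c + c_s`.  Its
switching boundary consequently moves less with `c_s` than the exact
solver's (tested as a symmetric-difference comparison).

## Value-function approximation

Both surrogates follow the same outer loop: draw `m` fresh uniform beliefs
(flat Dirichlet), apply one Bellman backup through the current surrogate,
refit, repeat.  One surrogate is kept per current-fixation location, since
the switch cost makes the value fixation-dependent.  Surrogate outputs are
clipped to `[0, 1]` (the value is a probability plus bounded increments);
clip counts are recorded in the policy metadata.

**RBF.**  `M = 49` Gaussian bases (variance σ² = 0.05) centered on a 7×7
uniform lattice over the free belief coordinates `(p₁, p₂) ∈ [0,1]²` — the
lattice covers the simplex; bases centered outside it simply contribute
tails.  Weights are refit by ridge-regularized least squares (ridge 1e-8).
A constant field is *not* exactly representable in this basis (edge effects
leave a ≈0.8% residual), which the tests assert at its actual magnitude.

**GPR.**  Squared-exponential kernel with length scale 1, signal variance
1, noise variance 0.1, fit to 200 points per sweep.  Inputs are
standardized per dimension to the training sample's mean and standard
deviation — the convention under which a unit length scale means "one input
standard deviation".  On raw simplex coordinates (domain diameter ≈1.4) the
same hyperparameters make the kernel nearly degenerate and the fit visibly
biased; with standardization the fixed-hyperparameter fit reaches ≈0.9%
RMSE against the exact value function, and the ARD variant (per-dimension
length scales, signal and noise variances re-learned each sweep by marginal
likelihood) independently recovers length scales of the same order.

**Convergence of the sweeps.**  Because each sweep refits on a fresh random
sample and the smooth surrogate cannot represent the kinks of the exact
value function, the iteration does not contract to a fixed point: it
settles into a steady state where the fit fluctuates at the
approximation-error scale (≈2% relative for the RBF configuration above).
A weight-space criterion is additionally meaningless for correlated bases —
refitting the *same* surface on a new sample changes the RBF weight vector
by ≈100% (condition number ≈2×10⁷) while changing predictions by ≈2% — and
a GP has no weight vector at all.  Convergence is therefore declared in
function space, on a fixed seeded reference set of 500 beliefs: the sweep
stops when the relative ℓ2 change of the surrogate's reference predictions
either falls below `tol = 1e-3` or stops decreasing geometrically (change
larger than half the previous sweep's change), i.e. when the Bellman
transient is exhausted and only steady-state fluctuation remains.  Under
this criterion both surrogates converge in 4 outer sweeps at
`(c, c_s, β) = (0.1, 0.1, 0.9)` across seeds, and their induced grid
policies agree with the exact solver on 91–96% of belief-fixation pairs.

## Simulator

Within a trial the belief is tracked exactly (no gridding); the first
observation is always taken at the supplied initial fixation (the saccade
is already committed), after which the policy is consulted after every
update.  A step cap (default 10⁴) flags runaway trials as truncated, which
count as errors.  Per-trial randomness derives from child seeds of a master
seed (`numpy` `SeedSequence.spawn`), so trial `i` is reproducible in
isolation and results are order-independent; paired policy comparisons
share the master seed, giving identical target sequences and initial
fixations across policies.

Experiment emulation: targets are i.i.d. from the block's distribution
(uniform, or 1:3:9 odds).  Initial fixations can be fixed (the peripheral
task starts at the center), uniform, probability-matched to the prior
(emulating human first-fixation statistics, and used for the
confirmation-bias analysis so that both patch classes are visited first),
or chosen greedily from a value table.  The point score of a trial is
`100 − 12.5·seconds − 25·switches ± 50` by response correctness; model time
steps are not converted to physical seconds anywhere else.

## Confirmation-bias analysis

Trials are conditioned on the class of the first-fixated patch: the labeled
("9") patch versus the two less probable patches pooled (individually they
attract too few first fixations).  Within a class: *hit rate* — fraction of
first-fixations on the actual target that were declared; *false-alarm
rate* — fraction of first-fixations on a distractor that were declared
anyway; *dwell* — consecutive steps at the first fixation before the first
switch or stop, reported separately for target-first and distractor-first
trials and restricted to correct trials.  Cells with fewer than 20 trials
are flagged rather than reported.  Zero-step trials carry no first fixation
and are excluded (counted).

## What the synthetic data does and does not emulate

The simulator generates exactly the observation process the model assumes:
Bernoulli evidence that is i.i.d. given target and fixation, stationary
reliabilities, a prior that is known and fixed within a block, and
cost-free instantaneous saccades apart from the lump `c_s`.  Real
gaze-contingent search data violate all of these in degree — motion
evidence is temporally correlated, sensitivity fluctuates, subjects learn
the prior across trials and differ in their internal costs, and saccades
take time that scales with amplitude.  Passing behavioral checks therefore
show that the *policies* differ in the predicted directions under the
model's own assumptions (confirmation-bias orderings, switch-cost
sensitivity), not that any particular human dataset is fit; fitting `c` and
`c_s` to individuals is out of scope.

## Problem sizes and defaults

| quantity | default | note |
|---|---|---|
| grid resolution `n` | 200 | 201 points/edge; 20 301 points at k=3 |
| value-iteration tol | 1e-6 sup-norm | ≤ 500 sweeps |
| foveal environments | (0.1, {0, 0.1}, 0.9), (0.005, {0, 0.1}, 0.68) | costs in error units |
| peripheral tiers | (0.62, 0.60, 0.55, 0.50), c = 0.05, c_s ∈ {0, 0.005} | start at center |
| behavioral runs | 10⁴ trials per condition | paired master seeds |
| RBF | M = 49, σ² = 0.05, m = 200 | ridge 1e-8 |
| GPR | ls 1, signal var 1, noise var 0.1, 200 points | standardized inputs |
| surrogate convergence | pred-change < 1e-3 or stalled | 500-point reference set |

## Known limitations

Exact solving scales as `O(k n^{k−1})` grid points; `k > 5` is out of reach
by design and the surrogates are the intended route for larger `k` (only
`k ≤ 4` is exercised).  The closed-form stopping bound applies to the
zero-switch-cost foveal task; with `c_s > 0` it remains an inner bound
(the stopping region only grows) but is not tight.  The Infomax horizon is
treated as converged-absorbing; alternatives (entropy accrual after
stopping, finite horizons) change the policy little but are only exposed,
not studied.  Greedy maximum-a-posteriori search is represented by a
uniform-random baseline rather than reimplemented, as it is near-random on
this task.  Gaussian (continuous) observation noise is not implemented.
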