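# Methods

## Models and rollouts

Two model contracts are supported.

**Transcriptional gene circuit.** State y ∈ (0,1)^n with the explicit
discrete update

    y(t+Δt) = (Δt/τ) ⊙ σ(W y + B) + (1 − Δt/τ) ⊙ y,

σ the logistic function, W the n×n interaction matrix (zeros encode absent
edges), B the bias, τ > 0 per-node time constants (seconds). The update is
a convex combination of y and a sigmoid value whenever Δt/τ ≤ 1, so the
open unit box is forward-invariant; the simulator rejects Δt/τ > 1.
Random circuits draw nonzero W ~ U[−30, 30], B ~ U[−10, 10], τ ~ U[1, 15],
with row-wise in-degrees enforced by zeroing weights. The inner loop is a
numba kernel; a reverse-mode (backpropagation-through-time) kernel returns
exact gradients of the oscillator loss with respect to (y0, W, B) for the
Adam optimizer.

**Generic ODE.** `rate_fn(y, t) → dy/dt` integrated with LSODA
(`scipy.integrate.odeint`) between uniform output grid points at
atol 1e−6, rtol 1e−12, at most 1000 internal steps per interval. These
tolerances are kept exactly as configured even though rtol < atol is
unusual; both are exposed in `RolloutConfig`. Defaults: T = 2500 s,
Δt = 0.1 s → 25,001 output points including t0. A longer default horizon
(T = 25000) is intended when deriving intervention bounds from a default
time course; both are plain config values. Hooks (perturbation
displacements, clamps) are applied after each output step in the fixed
order *integrate → displace → clamp*, and integration restarts at each
hook application.

**Failure policy.** A rollout that produces NaN or negative states is
*flagged* invalid, never raised, because the curation filters must count
failures. Negative values within the solver atol (1e−6) are treated as
numerical zero.

## Spaces and encoders

The intervention space is an axis-aligned box: per-node initial states
[min_t y_d(t)/r, r·max_t y_d(t)] around a default rollout with r = 20, or
the joint (y0, W, B) box for circuit engineering (n² + 2n dimensions).

Behavior encoders:

* **endpoint** — (y_i(T), y_j(T)) for a chosen node pair; Euclidean
  metric;
* **fourier** — amplitude spectrum (unnormalized rfft) of one node's
  signal over the settled half-window [T/2, T], truncated to the first
  256 bins; catalog distance is the mean absolute spectral difference.
  The half-window and the 256-bin truncation are package choices: the
  transient is excluded for the same reason the periodicity filter uses
  the second half, and the low bins carry the oscillation content;
* **oscillation** — (A, ω, b) with A = (max − min)/2 on the half-window,
  ω the non-DC amplitude argmax refined by parabolic interpolation on a
  Hann-windowed spectrum (ties toward lower frequency; cycles per second
  on the Δt grid; 0 for constants by convention), and b the signal mean
  taken over an integer number of estimated periods to suppress
  partial-cycle bias. On the default grid this recovers synthetic cosines
  with A ∈ [0.1, 0.5], ω ∈ [0.005, 0.2] Hz to well under 1%.

## Exploration

`run_random_search` draws i ~ U(I). `run_imgep` bootstraps with N_init
uniform draws (default 10% of the budget N — the bootstrap share is not a
prescribed constant, so it is exposed in `ImgepConfig`), then repeats:
goal ~ U(bounding box of reached goals, scaled 1.3 about its center;
degenerate axes floored at 1e−6 of the axis scale so the first
goal-directed step is defined); intervention = nearest reached goal's
intervention + N(0, 0.1·(high − low)) per dimension, clipped to I.
Invalid records are stored but excluded from nearest-goal queries — the
policy must not chase NaN outcomes. Three named RNG substreams
(bootstrap, goal sampling, policy steps) are spawned from the run seed so
each component replays independently; with N_init = N the process is
exactly random search on the bootstrap stream.

## Perturbation battery

All perturbations are conditioned on the unperturbed reference
trajectory; per-node extent means max_t y − min_t y.

* **noise(σ, p)** — Gaussian kicks, std σ × extent per node, every p
  seconds within a window (default 80 s from t = 0; the window is a
  package default, configurable);
* **push(m, k)** — k instantaneous displacements of the behavior-plane
  coordinates, magnitude m × extent along a uniformly random direction,
  at times uniform in [0, settling time], where the settling time is the
  first t with |y(t) − y(T)| < 0.02·|y(T) − y(0)| (vector norms);
* **wall(l, k)** — k hard segments of length l × (Euclidean norm of the
  plane extent), centered at uniform fractions of the reference path
  length and oriented perpendicular to the local motion. Collisions are
  resolved by hard projection: the step is cut at the wall, its remainder
  is projected onto the wall tangent (sliding allowed), with a tiny
  back-offset; after four unresolved passes the step is blocked. This law
  was chosen over a repulsive force field for determinism and
  testability; walls act only in the 2-D behavior plane.

The default evaluation grid has 18 sub-families, replicated 3 times
(P = 54): noise (σ, p) ∈ {(0.001,5), (0.005,5), (0.1,5), (0.005,10),
(0.005,5), (0.005,1)} — the duplicate pair is kept as configured in the
reference protocol — and push/wall sextuples read as magnitudes
{0.05, 0.1, 0.15} with one event plus counts {1, 2, 3} at magnitude 0.1
(fractional event counts are meaningless; the reading is configurable).

A zero-extent reference yields zero-magnitude perturbations and a
`degenerate` flag rather than an error.

## Sensitivity and diversity

Goal sensitivity = mean over valid perturbed rollouts of
‖z_p − z‖₂ / extent, with extent the Euclidean norm of the per-axis
ranges of the unperturbed trajectory projected to Z (a per-axis vector
normalization is available as an alternative; "extent" has no unique
formula). Invalid perturbed rollouts are excluded and counted, not
imputed as zero. A zero-extent trajectory reports absolute distances with
a flag. A goal's headline sensitivity is the pooled mean over all P
perturbations; the versatility-robustness curve uses the per-family wall
mean by default.

Representative goals for the battery: sample K-subsets (default K = N/10)
of the valid records 500 times, keep the subset with maximal threshold
coverage.

**Threshold coverage** rescales descriptors to [0,1]² with a shared
normalization box, places ε-disks (ε = 0.05) at the points, and divides
the union area by (1 + 2ε)² — the padded square, which the disks cannot
exit. This normalization is the one under which four disjoint attractors
cap at 4πε²/(1+2ε)² ≈ 0.026. Area integration is a deterministic
2000×2000 cell-center grid; shapely polygon unions and Monte-Carlo darts
serve as independent oracles in the tests. Supported in 2-D only;
**binning coverage** (occupied-bin fraction, default 20 bins per
dimension) serves higher-dimensional spaces such as (A, ω, b).

## Curation

Per-node classification: *valid* (no NaN/negative), *settled* (no
t ≥ settle_after — default 0.96·T, i.e. 2400 s on the default horizon —
with |y(t) − y(T)| ≥ 0.02·|y(T) − y(0)|; a zero net move requires exactly
zero late deviation), *periodic* (some non-DC bin of the unnormalized DFT
of [T/2, T] has magnitude ≥ 40). The threshold 40 is scale-bound to the
default sampling — a 0.1-amplitude bin-aligned sine peaks at
0.1·12501/2 ≈ 625 — so the half-window length is recorded in the
diagnostics of every classification. "Sustained oscillator" = valid and
periodic.

System filters on a 50-rollout batch from random initial states:
F1 fails at ≥ 20% invalid/unsettled/periodic trajectories (inclusive at
equality); F2 fails if either behavior axis spans < 0.1 (both axes must
pass); F3 fails if the endpoints occupy ≤ 4 bins of a 20×20 grid.

## Energy landscape

All states of a trajectory set are projected to the behavior plane and
histogrammed on a G×G grid (default G = 100); a pseudocount (default 0.5)
is added before normalizing to P, and U = −ln P is smoothed by a bicubic
spline (default smoothing 0, i.e. interpolating — grid values are
unchanged; a regularized mode is available). States are weighted
uniformly over time (no burn-in discard). Attractors appear as local
minima of U.

## Oscillator benchmark

Target: A ~ U(0.1, 0.5), b ~ U(A, 1 − A), ω ~ Beta(2, 8) — the wave
A·cos(2πωt) + b stays in [0, 1]. Loss L = Σ_t (y_0(t) − wave(t))², node 0
is the phenotype node, τ = 1, n = 3. Four strategies share one budget
(default 5000): Adam (lr 1e−3, β1 = 0.02, β2 = 0.001, eps 1e−8 — the
reference protocol's nonstandard names b1/b3 are mapped to β1/β2, with
the conventional (0.9, 0.999) behind a flag; gradients are exact BPTT
through the unrolled update, cross-checked against central finite
differences), CMA-ES (own implementation of the standard rank-μ update;
initial mean at the box center, initial σ = 0.25 of the shortest axis —
unspecified in the protocol, chosen here), uniform random search, and the
IMGEP over the Fourier goal space. One target is sampled per run
(pooling across targets is available). Sustained oscillators are counted
with the DFT criterion; diversity in (A, ω, b) uses 20 bins per
dimension; the best random/IMGEP discoveries can be finetuned with 100
Adam steps under an accept-if-better guard. Budget is counted in
optimization steps/rollouts per method, matching the equal-budget
protocol.

At the full 5000-rollout budget (see `scripts/acceptance.py`) curiosity
search discovers sustained oscillators at a 20–30× higher rate than
uniform sampling; the absolute uniform-sampling rate is ~1% and is
sensitive to the integrator of the circuit (the explicit Δt = 0.1 update
used here can sustain marginal oscillations that an adaptive solver
damps).

## Setpoint-reset search

A clamp schedule overwrites one node's value at every output step during
the active window (default: a new level every 10 s for 100 s), then the
system evolves freely. A schedule is scored by the mean Euclidean
distance of the final endpoints (over start states × optional
perturbation battery draws) to the target setpoint. Random search draws
candidate levels log-uniformly in [0.1×, 10×] of the start states' mean
clamp-node level ("near the current steady states" made concrete;
configurable). Without a battery the score is deterministic.

## What the synthetic fixtures do and do not show

The test fixtures are random transcriptional gene circuits, closed-form
redundant I→Z mappings, a two-node toggle switch, and synthetic cosines.
They exercise every pipeline stage without downloads, and they reproduce
the qualitative phenomena (curiosity search dominating uniform screening
under redundancy, severalfold oscillator enrichment, landscape minima at
attractors, basin-flipping clamps). They do not emulate stiff biochemical
kinetics, conservation laws, wide dynamic ranges across nodes, or
assignment-rule/event semantics of real SBML models — passing tests show
the machinery is correct, not that any particular biological model is
well-behaved under it. Reduced problem sizes (budgets of a few hundred,
shorter horizons) are used in the unit suite; the acceptance script runs
the full 5000-rollout study conditions.

## Known limitations

Threshold coverage is 2-D only. Wall semantics live in the behavior
plane, not the full state space. The SBML path is an adapter contract
(wrap a parsed rate function as `OdeModel`); no SBML semantics are
implemented. Stochastic (SSA) simulation, delay equations and
parameter-space (genetic) perturbations are out of scope.
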