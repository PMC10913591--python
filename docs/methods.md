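# Methods

## Simulation model

spikemesh is a discrete-time simulator: time advances in unit steps, and
each step updates the system from the previous step's state.  Structure and
dynamics are separated.  Components (`NeuronGroup`, `SynapseGroup`,
`Network`) hold state but execute nothing; all dynamics live in `Behavior`
modules attached under integer priority keys.  The scheduler flattens every
attached behavior into one globally key-sorted list; each iteration runs
each behavior's `step` hook exactly once in that order.  Key ties across
components resolve by component registration order, which is stable and
reproducible.  The iteration counter is 0 before the first step and is
incremented at the start of each step, so the first step observes
`iteration == 1` and interval work gated on `iteration % k == 0` first
fires at step k (100, 200, 300 for k=100 over 300 steps).  Re-initializing
an initialized network is an error, not a no-op: silently re-running setup
hooks would reset learned weights.

Randomness: the network holds one master seed; each component derives its
generator from `SeedSequence(master_seed, spawn_key=(registration_index,))`.
Attaching a recorder or any behavior that draws no random numbers therefore
never perturbs another component's stream, and two runs with the same seed
are bit-identical.

All array work goes through a small backend facade (allocate, seeded fills,
boolean-mask and integer-mesh indexing, axis sums, clip, cast, synchronize).
The shipped implementation is NumPy on the CPU; the registry accepts
alternative implementations with the same contract, and the `synchronize`
barrier is part of the timing protocol so asynchronous backends cannot leak
queued work past a clock stop.

## Kernels and the exactness argument

Every optimized kernel has a naive counterpart that serves as its oracle:

| optimized | naive oracle | agreement |
|---|---|---|
| indexed row/column gather-sum | full matrix-vector product | bit-identical (f64/f32, src-major); rel. err < 1e-5 in f32 worst case |
| mesh STDP `W[ix_(post, pre)] += lr` | outer-product update | bit-identical, all dtypes |
| multi-lag mesh STDP | sequential outer updates per lag | bit-identical |
| masked (mesh) clipping | full-matrix clipping | identical on touched entries; untouched entries preserved |
| CSR sparse row gather | densified indexed gather | bit-identical |

The transmission equivalence deserves a note.  Floating-point addition is
not associative, so a BLAS product and a fancy-indexed sum can differ by
ulps.  The naive product here therefore accumulates in strict ascending
source order.  Adding an exact zero is a floating-point identity, so the
product (which adds a zero term for every silent source) produces the same
partial sums as the gather (which skips them) whenever the gather also
reduces sequentially.  NumPy's axis-0 reduction over gathered rows is
sequential, so for src-major matrices the equivalence is exact by
construction at any active count; dst-major axis-1 gathers switch to
pairwise summation above 8 active sources, which is why the certification
sweep (and the reference models) use the src-major layout — also the
cache-friendly choice, since gathered source rows are contiguous.

The mesh STDP identity needs no tolerance at all: spike vectors are
boolean, so a (pre, post) pair occurs at most once per mesh and fancy
indexing's repeated-index ambiguity cannot arise; both forms add exactly
`lr` (cast to the weight dtype) to exactly the coincident entries, and
`x + 0.0 == x` for the rest.

Weight layouts: `dst_major` (D×S, a destination's incoming weights per row)
and `src_major` (S×D).  `transpose_layout` physically transposes into
contiguous storage and flips the tag; `W[d, s]` semantics are
layout-independent.  Nominal storage is element count × dtype width
(8/4/2 bytes); f16 is supported for storage and correctness only, with no
performance claim.

Multi-lag STDP default window: lags −4…+4 with amplitude
`sign(lag) · lr · exp(−|lag|/3)` and 0 at lag 0 — an antisymmetric
discrete exponential, fully overridable per lag.  The window pairs pre
spikes from `lag` steps ago with current post spikes for positive lags and
vice versa for negative ones, using ring-buffered spike histories.

Normalization divides each destination neuron's afferent weight sum to a
target of 1.0 (configurable); zero-sum rows are left untouched (0/0 would
destroy the row).  It is idempotent to within one rounding step.

## Reference models

Both models are a single population with dense all-to-all recurrence
(self-connections included) and no homeostasis; activity is sustained
purely by strong external noise.  Behavior keys: 1 noise, 2 neuron
dynamics, 3 transmission, 4 plasticity, 5 interval normalization (disabled
by default; enabled in the example config), 9 recorders.  Transmission
reads the current step's source spikes (computed at key 2) and its output
is consumed by the membrane update of the next step; One-Step STDP pairs
the previous step's pre spikes with the current step's post spikes
(`spikes_old` is all-false on the first step).

LIF (dimensionless units): `v ← v + λ(v_rest − v) + I_syn + U(0, h)`,
inclusive threshold `v ≥ v_th` → spike, reset to `v_reset`.  Defaults
`v_rest = v_reset = 0`, `v_th = 1`, `λ = 0.1`, `h = 0.165`.  The noise
bound was calibrated once so an isolated neuron fires on ≈1% of steps;
subthreshold decay follows the closed form
`v_rest + (v0 − v_rest)(1 − λ)^k` exactly.

Izhikevich: one Euler step per unit time of
`v' = 0.04v² + 5v + 140 − u + I`, `u' = a(bv − u)` (simultaneous update
from the old state), spike at `v ≥ 30`, reset `v ← c`, `u ← u + d`;
regular-spiking parameters `a=0.02, b=0.2, c=−65, d=8`.  The noise-free
resting equilibrium is the stable root of `0.04v² + (5−b)v + 140 = 0`
(v = −70, u = bv for b = 0.2) and is an exact fixed point of the update.
Gaussian drive `N(0, 7²)` gives ≈1% isolated-neuron firing.  The unit-step
Euler scheme tracks a 100×-finer integration to within 0.25 model units
over 100 steps at constant drive I = 1; above I ≈ 3 the unit step departs
from the fold of the quadratic nullcline and no such bound holds, which
bounds the regime in which single-step integration is trustworthy.

Trace STDP: per-neuron eligibility traces decay by `exp(−1/τ)` each step
(τ = 20) and gain +1 at spikes; each post spike potentiates its incoming
row by `a₊ · x_pre`, each pre spike depresses its outgoing column by
`a₋ · x_post`, touched rows/columns are clipped.  A single pre→post pair
at lag Δ yields `Δw = a₊ e^{−Δ/τ}` exactly, and the window is
antisymmetric and monotone in |Δ|.

Scaling: initial weights are `U(0, 1/N)` so the total recurrent drive at a
given firing rate is independent of population size, and the builder's
default plasticity increment scales the same way (0.1/N).  A size-fixed
increment makes the relative weight growth — and through the recurrent
loop, the firing rate — grow with N; with both scaled, the mean firing
fraction varies by under ~2% across N ∈ {1,000 … 10,000} instead of
running away.  Weight bounds stay at [0, 1].

## Synthetic inputs and what the tests show

There is no external data; all inputs are generated: Bernoulli spike
vectors at a given rate (default 1%, the sparse-activity regime the
optimizations target) and dense uniform weight matrices.  This emulates
the *load profile* of a sparsely firing recurrent network — realistic
active-set sizes, realistic memory traffic — but not structured biology:
no topology, no Dale's law, no input correlations, no delays.  Passing
tests certify numerical equivalence, scheduling semantics, determinism
and relative performance; they say nothing about the biological fidelity
of any particular model built on the framework.

## Problem sizes and numerical choices

* Construction/storage counts run at the full 5,000 → 10,000 scale
  (5×10⁷ entries, 200 MB in f32); the naive update at that scale is
  *counted* by an instrumented walk of the outer product's broadcast index
  space rather than executed repeatedly.
* Equivalence sweeps: 1,000 random instances, sizes ≤ 200, 1% spikes —
  small enough to run in seconds, large enough to hit empty/singleton/
  multi-active cases.
* Model-level naive-vs-optimized equivalence: N = 1,000, 300 steps, f64.
* The timing experiment uses N = 2,000, 300 steps, 10 replicates per
  variant: large enough that the naive outer product dominates the naive
  variant's cost, small enough to keep a full grid in minutes on one CPU.
  Replicate r shares its seed across cells, so timing comparisons are on
  identical spike streams.  Only the *ordering* (optimized < naive) is
  asserted; the magnitude is hardware-dependent and merely reported.
* Tolerances: f64 equivalences are exact (see the argument above); the f32
  transmission tolerance is 1e-5 relative, two orders above f32's ~6e-8
  ulp at the observed sum magnitudes; normalization checks use 1e-9 in
  f64; the LIF closed form is checked at 1e-10 over 50 steps.

## Known limitations

* One CPU backend ships; the facade supports registering accelerated
  backends but none is bundled.
* The sparse path optimizes memory, not speed; no sparse-specific kernel
  tuning is attempted.
* No axonal delays beyond the one-step STDP pairing, no conductance-based
  synapses, no plotting.
* Subgroup views expose masked read/write of parent state but do not
  re-route synapse groups; partitioning a population into separately
  connected blocks is done by building multiple groups.
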