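# spikemesh

A discrete-time spiking neural network (SNN) simulation framework for
computational neuroscientists who want full control over every operation in
the simulation loop without giving up vector performance.  Models are
assembled from small *behavior* modules attached to neuron groups, synapse
groups, or the network under integer priority keys; one global key order
drives every simulation step.  The numerical core is a set of vectorized
kernels that exploit the binary nature of spikes — and, for every optimized
kernel, the package carries its naive counterpart as a built-in oracle so
the equivalence of the two can be certified on demand.

## The idea

Spikes are boolean, so most of the arithmetic in a dense SNN step is
multiplication by zero.  With a spike vector `s ∈ {0,1}^S` and weight
matrix `W` (destination-major, shape `D×S`):

* **Transmission.**  The textbook input `I = W s` costs `D·S`
  multiplications.  Gathering only the active rows of the source-major
  (`S×D`) matrix, `I = Σ_{i: s_i=1} W2[i, :]`, costs `|active|·D` additions
  over contiguous memory — at 1% firing, a ~100-fold reduction in work.
* **Plasticity.**  The Hebbian update `W += lr · (post ⊗ pre)` builds a full
  `D×S` outer product (50 million multiplications for a 5,000 → 10,000
  projection).  The *index mesh* — the cross product of active pre- and
  post-indices, `np.ix_`-style — addresses exactly the coincident entries,
  so `W[mesh] += lr` does the same update in `|pre|·|post|` operations,
  bit-identically.
* **Clipping and normalization.**  Hard bounds `[w_min, w_max]` are applied
  only to mesh entries that were just modified; afferent-sum normalization
  runs on an interval (e.g. every 100 steps) instead of every step.
* **Precision and sparsity.**  Weight matrices carry `f64/f32/f16` tags
  (a 5,000×10,000 `f32` matrix is 200 MB nominal), and a CSR sparse
  fallback covers the sub-1%-connectivity regime.

Two reference models exercise the kernels end to end: leaky
integrate-and-fire neurons with One-Step STDP (pre spike at `t−1` ×
post spike at `t`), and Izhikevich neurons with the standard pair-based
trace STDP rule `Δw = a± · exp(−Δt/τ)`.  Both are noise-driven with weak
all-to-all recurrence, firing near 1–3% per step independent of population
size.

## Worked example

```python
from spikemesh import build_reference_model, mean_firing_fraction, raster_of

net = build_reference_model("lif_onestep", 1000, seed=42)
net.simulate_iterations(300)
print(len(raster_of(net)), mean_firing_fraction(net))
```

prints `8205 0.0273...`: in 300 steps the 1,000-neuron network emitted
8,205 spikes, i.e. about 2.7% of the population fires per step.  The
`examples/` directory holds one short script per capability; running
`examples/03_benchmark_speedup.py` on a typical laptop CPU prints

```
      model implementation   N dtype backend  mean_seconds   speedup
lif_onestep          naive 500   f64   numpy      0.290330  1.000000
lif_onestep      optimized 500   f32   numpy      0.005268 55.111416
```

— the full optimized pipeline (indexed transmission, source-major layout,
mesh STDP, masked clipping, f32) against the naive one on the same seeds;
the two variants emit identical spike rasters in f64.

## Command line

```sh
spikemesh run examples/config_lif_normalized.yaml   # simulate, write raster/weights
spikemesh benchmark <config>                        # timing grid + speed-up table
spikemesh validate                                  # kernel-vs-oracle sweeps
spikemesh fixtures <spec>                           # seeded fixture files
```

Outputs are plain CSV (spike rasters with 0-based neuron indices and
1-based iterations; benchmark tables) or HDF5 (weight snapshots, array
records), all written atomically.

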