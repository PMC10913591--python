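# LIF + One-Step STDP run with interval weight normalization enabled.
# Usage: spikemesh run examples/config_lif_normalized.yaml --out out_lif
model: lif_onestep
n_neurons: 1000
implementation: optimized
dtype: f32
seed: 42
iterations: 300
normalize: true
plasticity:
  norm_interval: 100
recorders:
  - variable: v
    cadence: 10
    format: csv
output_dir: out_lif
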