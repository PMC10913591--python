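"""Build the LIF + One-Step STDP reference network, run it, inspect output.

A single 1,000-neuron population, all-to-all recurrent weak synapses,
driven by uniform noise.  Prints the mean firing fraction (expected near
the few-percent regime) and the first few raster rows (iteration, neuron).
"""

from spikemesh import build_reference_model, mean_firing_fraction, raster_of

net = build_reference_model("lif_onestep", 1000, seed=42)
net.simulate_iterations(300)

raster = raster_of(net)
print(f"simulated 300 steps of 1,000 LIF neurons")
print(f"total spikes: {len(raster)}")
print(f"mean firing fraction per step: {mean_firing_fraction(net):.4f}")
print("first spikes (iteration, neuron):")
for row in raster[:5]:
    print(f"  t={row[0]:3d}  neuron {row[1]}")
# The firing fraction is the average share of the population spiking per
# step; with weak synapses it is set almost entirely by the noise drive.
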