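"""Measure the trace-STDP timing window with a pair protocol.

One pre and one post neuron; force a single spike in each, separated by a
controlled lag, and record the weight change.  Pre-before-post pairs
potentiate, post-before-pre pairs depress, and the magnitude decays
exponentially with the lag (time constant 20 steps here).
"""

import numpy as np

from spikemesh import Network, NeuronGroup, SynapseGroup
from spikemesh.core import Behavior
from spikemesh.kernels import DST_MAJOR, SpikeVector, WeightMatrix
from spikemesh.models import (KEY_PLASTICITY, KEY_SYNAPSE, PlasticityParams,
                              TraceParams, TraceSTDP)


def measure_dw(lag, pre_first):
    net = Network(seed=0)
    pre, post = NeuronGroup(net, 1), NeuronGroup(net, 1)
    syn = SynapseGroup(net, pre, post)

    class Init(Behavior):
        def setup(self, s):
            s.W = WeightMatrix(np.array([[0.5]]), DST_MAJOR)

    syn.attach_behavior(KEY_SYNAPSE, Init())
    syn.attach_behavior(KEY_PLASTICITY, TraceSTDP(
        TraceParams(tau_pre=20, tau_post=20, a_plus=0.05, a_minus=0.05),
        PlasticityParams()))
    for g in (pre, post):
        g.spikes = SpikeVector.empty(1)
        g.spikes_old = SpikeVector.empty(1)
    net.initialize()

    first, second = (pre, post) if pre_first else (post, pre)
    w0 = syn.W.data[0, 0]
    first.spikes = SpikeVector([True])
    net.simulate_iterations(1)
    first.spikes = SpikeVector([False])
    for _ in range(lag - 1):
        net.simulate_iterations(1)
    second.spikes = SpikeVector([True])
    net.simulate_iterations(1)
    return syn.W.data[0, 0] - w0


print(f"{'lag':>5s} {'pre->post dW':>14s} {'post->pre dW':>14s}")
for lag in (1, 2, 4, 8, 16):
    dw_pot = measure_dw(lag, pre_first=True)
    dw_dep = measure_dw(lag, pre_first=False)
    print(f"{lag:5d} {dw_pot:14.6f} {dw_dep:14.6f}")
print("\npositive left column, negative right, both shrinking with lag:")
print("the classic exponential plasticity window, here 0.05*exp(-lag/20).")
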