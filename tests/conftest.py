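import numpy as np
import pytest
from hypothesis import settings

from spikemesh import Behavior, Network, NeuronGroup, SynapseGroup

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


class ProbeBehavior(Behavior):
    """Appends (key, component name) to a shared trace on every hook call."""

    def __init__(self, trace, **kw):
        super().__init__(**kw)
        self.trace = trace

    def setup(self, component):
        self.trace.append(("setup", self.key, component.unique_name))

    def step(self, component):
        self.trace.append(("step", self.key, component.unique_name))


@pytest.fixture
def probe_cls():
    return ProbeBehavior


def pair_network(plastic_behavior):
    """Two one-neuron groups joined by one synapse, no noise or dynamics.

    The test drives spiking directly by replacing the groups' spike
    vectors; the initial weight is 0.5.
    """
    import numpy as np
    from spikemesh.kernels import DST_MAJOR, SpikeVector, WeightMatrix
    from spikemesh.models import KEY_PLASTICITY, KEY_SYNAPSE

    net = Network(seed=0)
    pre = NeuronGroup(net, 1)
    post = NeuronGroup(net, 1)
    syn = SynapseGroup(net, pre, post)

    class Init(Behavior):
        def setup(self, s):
            s.W = WeightMatrix(np.array([[0.5]]), DST_MAJOR)

    syn.attach_behavior(KEY_SYNAPSE, Init())
    syn.attach_behavior(KEY_PLASTICITY, plastic_behavior)
    for g in (pre, post):
        g.spikes = SpikeVector.empty(1)
        g.spikes_old = SpikeVector.empty(1)
    net.initialize()
    return net, pre, post, syn


@pytest.fixture
def tiny_net():
    """Network with two neuron groups and one connecting synapse group."""
    net = Network(seed=7)
    a = NeuronGroup(net, 4, tags={"A"})
    b = NeuronGroup(net, 3, tags={"B"})
    syn = SynapseGroup(net, a, b, tags={"ab"})
    return net, a, b, syn
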