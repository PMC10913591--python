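"""Reference network models as behavior stacks.

Two self-connected single-population models, each driven purely by strong
external noise (no homeostasis), with all-to-all recurrent synapses that
are deliberately weak so the firing rate stays near the 1% regime across
population sizes:

* ``lif_onestep`` — leaky integrate-and-fire neurons, uniform noise input,
  Dirac (pulse) synapses, and One-Step STDP: a pre spike at step t-1 that
  coincides with a post spike at step t increments the weight, then only
  the touched weights are clipped into [w_min, w_max].  Built in an
  ``optimized`` variant (src-major layout, indexed transmission, mesh STDP,
  masked clipping) and a ``naive`` variant (dst-major, full matrix-vector
  product, outer-product STDP, whole-matrix clipping).  Both compute the
  same mathematics; with f64 weights they emit identical spike rasters.

* ``izhikevich_trace`` — Izhikevich neurons (regular-spiking parameters),
  normal noise input, and the standard pair-based trace STDP rule with
  exponentially decaying pre/post eligibility traces.

Behavior key order (documented contract): 1 noise input, 2 neuron dynamics,
3 synaptic transmission, 4 plasticity, 5 interval normalization (off by
default), 9 recorders.  Transmission therefore uses the current step's
source spikes and its result is consumed by the neuron update of the *next*
step; plasticity pairs the previous step's pre spikes with the current
step's post spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Behavior, Network, NeuronGroup, SpikeRasterRecorder, SynapseGroup
from .kernels import (DST_MAJOR, SRC_MAJOR, SpikeVector, WeightMatrix, clip_full,
                      clip_mesh, mesh_from_spikes, stdp_mesh, stdp_outer,
                      synaptic_input_indexed, synaptic_input_product)

# Behavior key contract of the reference models.
KEY_NOISE = 1
KEY_NEURON = 2
KEY_SYNAPSE = 3
KEY_PLASTICITY = 4
KEY_NORMALIZATION = 5
KEY_RECORDER = 9


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire parameters (dimensionless model units).

    Per step: v <- v + leak * (v_rest - v) + I_syn + U(0, noise_high);
    spike (inclusive) at v >= v_threshold, then reset to v_reset.
    ``noise_high`` is calibrated so an isolated neuron fires on ~1% of
    steps.
    """

    v_rest: float = 0.0
    v_reset: float = 0.0
    v_threshold: float = 1.0
    leak: float = 0.1
    noise_high: float = 0.165

    def __post_init__(self):
        if not (self.v_reset <= self.v_rest < self.v_threshold):
            raise ValueError("require v_reset <= v_rest < v_threshold")
        if not 0.0 < self.leak <= 1.0:
            raise ValueError("leak must be in (0, 1]")


@dataclass(frozen=True)
class IzhikevichParams:
    """Izhikevich two-variable neuron, regular-spiking defaults.

    Euler step of one model-time unit: v' = 0.04 v^2 + 5 v + 140 - u + I,
    u' = a (b v - u); spike at v >= spike_cutoff, then v <- c, u <- u + d.
    ``noise_sd`` is calibrated so an isolated neuron fires on ~1% of steps.
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    spike_cutoff: float = 30.0
    noise_mean: float = 0.0
    noise_sd: float = 7.0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")
        if self.c >= self.spike_cutoff:
            raise ValueError("reset potential c must lie below spike_cutoff")

    def resting_state(self) -> tuple[float, float]:
        """Stable equilibrium (v*, u* = b v*) of the noise-free dynamics."""
        # roots of 0.04 v^2 + (5 - b) v + 140 = 0; the more negative is stable
        p = [0.04, 5.0 - self.b, 140.0]
        roots = np.roots(p)
        v = float(np.min(roots.real))
        return v, self.b * v


@dataclass(frozen=True)
class PlasticityParams:
    """Hebbian update magnitude and hard weight bounds."""

    learning_rate: float = 0.001
    w_min: float = 0.0
    w_max: float = 1.0
    norm_interval: int = 100

    def __post_init__(self):
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")
        if self.norm_interval < 1:
            raise ValueError("norm_interval must be >= 1")


@dataclass(frozen=True)
class TraceParams:
    """Pair-based trace STDP: exponential eligibility traces per neuron."""

    tau_pre: float = 20.0
    tau_post: float = 20.0
    a_plus: float = 0.001
    a_minus: float = 0.001


# ---------------------------------------------------------------------------
# neuron behaviors
# ---------------------------------------------------------------------------

class UniformNoiseInput(Behavior):
    """Adds U(0, high) external drive to the group's input accumulator."""

    def __init__(self, high: float, **kw):
        super().__init__(high=high, **kw)

    def setup(self, group: NeuronGroup) -> None:
        if not hasattr(group, "input"):
            group.input = group.vector("zeros")

    def step(self, group: NeuronGroup) -> None:
        high = self.parameter("high")
        group.input += group.rng.uniform(0.0, high, group.size).astype(
            group.input.dtype, copy=False)


class NormalNoiseInput(Behavior):
    """Adds N(mean, sd^2) external drive to the group's input accumulator."""

    def __init__(self, mean: float, sd: float, **kw):
        super().__init__(mean=mean, sd=sd, **kw)

    def setup(self, group: NeuronGroup) -> None:
        if not hasattr(group, "input"):
            group.input = group.vector("zeros")

    def step(self, group: NeuronGroup) -> None:
        group.input += group.rng.normal(
            self.parameter("mean"), self.parameter("sd"), group.size).astype(
            group.input.dtype, copy=False)


class LIFDynamics(Behavior):
    """LIF membrane update, threshold spike, reset, buffer rotation.

    Consumes (and zeroes) ``group.input``, which at this point holds the
    current step's noise plus the synaptic input transmitted at the end of
    the previous step.
    """

    def __init__(self, params: LIFParams, **kw):
        super().__init__(**kw)
        self.params = params

    def setup(self, group: NeuronGroup) -> None:
        p = self.params
        group.v = group.vector(p.v_rest)
        if not hasattr(group, "input"):
            group.input = group.vector("zeros")
        group.spikes = SpikeVector.empty(group.size)
        group.spikes_old = SpikeVector.empty(group.size)

    def step(self, group: NeuronGroup) -> None:
        p = self.params
        v = group.v
        v += p.leak * (p.v_rest - v) + group.input
        fired = v >= p.v_threshold
        v[fired] = p.v_reset
        group.spikes_old = group.spikes
        group.spikes = SpikeVector(fired)
        group.input[:] = 0.0


class IzhikevichDynamics(Behavior):
    """One-unit Euler step of the Izhikevich model with spike-reset."""

    def __init__(self, params: IzhikevichParams, **kw):
        super().__init__(**kw)
        self.params = params

    def setup(self, group: NeuronGroup) -> None:
        v0, u0 = self.params.resting_state()
        group.v = group.vector(v0)
        group.u = group.vector(u0)
        if not hasattr(group, "input"):
            group.input = group.vector("zeros")
        group.spikes = SpikeVector.empty(group.size)
        group.spikes_old = SpikeVector.empty(group.size)

    def step(self, group: NeuronGroup) -> None:
        p = self.params
        v, u = group.v, group.u
        dv = 0.04 * v * v + 5.0 * v + 140.0 - u + group.input
        du = p.a * (p.b * v - u)
        v += dv
        u += du
        fired = v >= p.spike_cutoff
        v[fired] = p.c
        u[fired] += p.d
        group.spikes_old = group.spikes
        group.spikes = SpikeVector(fired)
        group.input[:] = 0.0


# ---------------------------------------------------------------------------
# synapse behaviors
# ---------------------------------------------------------------------------

class DiracSynapse(Behavior):
    """Pulse transmission: each source spike delivers its full weight.

    ``implementation="optimized"`` allocates the matrix src-major and sums
    the active source rows; ``"naive"`` allocates dst-major and runs the
    full matrix-vector product.  Contributions from multiple afferent
    synapse groups accumulate in the destination's input.
    """

    def __init__(self, implementation: str = "optimized", init_scale: float | None = None,
                 **kw):
        if implementation not in ("optimized", "naive"):
            raise ValueError(f"unknown implementation {implementation!r}")
        super().__init__(implementation=implementation, init_scale=init_scale, **kw)
        self.implementation = implementation
        self.init_scale = init_scale

    def setup(self, syn: SynapseGroup) -> None:
        # weak weights ~ U(0, 1/src_size): total recurrent drive stays O(rate)
        scale = self.init_scale if self.init_scale is not None else 1.0 / syn.src.size
        layout = SRC_MAJOR if self.implementation == "optimized" else DST_MAJOR
        syn.W = syn.matrix(layout, "uniform", scale=scale)
        if not hasattr(syn.dst, "input"):
            syn.dst.input = syn.dst.vector("zeros")

    def step(self, syn: SynapseGroup) -> None:
        if self.implementation == "optimized":
            contrib = synaptic_input_indexed(syn.W, syn.src.spikes,
                                             backend=syn.network.backend)
        else:
            contrib = synaptic_input_product(syn.W, syn.src.spikes)
        syn.dst.input += contrib


class OneStepSTDP(Behavior):
    """Degenerate STDP window: pre at t-1 coincident with post at t.

    Optimized: mesh increment plus masked clipping.  Naive: full outer
    product plus whole-matrix clipping.  Both add the same learning_rate to
    the same entries, so final weights are bit-identical when initial
    weights lie inside [w_min, w_max].
    """

    def __init__(self, params: PlasticityParams, implementation: str = "optimized", **kw):
        if implementation not in ("optimized", "naive"):
            raise ValueError(f"unknown implementation {implementation!r}")
        super().__init__(**kw)
        self.params = params
        self.implementation = implementation

    def step(self, syn: SynapseGroup) -> None:
        p = self.params
        pre, post = syn.src.spikes_old, syn.dst.spikes
        if self.implementation == "optimized":
            mesh = mesh_from_spikes(pre, post, syn.W.layout)
            if mesh.size == 0:
                return
            b = syn.network.backend
            stdp_mesh(syn.W, mesh, p.learning_rate, backend=b)
            clip_mesh(syn.W, mesh, p.w_min, p.w_max, backend=b)
        else:
            stdp_outer(syn.W, pre, post, p.learning_rate)
            clip_full(syn.W, p.w_min, p.w_max, backend=syn.network.backend)


class TraceSTDP(Behavior):
    """Standard pair-based STDP via exponentially decaying traces.

    Each step: traces decay by exp(-1/tau) and gain +1 at spikes; every
    post spike potentiates its incoming row by a_plus * x_pre; every pre
    spike depresses its outgoing column by a_minus * x_post; the touched
    rows/columns are clipped into [w_min, w_max].
    """

    def __init__(self, trace: TraceParams, plasticity: PlasticityParams, **kw):
        super().__init__(**kw)
        self.trace = trace
        self.plasticity = plasticity

    def setup(self, syn: SynapseGroup) -> None:
        self.x_pre = np.zeros(syn.src.size)
        self.x_post = np.zeros(syn.dst.size)
        self._decay_pre = float(np.exp(-1.0 / self.trace.tau_pre))
        self._decay_post = float(np.exp(-1.0 / self.trace.tau_post))

    def step(self, syn: SynapseGroup) -> None:
        t, p = self.trace, self.plasticity
        pre, post = syn.src.spikes, syn.dst.spikes
        self.x_pre *= self._decay_pre
        self.x_post *= self._decay_post
        self.x_pre[pre.active] += 1.0
        self.x_post[post.active] += 1.0

        W = syn.W
        dt = W.data.dtype
        if post.count():
            dw = (t.a_plus * self.x_pre).astype(dt)
            if W.layout == DST_MAJOR:
                W.data[post.active, :] += dw[None, :]
                W.data[post.active, :] = np.clip(W.data[post.active, :], p.w_min, p.w_max)
            else:
                W.data[:, post.active] += dw[:, None]
                W.data[:, post.active] = np.clip(W.data[:, post.active], p.w_min, p.w_max)
        if pre.count():
            dw = (t.a_minus * self.x_post).astype(dt)
            if W.layout == DST_MAJOR:
                W.data[:, pre.active] -= dw[:, None]
                W.data[:, pre.active] = np.clip(W.data[:, pre.active], p.w_min, p.w_max)
            else:
                W.data[pre.active, :] -= dw[None, :]
                W.data[pre.active, :] = np.clip(W.data[pre.active, :], p.w_min, p.w_max)


class IntervalNormalization(Behavior):
    """Afferent-sum normalization executed every ``interval`` iterations.

    With the iteration counter starting at 1 on the first step, an interval
    of 100 over 300 steps fires at iterations 100, 200 and 300.
    """

    def __init__(self, interval: int = 100, target: float = 1.0, **kw):
        if interval < 1:
            raise ValueError("interval must be >= 1")
        super().__init__(interval=int(interval), target=target, **kw)
        self.interval = int(interval)
        self.target = target
        self.executions = 0

    def setup(self, syn: SynapseGroup) -> None:
        self.executions = 0

    def step(self, syn: SynapseGroup) -> None:
        if syn.network.iteration % self.interval != 0:
            return
        from .kernels import normalize_afferent
        normalize_afferent(syn.W, self.target)
        self.executions += 1


class PopulationRateRecorder(Behavior):
    """Records the firing fraction (spikes / N) of a group each step."""

    def __init__(self, **kw):
        super().__init__(tags={"recorder", "rate"}, **kw)
        self.buffer: list[float] = []

    def setup(self, group: NeuronGroup) -> None:
        self.buffer = []

    def step(self, group: NeuronGroup) -> None:
        self.buffer.append(group.spikes.count() / group.size)

    def mean_rate(self) -> float:
        return float(np.mean(self.buffer)) if self.buffer else 0.0


# ---------------------------------------------------------------------------
# model builder
# ---------------------------------------------------------------------------

MODEL_KINDS = ("lif_onestep", "izhikevich_trace")


def build_reference_model(kind: str, n_neurons: int, *, seed: int = 0,
                          implementation: str = "optimized", dtype: str = "f64",
                          backend: str = "numpy",
                          lif: LIFParams | None = None,
                          izhikevich: IzhikevichParams | None = None,
                          plasticity: PlasticityParams | None = None,
                          trace: TraceParams | None = None,
                          normalize: bool = False,
                          record_raster: bool = True,
                          record_rate: bool = True) -> Network:
    """Assemble one of the two reference networks.

    One N-neuron group, one dense all-to-all recurrent synapse group
    (self-connections included), and the model's behavior stack under the
    documented key order.  Interval normalization ships disabled by default
    (``normalize=True`` enables it).  The network is returned initialized.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    net = Network(seed=seed, backend=backend, dtype=dtype)
    group = NeuronGroup(net, n_neurons, tags={"exc"})
    syn = SynapseGroup(net, group, group, tags={"recurrent"})
    # Weights are initialized ~U(0, 1/N) so total recurrent drive is
    # population-size-invariant; the default plasticity increment scales the
    # same way, keeping relative weight growth (and hence the firing rate)
    # comparable across N.  Explicit parameter blocks override both.
    if plasticity is None:
        plasticity = PlasticityParams(learning_rate=0.1 / n_neurons)
    if trace is None:
        trace = TraceParams(a_plus=0.1 / n_neurons, a_minus=0.1 / n_neurons)

    if kind == "lif_onestep":
        group.attach_behavior(KEY_NOISE, UniformNoiseInput((lif or LIFParams()).noise_high))
        group.attach_behavior(KEY_NEURON, LIFDynamics(lif or LIFParams()))
        syn.attach_behavior(KEY_SYNAPSE, DiracSynapse(implementation=implementation))
        syn.attach_behavior(KEY_PLASTICITY,
                            OneStepSTDP(plasticity, implementation=implementation))
    else:
        izh = izhikevich or IzhikevichParams()
        group.attach_behavior(KEY_NOISE, NormalNoiseInput(izh.noise_mean, izh.noise_sd))
        group.attach_behavior(KEY_NEURON, IzhikevichDynamics(izh))
        syn.attach_behavior(KEY_SYNAPSE, DiracSynapse(implementation=implementation))
        syn.attach_behavior(KEY_PLASTICITY, TraceSTDP(trace, plasticity))

    if normalize:
        syn.attach_behavior(KEY_NORMALIZATION,
                            IntervalNormalization(plasticity.norm_interval))
    if record_raster:
        group.attach_behavior(KEY_RECORDER, SpikeRasterRecorder())
    if record_rate:
        group.attach_behavior(KEY_RECORDER + 1, PopulationRateRecorder())
    net.initialize()
    return net


def raster_of(net: Network) -> np.ndarray:
    """The raster recorder's (iteration, neuron_index) array."""
    for rec in net.find_by_tag("raster"):
        return rec.as_array()
    raise LookupError("network has no raster recorder")


def mean_firing_fraction(net: Network) -> float:
    for rec in net.find_by_tag("rate"):
        return rec.mean_rate()
    raise LookupError("network has no rate recorder")
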