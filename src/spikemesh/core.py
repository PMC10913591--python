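"""Behavior-based simulation scaffold.

A network is a bag of components — neuron groups, synapse groups, the
network itself — that carry no dynamics of their own.  All dynamics live in
:class:`Behavior` objects attached under integer priority keys.  Each
simulation step executes every behavior's ``step`` hook once, in a single
*global* key order across all components, so e.g. every noise behavior in
the network can run before any membrane update regardless of which group it
sits on.

Determinism: the network owns one master seed; every component derives its
own random generator from (master seed, registration index), so adding a
recorder or reordering unrelated code never perturbs another component's
random stream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Any, Callable, Iterable

import numpy as np

from .backend import get_backend
from .kernels import DST_MAJOR, SRC_MAJOR, SpikeVector, WeightMatrix

_uid_counter = itertools.count()


class TaggableObject:
    """Base for every component and behavior: a unique name plus tag labels."""

    def __init__(self, tags: Iterable[str] = (), name: str | None = None):
        self.tags: set[str] = set(tags)
        self.unique_name = name or f"{type(self).__name__}_{next(_uid_counter)}"

    def add_tag(self, tag: str) -> None:
        self.tags.add(tag)

    def has_tag(self, tag: str) -> bool:
        return tag in self.tags

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<{type(self).__name__} {self.unique_name} tags={sorted(self.tags)}>"


class Behavior(TaggableObject):
    """A unit of dynamics attached to a component under a priority key.

    Subclasses override :meth:`setup` (runs once, before the first step) and
    :meth:`step` (runs once per iteration); both receive the owning
    component.  Keyword arguments become the behavior's parameter map,
    retrievable with :meth:`parameter`.
    """

    _REQUIRED = object()

    def __init__(self, tags: Iterable[str] = (), **parameters):
        super().__init__(tags=tags)
        self.parameters: dict[str, Any] = dict(parameters)
        self.key: int | None = None        # set at attachment
        self.owner: NetworkObject | None = None

    def parameter(self, name: str, default: Any = _REQUIRED) -> Any:
        if name in self.parameters:
            return self.parameters[name]
        if default is Behavior._REQUIRED:
            raise KeyError(f"behavior {self.unique_name} requires parameter {name!r}")
        return default

    def setup(self, component: "NetworkObject") -> None:  # noqa: D401
        """One-time initialization; override in subclasses."""

    def step(self, component: "NetworkObject") -> None:
        """Per-iteration dynamics; override in subclasses."""


class NetworkObject(TaggableObject):
    """A component that can hold behaviors: group, synapse group, or network."""

    def __init__(self, network: "Network | None", tags: Iterable[str] = ()):
        super().__init__(tags=tags)
        self.behaviors: dict[int, Behavior] = {}
        self.network = network
        self.registration_index: int = -1
        self._rng: np.random.Generator | None = None
        if network is not None:
            network._register(self)

    # -- behaviors ------------------------------------------------------
    def attach_behavior(self, key: int, behavior: Behavior) -> Behavior:
        """Register ``behavior`` under ``key``; keys are unique per component."""
        key = int(key)
        if key in self.behaviors:
            raise ValueError(
                f"key {key} already attached on {self.unique_name} "
                f"(held by {self.behaviors[key].unique_name})")
        behavior.key = key
        behavior.owner = self
        self.behaviors[key] = behavior
        return behavior

    # -- randomness -----------------------------------------------------
    @property
    def rng(self) -> np.random.Generator:
        """Per-component generator derived from the network master seed."""
        if self._rng is None:
            raise RuntimeError(f"{self.unique_name} is not registered on a network")
        return self._rng

    def _derive_rng(self, master_seed: int) -> None:
        ss = np.random.SeedSequence(entropy=master_seed,
                                    spawn_key=(self.registration_index,))
        self._rng = np.random.default_rng(ss)


class NeuronGroup(NetworkObject):
    """A homogeneous population; per-neuron state lives as attributes.

    Behaviors create state with :meth:`vector` and read/write it as plain
    attributes (``group.v``, ``group.spikes``, ...).  The afferent/efferent
    registries are filled in by :class:`SynapseGroup` construction.
    """

    def __init__(self, network: "Network", size: int, tags: Iterable[str] = ()):
        if size < 1:
            raise ValueError("neuron group size must be >= 1")
        self.size = int(size)
        self.afferent_synapses: dict[str, list[SynapseGroup]] = {}
        self.efferent_synapses: dict[str, list[SynapseGroup]] = {}
        super().__init__(network, tags=tags)

    def vector(self, init="zeros", *, dtype: str | None = None,
               low: float = 0.0, high: float = 1.0,
               mean: float = 0.0, sd: float = 1.0) -> np.ndarray:
        """Allocate a per-neuron array on the network backend.

        ``init`` is one of ``"zeros"``, ``"uniform"``, ``"normal"`` or a
        numeric constant.
        """
        b = self.network.backend
        dtype = dtype or self.network.dtype
        if init == "zeros":
            return b.zeros(self.size, dtype)
        if init == "uniform":
            return b.uniform(self.rng, self.size, low, high, dtype)
        if init == "normal":
            return b.normal(self.rng, self.size, mean, sd, dtype)
        if isinstance(init, (int, float, np.floating, np.integer)):
            return b.full(self.size, float(init), dtype)
        raise ValueError(f"unknown vector init mode {init!r}")

    def synapses(self, direction: str, tag: str = "all") -> "list[SynapseGroup]":
        """Connected synapse groups: ``direction`` is 'afferent' or 'efferent'."""
        reg = {"afferent": self.afferent_synapses,
               "efferent": self.efferent_synapses}[direction]
        return list(reg.get(tag, ()))

    def subgroup(self, mask) -> "NeuronGroupView":
        return NeuronGroupView(self, mask)


class NeuronGroupView:
    """Masked view onto a parent group's state; writes go through.

    Reading ``view.read(name)`` returns the masked slice of the parent's
    array; ``view.write(name, value)`` assigns into exactly the masked
    positions of the parent.
    """

    def __init__(self, parent: NeuronGroup, mask):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (parent.size,):
            raise ValueError(f"mask length {mask.size} != group size {parent.size}")
        self.parent = parent
        self.mask = mask
        self.indices = np.flatnonzero(mask)
        self.size = int(self.indices.size)

    def read(self, name: str) -> np.ndarray:
        return getattr(self.parent, name)[self.indices]

    def write(self, name: str, value) -> None:
        getattr(self.parent, name)[self.indices] = value


class SynapseGroup(NetworkObject):
    """Dense connection block between a source and a destination group."""

    def __init__(self, network: "Network", src: NeuronGroup, dst: NeuronGroup,
                 tags: Iterable[str] = ()):
        self.src = src
        self.dst = dst
        super().__init__(network, tags=tags)
        for tag in self.tags | {"all"}:
            dst.afferent_synapses.setdefault(tag, []).append(self)
            src.efferent_synapses.setdefault(tag, []).append(self)

    def matrix(self, layout: str = DST_MAJOR, init="zeros", *,
               dtype: str | None = None, scale: float = 1.0) -> WeightMatrix:
        """Allocate the weight matrix for this connection.

        Shape is (dst, src) for ``dst_major`` and (src, dst) for
        ``src_major``; random fills draw from this component's generator in
        the *canonical dst-major element order* and are then laid out, so
        the same seed yields the same logical weights in either layout.
        """
        b = self.network.backend
        dtype = dtype or self.network.dtype
        canonical = (self.dst.size, self.src.size)
        if init == "zeros":
            data = b.zeros(canonical, dtype)
        elif init == "uniform":
            data = b.random01(self.rng, canonical, dtype)
            if scale != 1.0:
                data *= np.asarray(scale, dtype=data.dtype)
        elif isinstance(init, (int, float, np.floating, np.integer)):
            data = b.full(canonical, float(init), dtype)
        else:
            raise ValueError(f"unknown matrix init mode {init!r}")
        W = WeightMatrix(data, DST_MAJOR)
        if layout == SRC_MAJOR:
            from .kernels import transpose_layout
            W = transpose_layout(W)
        return W


@dataclass(frozen=True)
class ScheduleEntry:
    key: int
    component: NetworkObject
    behavior: Behavior


class BehaviorSchedule:
    """Globally ordered execution plan: (key, component, behavior) triples."""

    def __init__(self, entries: list[ScheduleEntry]):
        self.entries = entries

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    @property
    def keys(self) -> list[int]:
        return [e.key for e in self.entries]


class SimulationError(RuntimeError):
    """A behavior hook raised; carries the behavior identity and iteration."""


class Network(NetworkObject):
    """Component container, scheduler, and iteration loop.

    The iteration counter is 0 before any step and is incremented at the
    start of each step, so the first executed step observes
    ``network.iteration == 1`` and interval work gated on
    ``iteration % k == 0`` first fires at step k.
    """

    def __init__(self, seed: int = 0, backend: str = "numpy", dtype: str = "f64",
                 tags: Iterable[str] = ()):
        self.components: list[NetworkObject] = []
        self.neuron_groups: list[NeuronGroup] = []
        self.synapse_groups: list[SynapseGroup] = []
        self.seed = int(seed)
        self.backend = get_backend(backend)
        self.backend_name = backend
        self.dtype = dtype
        self.iteration = 0
        self.initialized = False
        super().__init__(None, tags=tags)
        self._register(self)

    # -- registration ---------------------------------------------------
    def _register(self, component: NetworkObject) -> None:
        component.network = self
        component.registration_index = len(self.components)
        self.components.append(component)
        component._derive_rng(self.seed)
        if isinstance(component, NeuronGroup):
            self.neuron_groups.append(component)
        elif isinstance(component, SynapseGroup):
            self.synapse_groups.append(component)

    # -- scheduling -----------------------------------------------------
    def build_schedule(self) -> BehaviorSchedule:
        """All behaviors of all components, stably sorted by key.

        Key ties across components resolve by component registration order
        (components are collected in registration order and the sort is
        stable), so repeated builds yield the identical schedule.
        """
        entries = [ScheduleEntry(key, comp, beh)
                   for comp in self.components
                   for key, beh in sorted(comp.behaviors.items())]
        entries.sort(key=lambda e: e.key)
        return BehaviorSchedule(entries)

    # -- lifecycle ------------------------------------------------------
    def initialize(self) -> None:
        """Run every behavior's setup hook once, in schedule order."""
        if self.initialized:
            raise RuntimeError("network is already initialized; re-initialization "
                               "would silently reset learned state")
        for e in self.build_schedule():
            try:
                e.behavior.setup(e.component)
            except Exception as exc:
                raise SimulationError(
                    f"setup failed in behavior {e.behavior.unique_name} "
                    f"(key {e.key} on {e.component.unique_name}): {exc}") from exc
        self.iteration = 0
        self.initialized = True

    def simulate_iterations(self, n: int) -> None:
        """Advance the simulation by ``n`` steps."""
        if not self.initialized:
            raise RuntimeError("call initialize() before simulate_iterations()")
        schedule = self.build_schedule()
        for _ in range(int(n)):
            self.iteration += 1
            for e in schedule:
                try:
                    e.behavior.step(e.component)
                except Exception as exc:
                    raise SimulationError(
                        f"step failed at iteration {self.iteration} in behavior "
                        f"{e.behavior.unique_name} (key {e.key} on "
                        f"{e.component.unique_name}): {exc}") from exc

    # -- lookup ---------------------------------------------------------
    def find_by_tag(self, tag: str) -> list[TaggableObject]:
        """Every component and behavior carrying ``tag``, registration order."""
        found: list[TaggableObject] = []
        for comp in self.components:
            if comp.has_tag(tag):
                found.append(comp)
            for _, beh in sorted(comp.behaviors.items()):
                if beh.has_tag(tag):
                    found.append(beh)
        return found

    def recorders(self) -> "list[Recorder]":
        return [b for c in self.components for b in c.behaviors.values()
                if isinstance(b, Recorder)]


class Recorder(Behavior):
    """Snapshot a component state variable every ``cadence`` iterations.

    Snapshots stay on the network backend; :meth:`flush` copies them to host
    memory (and clears the buffer) for export.  After T iterations at
    cadence k the buffer holds floor(T/k) snapshots.
    """

    def __init__(self, variable: str, cadence: int = 1, transform: Callable | None = None,
                 tags: Iterable[str] = ()):
        if cadence < 1:
            raise ValueError("cadence must be >= 1")
        super().__init__(tags=set(tags) | {"recorder"},
                         variable=variable, cadence=int(cadence))
        self.variable = variable
        self.cadence = int(cadence)
        self.transform = transform
        self.buffer: list[Any] = []

    def setup(self, component: NetworkObject) -> None:
        self.buffer = []

    def step(self, component: NetworkObject) -> None:
        if component.network.iteration % self.cadence != 0:
            return
        value = getattr(component, self.variable)
        if self.transform is not None:
            value = self.transform(value)
        if isinstance(value, SpikeVector):
            value = value.values.copy()
        elif isinstance(value, np.ndarray):
            value = value.copy()
        self.buffer.append(value)

    def flush(self) -> list[Any]:
        """Move the buffered snapshots to the host and clear the buffer."""
        b = self.owner.network.backend
        out = [b.to_host(v) if isinstance(v, np.ndarray) else v for v in self.buffer]
        self.buffer = []
        return out


class SpikeRasterRecorder(Behavior):
    """Collect (iteration, neuron index) pairs of every emitted spike."""

    def __init__(self, variable: str = "spikes", tags: Iterable[str] = ()):
        super().__init__(tags=set(tags) | {"recorder", "raster"}, variable=variable)
        self.variable = variable
        self.rows: list[tuple[int, int]] = []

    def setup(self, component: NetworkObject) -> None:
        self.rows = []

    def step(self, component: NetworkObject) -> None:
        spikes: SpikeVector = getattr(component, self.variable)
        it = component.network.iteration
        self.rows.extend((it, int(i)) for i in spikes.active)

    def as_array(self) -> np.ndarray:
        """(n_spikes, 2) array of [iteration, neuron_index] rows."""
        if not self.rows:
            return np.empty((0, 2), dtype=np.int64)
        return np.asarray(self.rows, dtype=np.int64)
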