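"""Vectorized synaptic kernels and their naive oracles.

Spiking networks exchange binary events, so the dense linear-algebra idioms
used for rate models waste most of their work multiplying by zero.  This
module implements both forms of every operation:

* the *naive* form — the textbook matrix-vector product, full outer-product
  plasticity update, whole-matrix clipping — which serves as the oracle, and
* the *optimized* form — gathering only the rows/columns of active neurons
  and updating only the index mesh (cross product of active pre- and
  post-synaptic indices).

The naive oracles accumulate in strict ascending source order.  Adding an
exact zero is a floating-point identity, so the optimized gathers (which sum
the same nonzero terms in the same order) produce bit-identical results in
every dtype whenever their reduction is itself sequential; see
docs/methods.md for the one pairwise-summation caveat (dst-major gathers
with more than 8 active sources).

Weight matrices carry a layout tag: ``dst_major`` stores the incoming
weights of one destination neuron in one row (shape D x S, the conventional
orientation), ``src_major`` stores the outgoing weights of one source neuron
in one row (shape S x D).  With row-major storage the src-major layout makes
the active-source gather touch contiguous memory, which is where most of the
transmission speed-up comes from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .backend import DTYPE_BYTES, NumpyBackend, dtype_of, tag_of

_default_backend = NumpyBackend()

DST_MAJOR = "dst_major"
SRC_MAJOR = "src_major"
_LAYOUTS = (DST_MAJOR, SRC_MAJOR)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

class SpikeVector:
    """Boolean firing state of one neuron group for one time step.

    The ascending index list of active neurons is built lazily and cached;
    the underlying array is frozen (non-writeable) so the cache can never go
    stale.  Replace the contents with :meth:`replace`.
    """

    __slots__ = ("_values", "_active")

    def __init__(self, values):
        values = np.asarray(values, dtype=bool)
        values.setflags(write=False)
        self._values = values
        self._active = None

    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def active(self) -> np.ndarray:
        """Ascending indices of the neurons that fired."""
        if self._active is None:
            self._active = np.flatnonzero(self._values)
        return self._active

    def replace(self, values) -> None:
        values = np.asarray(values, dtype=bool)
        if values.shape != self._values.shape:
            raise ValueError("spike vector length is fixed")
        values = values.copy()
        values.setflags(write=False)
        self._values = values
        self._active = None

    def count(self) -> int:
        return int(self.active.size)

    def __len__(self) -> int:
        return self._values.size

    @classmethod
    def empty(cls, n: int) -> "SpikeVector":
        return cls(np.zeros(n, dtype=bool))


class WeightMatrix:
    """Dense 2-D synaptic weights with layout and precision tags.

    ``W[d, s]`` semantics are layout-independent: ``get(d, s)`` reads the
    weight from source neuron *s* onto destination neuron *d* regardless of
    how the data is physically stored.
    """

    __slots__ = ("data", "layout")

    def __init__(self, data: np.ndarray, layout: str):
        if layout not in _LAYOUTS:
            raise ValueError(f"layout must be one of {_LAYOUTS}, got {layout!r}")
        data = np.ascontiguousarray(data)
        if data.ndim != 2:
            raise ValueError("weight matrix must be 2-D")
        self.data = data
        self.layout = layout

    @property
    def src_size(self) -> int:
        return self.data.shape[1] if self.layout == DST_MAJOR else self.data.shape[0]

    @property
    def dst_size(self) -> int:
        return self.data.shape[0] if self.layout == DST_MAJOR else self.data.shape[1]

    @property
    def dtype_tag(self) -> str:
        return tag_of(self.data.dtype)

    def get(self, d: int, s: int) -> float:
        return self.data[d, s] if self.layout == DST_MAJOR else self.data[s, d]

    def as_dst_major_array(self) -> np.ndarray:
        """The weights as a D x S array (copy if stored src-major)."""
        return self.data if self.layout == DST_MAJOR else np.ascontiguousarray(self.data.T)

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(self.data.copy(), self.layout)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (f"WeightMatrix(S={self.src_size}, D={self.dst_size}, "
                f"layout={self.layout}, dtype={self.dtype_tag})")


@dataclass(frozen=True)
class IndexMesh:
    """Rectangular index set rows x cols addressing a submatrix.

    Built from the active indices of a post- and pre-synaptic spike vector;
    because spike vectors are boolean, every (row, col) pair occurs at most
    once, so fancy-indexed ``+=`` never hits the repeated-index accumulation
    ambiguity.
    """

    rows: np.ndarray
    cols: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rows", np.asarray(self.rows, dtype=np.intp))
        object.__setattr__(self, "cols", np.asarray(self.cols, dtype=np.intp))

    @property
    def size(self) -> int:
        return int(self.rows.size * self.cols.size)

    def check_bounds(self, shape) -> None:
        if self.rows.size and (self.rows.min() < 0 or self.rows.max() >= shape[0]):
            raise IndexError("mesh row index out of range")
        if self.cols.size and (self.cols.min() < 0 or self.cols.max() >= shape[1]):
            raise IndexError("mesh column index out of range")


class SpikeHistory:
    """Ring buffer of the last ``depth`` spike vectors of one group.

    ``history[0]`` is the current step, ``history[k]`` the vector from k
    steps ago.  Push order is oldest-evicted-first.
    """

    def __init__(self, depth: int):
        if depth < 1:
            raise ValueError("history depth must be >= 1")
        self.depth = depth
        self._slots: list[SpikeVector] = []

    def push(self, spikes: SpikeVector) -> None:
        self._slots.insert(0, spikes)
        del self._slots[self.depth:]

    def __getitem__(self, lag: int) -> SpikeVector:
        if not 0 <= lag < len(self._slots):
            raise IndexError(f"no spike vector recorded at lag {lag} "
                             f"(have {len(self._slots)} of depth {self.depth})")
        return self._slots[lag]

    def __len__(self) -> int:
        return len(self._slots)


# ---------------------------------------------------------------------------
# synaptic transmission
# ---------------------------------------------------------------------------

def _check_src(W: WeightMatrix, src: SpikeVector) -> None:
    if len(src) != W.src_size:
        raise ValueError(f"source spike vector length {len(src)} != src size {W.src_size}")


def synaptic_input_product(W: WeightMatrix, src: SpikeVector) -> np.ndarray:
    """Naive transmission: full matrix-vector product over all sources.

    out[d] = sum_s W[d, s] * src[s], accumulated in strict ascending source
    order so the result is a deterministic reference for the indexed kernel.
    Performs D multiplications for every source neuron, active or not.
    """
    _check_src(W, src)
    x = src.values.astype(W.data.dtype)
    out = np.zeros(W.dst_size, dtype=W.data.dtype)
    if W.layout == DST_MAJOR:
        for s in range(W.src_size):
            out += W.data[:, s] * x[s]
    else:
        for s in range(W.src_size):
            out += W.data[s] * x[s]
    return out


def synaptic_input_indexed(W: WeightMatrix, src: SpikeVector,
                           backend=_default_backend) -> np.ndarray:
    """Optimized transmission: gather active source rows/columns and sum.

    Skips every multiplication — spikes are binary, so the contribution of
    an active source is just its weight row.  With the src-major layout the
    gathered rows are contiguous in memory.
    """
    _check_src(W, src)
    if W.layout == SRC_MAJOR:
        return backend.gather_rows_sum(W.data, src.active)
    return backend.gather_cols_sum(W.data, src.active)


def transpose_layout(W: WeightMatrix) -> WeightMatrix:
    """Flip the storage layout, physically transposing into contiguous order."""
    flipped = SRC_MAJOR if W.layout == DST_MAJOR else DST_MAJOR
    return WeightMatrix(np.ascontiguousarray(W.data.T), flipped)


# ---------------------------------------------------------------------------
# plasticity
# ---------------------------------------------------------------------------

def _check_pair(W: WeightMatrix, pre: SpikeVector, post: SpikeVector) -> None:
    if len(pre) != W.src_size:
        raise ValueError(f"pre vector length {len(pre)} != src size {W.src_size}")
    if len(post) != W.dst_size:
        raise ValueError(f"post vector length {len(post)} != dst size {W.dst_size}")


def stdp_outer(W: WeightMatrix, pre: SpikeVector, post: SpikeVector, lr: float) -> None:
    """Naive Hebbian update: add lr times the full outer product (in place).

    Multiplies every (d, s) pair even though almost all products are zero in
    a sparsely firing network; the oracle for :func:`stdp_mesh`.
    """
    _check_pair(W, pre, post)
    dt = W.data.dtype
    pre_f = pre.values.astype(dt)
    post_f = post.values.astype(dt)
    if W.layout == DST_MAJOR:
        W.data += dt.type(lr) * (post_f[:, None] * pre_f[None, :])
    else:
        W.data += dt.type(lr) * (pre_f[:, None] * post_f[None, :])


def mesh_from_spikes(pre: SpikeVector, post: SpikeVector,
                     layout: str = DST_MAJOR) -> IndexMesh:
    """Index mesh of the weight entries that a pre/post coincidence touches."""
    if layout == DST_MAJOR:
        return IndexMesh(rows=post.active, cols=pre.active)
    if layout == SRC_MAJOR:
        return IndexMesh(rows=pre.active, cols=post.active)
    raise ValueError(f"unknown layout {layout!r}")


def stdp_mesh(W: WeightMatrix, mesh: IndexMesh, lr: float,
              backend=_default_backend) -> None:
    """Optimized Hebbian update: increment only the mesh-addressed entries.

    Bit-identical to :func:`stdp_outer` on the spike vectors the mesh was
    built from — both add exactly ``lr`` to exactly the coincident entries.
    """
    mesh.check_bounds(W.data.shape)
    backend.mesh_add(W.data, mesh.rows, mesh.cols, lr)


def clip_mesh(W: WeightMatrix, mesh: IndexMesh, w_min: float, w_max: float,
              backend=_default_backend) -> None:
    """Clamp only the mesh entries into [w_min, w_max]; the rest untouched."""
    if w_min > w_max:
        raise ValueError(f"w_min {w_min} > w_max {w_max}")
    mesh.check_bounds(W.data.shape)
    backend.mesh_clip(W.data, mesh.rows, mesh.cols, w_min, w_max)


def clip_full(W: WeightMatrix, w_min: float, w_max: float,
              backend=_default_backend) -> None:
    """Naive counterpart: clamp every weight, modified or not."""
    if w_min > w_max:
        raise ValueError(f"w_min {w_min} > w_max {w_max}")
    backend.clip(W.data, w_min, w_max)


def normalize_afferent(W: WeightMatrix, target: float = 1.0) -> None:
    """Scale each destination neuron's incoming weights to sum to ``target``.

    Rows (dst-major) or columns (src-major) whose sum is zero are left
    untouched — dividing them would be 0/0.
    """
    axis = 1 if W.layout == DST_MAJOR else 0
    sums = W.data.sum(axis=axis)
    factors = np.where(sums != 0, sums / W.data.dtype.type(target), 1.0).astype(W.data.dtype)
    if W.layout == DST_MAJOR:
        W.data /= factors[:, None]
    else:
        W.data /= factors[None, :]


def normalize_efferent(W: WeightMatrix, target: float = 1.0) -> None:
    """Scale each source neuron's outgoing weights to sum to ``target``."""
    axis = 0 if W.layout == DST_MAJOR else 1
    sums = W.data.sum(axis=axis)
    factors = np.where(sums != 0, sums / W.data.dtype.type(target), 1.0).astype(W.data.dtype)
    if W.layout == DST_MAJOR:
        W.data /= factors[None, :]
    else:
        W.data /= factors[:, None]


def default_multi_lag_amplitudes(lr: float, n_lags: int = 4,
                                 tau_lag: float = 3.0) -> dict[int, float]:
    """Antisymmetric discrete exponential STDP window over +-n_lags steps.

    Positive lags (pre ``lag`` steps before post) potentiate, negative lags
    depress, amplitude lr * exp(-|lag| / tau_lag); the coincidence lag 0 is
    neutral.  Nine entries for the default n_lags=4.
    """
    amps: dict[int, float] = {0: 0.0}
    for lag in range(1, n_lags + 1):
        a = lr * float(np.exp(-lag / tau_lag))
        amps[lag] = a
        amps[-lag] = -a
    return amps


def stdp_multi_lag(W: WeightMatrix, pre_hist: SpikeHistory, post_hist: SpikeHistory,
                   amplitudes: Mapping[int, float], backend=_default_backend) -> None:
    """Multi-lag STDP: one mesh update per lag of the plasticity window.

    For lag l > 0 with amplitude a_l the pre spikes from l steps ago are
    paired with the current post spikes (pre-before-post); for l < 0 the
    current pre spikes are paired with the post spikes from |l| steps ago.
    """
    need = max((abs(l) for l in amplitudes), default=0) + 1
    if len(pre_hist) < need or len(post_hist) < need:
        raise ValueError(f"multi-lag window needs {need} history steps, "
                         f"have pre={len(pre_hist)}, post={len(post_hist)}")
    for lag in sorted(amplitudes):
        a = amplitudes[lag]
        if a == 0.0:
            continue
        pre = pre_hist[lag] if lag >= 0 else pre_hist[0]
        post = post_hist[0] if lag >= 0 else post_hist[-lag]
        mesh = mesh_from_spikes(pre, post, W.layout)
        stdp_mesh(W, mesh, a, backend=backend)


# ---------------------------------------------------------------------------
# sparse fallback
# ---------------------------------------------------------------------------

class SparseWeights:
    """Row-compressed sparse weights, fixed to src-major orientation.

    CSR with source-neuron rows keeps the active-source row gather
    contiguous per row — the same rationale as the dense src-major layout.
    Useful below roughly one percent connectivity, mainly for memory.
    """

    def __init__(self, matrix: sp.csr_matrix):
        self.matrix = sp.csr_matrix(matrix)
        self.matrix.sum_duplicates()

    @classmethod
    def from_weight_matrix(cls, W: WeightMatrix) -> "SparseWeights":
        data = W.data if W.layout == SRC_MAJOR else W.data.T
        return cls(sp.csr_matrix(data))

    @classmethod
    def random(cls, src_size: int, dst_size: int, density: float, rng,
               dtype: str = "f64") -> "SparseWeights":
        m = sp.random(src_size, dst_size, density=density, format="csr",
                      dtype=dtype_of(dtype), random_state=rng)
        return cls(m)

    @property
    def src_size(self) -> int:
        return self.matrix.shape[0]

    @property
    def dst_size(self) -> int:
        return self.matrix.shape[1]

    @property
    def density(self) -> float:
        return self.matrix.nnz / (self.matrix.shape[0] * self.matrix.shape[1])

    def to_dense(self) -> WeightMatrix:
        return WeightMatrix(np.asarray(self.matrix.todense()), SRC_MAJOR)


def sparse_synaptic_input(Wsp: SparseWeights, src: SpikeVector) -> np.ndarray:
    """Transmission through sparse weights: sum the active source rows.

    Accumulates row by row in ascending source order, matching the dense
    indexed kernel bit-for-bit on the densified matrix (stored entries only;
    absent entries are exact zeros).
    """
    if len(src) != Wsp.src_size:
        raise ValueError(f"source spike vector length {len(src)} != src size {Wsp.src_size}")
    m = Wsp.matrix
    out = np.zeros(Wsp.dst_size, dtype=m.dtype)
    indptr, indices, data = m.indptr, m.indices, m.data
    for r in src.active:
        lo, hi = indptr[r], indptr[r + 1]
        out[indices[lo:hi]] += data[lo:hi]
    return out


# ---------------------------------------------------------------------------
# precision and storage accounting
# ---------------------------------------------------------------------------

def cast_precision(W: WeightMatrix, dtype: str) -> WeightMatrix:
    """Return a copy of ``W`` cast to the given precision tag."""
    return WeightMatrix(W.data.astype(dtype_of(dtype)), W.layout)


def nominal_bytes(W: WeightMatrix) -> int:
    """Element count times bytes-per-element of the precision tag."""
    return int(W.data.size) * DTYPE_BYTES[W.dtype_tag]


def outer_update_multiplications(dst_size: int, src_size: int) -> int:
    """Scalar multiplications the naive outer-product update performs."""
    return int(dst_size) * int(src_size)


def count_outer_multiplications_instrumented(pre: SpikeVector, post: SpikeVector) -> int:
    """Counting oracle: walk the naive outer product's broadcast index space.

    Enumerates the (d, s) pairs the dense outer product multiplies —
    independent of spike content, every pair is touched once.
    """
    b = np.broadcast(post.values[:, None], pre.values[None, :])
    return int(b.size)
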