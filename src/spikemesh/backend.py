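"""Array-backend facade.

All numerical modules go through a :class:`Backend` instance instead of
calling an array library directly, so the simulation core stays agnostic of
where tensors live.  The package ships a NumPy CPU backend; accelerated
backends (GPU tensor libraries) can be registered at runtime through
:func:`register_backend` as long as they honour the same contract:

* allocation and seeded random fills,
* boolean-mask and integer-mesh indexing,
* axis sums, clipping, elementwise arithmetic, dtype casts,
* a ``synchronize`` barrier that completes queued device work (a no-op on
  CPU) so timing measurements are honest.
"""

from __future__ import annotations

import numpy as np

#: canonical precision tags -> numpy dtypes
DTYPES = {"f64": np.float64, "f32": np.float32, "f16": np.float16}
#: bytes per element for each precision tag
DTYPE_BYTES = {"f64": 8, "f32": 4, "f16": 2}


def dtype_of(tag: str) -> np.dtype:
    """Resolve a precision tag (``f64``/``f32``/``f16``) to a dtype."""
    try:
        return np.dtype(DTYPES[tag])
    except KeyError:
        raise ValueError(f"unsupported dtype tag {tag!r}; expected one of {sorted(DTYPES)}") from None


def tag_of(dtype) -> str:
    dtype = np.dtype(dtype)
    for tag, dt in DTYPES.items():
        if np.dtype(dt) == dtype:
            return tag
    raise ValueError(f"no precision tag for dtype {dtype}")


class NumpyBackend:
    """CPU reference backend built on NumPy.

    Arrays are plain :class:`numpy.ndarray`; ``synchronize`` is a no-op
    because NumPy executes eagerly on the host.
    """

    name = "numpy"

    # -- allocation -----------------------------------------------------
    def zeros(self, shape, dtype="f64"):
        return np.zeros(shape, dtype=dtype_of(dtype))

    def full(self, shape, value, dtype="f64"):
        return np.full(shape, value, dtype=dtype_of(dtype))

    def uniform(self, rng, shape, low=0.0, high=1.0, dtype="f64"):
        return rng.uniform(low, high, size=shape).astype(dtype_of(dtype), copy=False)

    def normal(self, rng, shape, mean=0.0, sd=1.0, dtype="f64"):
        return rng.normal(mean, sd, size=shape).astype(dtype_of(dtype), copy=False)

    def random01(self, rng, shape, dtype="f64"):
        """Uniform [0, 1) fill, generated in f64 then cast to the target tag."""
        return rng.random(shape).astype(dtype_of(dtype), copy=False)

    # -- indexing and reduction -----------------------------------------
    def flatnonzero(self, mask):
        return np.flatnonzero(mask)

    def gather_rows_sum(self, data, rows):
        """Sum of the selected rows (axis 0); sequential over rows."""
        if len(rows) == 0:
            return np.zeros(data.shape[1], dtype=data.dtype)
        return data[rows].sum(axis=0)

    def gather_cols_sum(self, data, cols):
        """Sum of the selected columns (axis 1)."""
        if len(cols) == 0:
            return np.zeros(data.shape[0], dtype=data.dtype)
        return data[:, cols].sum(axis=1)

    def mesh_add(self, data, rows, cols, value):
        data[np.ix_(rows, cols)] += data.dtype.type(value)

    def mesh_clip(self, data, rows, cols, lo, hi):
        mesh = np.ix_(rows, cols)
        data[mesh] = np.clip(data[mesh], lo, hi)

    def clip(self, data, lo, hi):
        np.clip(data, lo, hi, out=data)

    # -- misc -----------------------------------------------------------
    def cast(self, data, dtype):
        return data.astype(dtype_of(dtype))

    def ascontiguous(self, data):
        return np.ascontiguousarray(data)

    def to_host(self, data):
        return np.asarray(data)

    def synchronize(self):  # CPU: nothing queued
        pass


_BACKENDS = {"numpy": NumpyBackend}


def register_backend(name: str, cls) -> None:
    """Register an alternative backend implementation under ``name``."""
    _BACKENDS[name] = cls


def get_backend(name: str = "numpy"):
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise ValueError(f"unknown backend {name!r}; registered: {sorted(_BACKENDS)}") from None
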