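"""Seeded random fixtures: spike vectors and weight matrices.

These generate the standard micro-benchmark inputs — binary spike vectors
with a given firing probability and dense random weight matrices — under an
explicit seed or generator, so every experiment is reproducible.
"""

from __future__ import annotations

import numpy as np

from .backend import dtype_of
from .kernels import DST_MAJOR, SpikeVector, WeightMatrix


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_spike_vector(n: int, p: float, seed=0) -> SpikeVector:
    """Spike vector of length ``n``: each neuron fires with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"spike probability must be in [0, 1], got {p}")
    rng = _as_rng(seed)
    return SpikeVector(rng.random(n) < p)


def gen_weight_matrix(shape, distribution: str = "uniform01", dtype: str = "f64",
                      seed=0, layout: str = DST_MAJOR, value: float = 0.0) -> WeightMatrix:
    """Dense weight matrix with a seeded fill.

    ``distribution`` is ``uniform01`` (entries in [0, 1)), ``zeros``, or
    ``value`` (constant fill of ``value``).
    """
    rng = _as_rng(seed)
    dt = dtype_of(dtype)
    if distribution == "uniform01":
        data = rng.random(shape).astype(dt, copy=False)
    elif distribution == "zeros":
        data = np.zeros(shape, dtype=dt)
    elif distribution == "value":
        data = np.full(shape, value, dtype=dt)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return WeightMatrix(data, layout)
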