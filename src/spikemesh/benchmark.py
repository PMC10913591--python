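"""Timing and validation harness.

Micro-benchmarks single kernels (repeated timed runs after warmup), runs
whole-model naive-vs-optimized grids, derives speed-up ratio tables, and
sweeps the kernel pairs against their naive oracles to certify numerical
equivalence.  Absolute wall-clock numbers are hardware-dependent and are
reported, never asserted; the one portable claim — the optimized pipeline
is strictly faster than the naive one — is checked by the test suite.
"""

from __future__ import annotations

import statistics
import time
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .backend import get_backend
from .fixtures import gen_spike_vector, gen_weight_matrix
from .kernels import (DST_MAJOR, SRC_MAJOR, SparseWeights, SpikeHistory,
                      WeightMatrix, default_multi_lag_amplitudes,
                      mesh_from_spikes, sparse_synaptic_input, stdp_mesh,
                      stdp_multi_lag, stdp_outer, synaptic_input_indexed,
                      synaptic_input_product)
from .models import build_reference_model, mean_firing_fraction, raster_of


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------

@dataclass
class TimingRecord:
    """Raw repeated-run durations of one operation plus summary statistics."""

    label: str
    durations: list[float]
    warmup: int

    @property
    def reps(self) -> int:
        return len(self.durations)

    @property
    def mean(self) -> float:
        return statistics.fmean(self.durations)

    @property
    def median(self) -> float:
        return statistics.median(self.durations)

    @property
    def std(self) -> float:
        return statistics.pstdev(self.durations) if len(self.durations) > 1 else 0.0

    @property
    def min(self) -> float:
        return min(self.durations)


def time_op(op: Callable[[], object], reps: int = 1000, warmup: int = 10,
            label: str = "op", backend=None) -> TimingRecord:
    """Time ``op`` over ``reps`` runs after ``warmup`` untimed runs.

    The backend's ``synchronize`` barrier runs before each clock stop so
    queued device work cannot leak out of the measured window.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    backend = backend or get_backend("numpy")
    try:
        for _ in range(warmup):
            op()
        backend.synchronize()
        durations = []
        for _ in range(reps):
            t0 = time.perf_counter()
            op()
            backend.synchronize()
            durations.append(time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"timed operation {label!r} raised: {exc}") from exc
    return TimingRecord(label=label, durations=durations, warmup=warmup)


# ---------------------------------------------------------------------------
# whole-model grid
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkGrid:
    """Cross product of model variants to run: the grid of the experiment.

    Defaults mirror the study conditions: 300 time steps, 10 replicates.
    Replicate r uses seed master_seed + r in every cell, so the same
    replicate index is statistically comparable across cells.
    """

    model_kinds: Sequence[str] = ("lif_onestep",)
    implementations: Sequence[str] = ("naive", "optimized")
    sizes: Sequence[int] = (10000,)
    dtypes: Sequence[str] | None = None   # None -> naive f64, optimized f32
    backends: Sequence[str] = ("numpy",)
    steps: int = 300
    replicates: int = 10
    master_seed: int = 0

    def cell_dtypes(self, implementation: str) -> Sequence[str]:
        if self.dtypes is not None:
            return self.dtypes
        return ("f64",) if implementation == "naive" else ("f32",)


RESULT_COLUMNS = ["model", "implementation", "N", "dtype", "backend",
                  "replicate", "steps", "total_seconds",
                  "mean_firing_fraction", "status"]


def run_cell(kind: str, implementation: str, n: int, dtype: str, backend: str,
             steps: int, seed: int) -> tuple[float, float]:
    """Build, run and time one model instance; returns (seconds, mean rate)."""
    net = build_reference_model(kind, n, seed=seed, implementation=implementation,
                                dtype=dtype, backend=backend, record_raster=False)
    t0 = time.perf_counter()
    net.simulate_iterations(steps)
    net.backend.synchronize()
    elapsed = time.perf_counter() - t0
    return elapsed, mean_firing_fraction(net)


def run_grid(grid: BenchmarkGrid) -> pd.DataFrame:
    """One row per grid cell and replicate; failed cells are data, not crashes."""
    rows = []
    for kind in grid.model_kinds:
        for impl in grid.implementations:
            for n in grid.sizes:
                for dtype in grid.cell_dtypes(impl):
                    for backend in grid.backends:
                        for r in range(grid.replicates):
                            seed = grid.master_seed + r
                            try:
                                secs, rate = run_cell(kind, impl, n, dtype,
                                                      backend, grid.steps, seed)
                                rows.append([kind, impl, n, dtype, backend, r,
                                             grid.steps, secs, rate, "ok"])
                            except MemoryError:
                                rows.append([kind, impl, n, dtype, backend, r,
                                             grid.steps, np.nan, np.nan, "failed"])
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def speedup_table(results: pd.DataFrame) -> pd.DataFrame:
    """Mean time per cell and its ratio to the slowest cell (slowest = 1.0)."""
    ok = results[results["status"] == "ok"]
    if ok.empty:
        raise ValueError("no successful cells to tabulate")
    cells = (ok.groupby(["model", "implementation", "N", "dtype", "backend"],
                        as_index=False)
               .agg(mean_seconds=("total_seconds", "mean")))
    if cells["implementation"].nunique() < 2:
        raise ValueError("speedup table needs at least two implementations")
    slowest = cells["mean_seconds"].max()
    cells["speedup"] = slowest / cells["mean_seconds"]
    return cells.sort_values("speedup").reset_index(drop=True)


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

@dataclass
class EquivalenceReport:
    """Difference summary of one optimized-kernel-vs-oracle sweep."""

    label: str
    trials: int
    max_abs_diff: float
    max_rel_diff: float

    @property
    def exact(self) -> bool:
        return self.max_abs_diff == 0.0


def _diffs(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    abs_diff = np.abs(a - b)
    scale = np.maximum(np.abs(a), np.abs(b))
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(scale > 0, abs_diff / scale, 0.0)
    return float(abs_diff.max(initial=0.0)), float(rel.max(initial=0.0))


def verify_equivalence(trials: int = 1000, size_cap: int = 200,
                       spike_rate: float = 0.01, seed: int = 0) -> list[EquivalenceReport]:
    """Sweep every optimized kernel against its naive oracle.

    Random instances with sizes up to ``size_cap`` and the given firing
    probability; reports max absolute/relative differences per kernel pair.
    Expected outcome: exact matches everywhere except the f32 transmission
    pair, which agrees to ~1e-7 relative.
    """
    rng = np.random.default_rng(seed)
    pairs = {
        "input_product_vs_indexed_f64": [],
        "input_product_vs_indexed_f32": [],
        "stdp_outer_vs_mesh_f64": [],
        "stdp_outer_vs_mesh_f32": [],
        "stdp_multilag_vs_sequential_f64": [],
        "sparse_vs_dense_indexed_f64": [],
    }
    for _ in range(trials):
        S = int(rng.integers(1, size_cap + 1))
        D = int(rng.integers(1, size_cap + 1))
        src = gen_spike_vector(S, spike_rate, rng)
        dst = gen_spike_vector(D, spike_rate, rng)
        # transmission: src-major so both reductions are sequential
        W64 = gen_weight_matrix((S, D), "uniform01", "f64", rng, layout=SRC_MAJOR)
        pairs["input_product_vs_indexed_f64"].append(
            _diffs(synaptic_input_product(W64, src), synaptic_input_indexed(W64, src)))
        W32 = WeightMatrix(W64.data.astype(np.float32), SRC_MAJOR)
        pairs["input_product_vs_indexed_f32"].append(
            _diffs(synaptic_input_product(W32, src), synaptic_input_indexed(W32, src)))
        # plasticity: outer vs mesh, bit identity expected in any dtype
        for tag, store in (("f64", "stdp_outer_vs_mesh_f64"),
                           ("f32", "stdp_outer_vs_mesh_f32")):
            Wa = WeightMatrix(W64.data.astype(np.float64 if tag == "f64" else np.float32),
                              SRC_MAJOR)
            Wb = Wa.copy()
            stdp_outer(Wa, src, dst, 0.1)
            stdp_mesh(Wb, mesh_from_spikes(src, dst, SRC_MAJOR), 0.1)
            pairs[store].append(_diffs(Wa.data, Wb.data))
        # multi-lag vs sequential outer applications
        depth = 5
        pre_hist, post_hist = SpikeHistory(depth), SpikeHistory(depth)
        for _ in range(depth):
            pre_hist.push(gen_spike_vector(S, spike_rate, rng))
            post_hist.push(gen_spike_vector(D, spike_rate, rng))
        amps = default_multi_lag_amplitudes(0.05)
        Wa = W64.copy()
        Wb = W64.copy()
        stdp_multi_lag(Wa, pre_hist, post_hist, amps)
        for lag in sorted(amps):
            if amps[lag] == 0.0:
                continue
            pre = pre_hist[lag] if lag >= 0 else pre_hist[0]
            post = post_hist[0] if lag >= 0 else post_hist[-lag]
            stdp_outer(Wb, pre, post, amps[lag])
        pairs["stdp_multilag_vs_sequential_f64"].append(_diffs(Wa.data, Wb.data))
        # sparse vs densified indexed
        density = float(rng.choice([0.001, 0.01, 0.1]))
        Wsp = SparseWeights.random(S, D, density, rng)
        pairs["sparse_vs_dense_indexed_f64"].append(
            _diffs(sparse_synaptic_input(Wsp, src),
                   synaptic_input_indexed(Wsp.to_dense(), src)))
    return [EquivalenceReport(label=k, trials=trials,
                              max_abs_diff=max(d[0] for d in v),
                              max_rel_diff=max(d[1] for d in v))
            for k, v in pairs.items()]


def rasters_identical(kind: str = "lif_onestep", n: int = 1000, steps: int = 300,
                      seed: int = 0) -> bool:
    """Do the naive and optimized variants emit the same spikes? (f64)."""
    nets = [build_reference_model(kind, n, seed=seed, implementation=impl, dtype="f64")
            for impl in ("naive", "optimized")]
    for net in nets:
        net.simulate_iterations(steps)
    a, b = (raster_of(net) for net in nets)
    return a.shape == b.shape and bool(np.array_equal(a, b))
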