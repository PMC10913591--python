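"""File output: spike rasters, recorder exports, weight snapshots.

All writers go through an atomic write-then-rename, so an interrupted run
never leaves a truncated file behind.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .backend import dtype_of
from .kernels import WeightMatrix

RASTER_HEADER = "iteration,neuron_group,neuron_index"
RASTER_COMMENT = ("# spike raster: 0-based neuron indices; "
                  "iterations are 1-based (first simulated step = 1)\n")


@contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a temp file in the target directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_raster_csv(path: str | Path, raster: np.ndarray, group_name: str) -> None:
    """Raster CSV: one row per spike, header plus a comment line on indexing."""
    raster = np.asarray(raster)
    with atomic_write(path) as fh:
        fh.write(RASTER_COMMENT)
        fh.write(RASTER_HEADER + "\n")
        for it, idx in raster:
            fh.write(f"{int(it)},{group_name},{int(idx)}\n")


def read_raster_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_records_csv(path: str | Path, values, variable: str) -> None:
    """Per-step scalar recorder buffer as a two-column CSV."""
    with atomic_write(path) as fh:
        fh.write(f"snapshot,{variable}\n")
        for i, v in enumerate(values):
            fh.write(f"{i},{float(v)}\n")


def write_records_hdf5(path: str | Path, values, variable: str) -> None:
    """Per-step array recorder buffer as an HDF5 dataset (snapshots stacked)."""
    arr = np.stack([np.asarray(v) for v in values]) if len(values) else np.empty((0,))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(f".{path.name}.tmp")
    with h5py.File(tmp, "w") as f:
        f.create_dataset(variable, data=arr)
    os.replace(tmp, path)


def write_weight_snapshot(path: str | Path, W: WeightMatrix) -> None:
    """HDF5 snapshot with layout/dtype/size attributes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(f".{path.name}.tmp")
    with h5py.File(tmp, "w") as f:
        ds = f.create_dataset("weights", data=W.data)
        ds.attrs["layout"] = W.layout
        ds.attrs["dtype"] = W.dtype_tag
        ds.attrs["src_size"] = W.src_size
        ds.attrs["dst_size"] = W.dst_size
    os.replace(tmp, path)


def read_weight_snapshot(path: str | Path) -> WeightMatrix:
    with h5py.File(path, "r") as f:
        ds = f["weights"]
        W = WeightMatrix(ds[...], ds.attrs["layout"])
    return W


def write_weight_csv(path: str | Path, W: WeightMatrix, max_entries: int = 1_000_000) -> None:
    """Plain-text export for small matrices."""
    if W.data.size > max_entries:
        raise ValueError(f"matrix too large for CSV export ({W.data.size} entries)")
    with atomic_write(path) as fh:
        fh.write(f"# layout={W.layout} dtype={W.dtype_tag} "
                 f"src_size={W.src_size} dst_size={W.dst_size}\n")
        np.savetxt(fh, W.data, delimiter=",")


def write_dataframe_csv(path: str | Path, df: pd.DataFrame) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, index=False)
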