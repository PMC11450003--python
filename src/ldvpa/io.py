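"""File I/O for trace datasets and media.

Two interchangeable on-disk forms for per-position trace collections:

* CSV — column 1 is time in seconds, remaining columns one per scan
  position with the position in metres as the header; lossless to
  ~1e-12 relative precision.
* HDF5 — datasets ``time``, ``positions``, ``traces`` with units, pitch
  and seed as attributes; exact round trip.

Media (sound-speed/density maps) persist to HDF5 with the grid spacing
and boundary specification as attributes.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .reconstruction import ScanDataset
from .wave_engine import Medium, SurfaceRecord

__all__ = [
    "TraceParseError",
    "write_traces",
    "read_traces",
    "write_medium",
    "read_medium",
]


class TraceParseError(ValueError):
    """Malformed trace file (ragged rows, bad header, truncation)."""


def _as_dataset(records) -> ScanDataset:
    if isinstance(records, ScanDataset):
        return records
    if isinstance(records, SurfaceRecord):
        return ScanDataset(
            positions=records.positions,
            time=records.time,
            traces=records.velocity,
            meta=dict(records.meta, kind="surface_velocity"),
        )
    raise TypeError(f"cannot serialise {type(records).__name__} as traces")


def write_traces(path, records, fmt: str | None = None) -> Path:
    """Write a ScanDataset (or a SurfaceRecord's velocity) to CSV or HDF5.

    The format follows ``fmt`` (``"csv"`` or ``"hdf5"``) or, when omitted,
    the file extension.
    """
    path = Path(path)
    ds = _as_dataset(records)
    fmt = fmt or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "csv")
    if fmt == "csv":
        df = pd.DataFrame(
            ds.traces.T, columns=[f"{x:.9e}" for x in ds.positions]
        )
        df.insert(0, "time", ds.time)
        df.to_csv(path, index=False, float_format="%.17e")
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=ds.time)
            f.create_dataset("positions", data=ds.positions)
            f.create_dataset("traces", data=ds.traces)
            f.attrs["units_time"] = "s"
            f.attrs["units_positions"] = "m"
            f.attrs["units_traces"] = str(ds.meta.get("units", "Pa"))
            f.attrs["pitch"] = ds.pitch
            if ds.meta.get("seed") is not None:
                f.attrs["seed"] = int(ds.meta["seed"])
    else:
        raise ValueError(f"unknown trace format {fmt!r}")
    return path


def read_traces(path, fmt: str | None = None) -> ScanDataset:
    """Read traces written by :func:`write_traces`.

    Raises :class:`TraceParseError` (with the offending line where
    known) for ragged or truncated files rather than misreading them.
    """
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "csv")
    if fmt == "csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.ParserError as e:
            raise TraceParseError(f"{path}: {e}") from e
        except pd.errors.EmptyDataError as e:
            raise TraceParseError(f"{path}: empty file") from e
        if df.shape[1] < 2 or df.columns[0] != "time":
            raise TraceParseError(
                f"{path}: expected a 'time' column followed by per-position columns"
            )
        if df.isna().any().any():
            row = int(df.isna().any(axis=1).idxmax()) + 2  # header is line 1
            raise TraceParseError(f"{path}: missing values near line {row}")
        try:
            positions = np.array([float(c) for c in df.columns[1:]])
        except ValueError as e:
            raise TraceParseError(f"{path}: non-numeric position header: {e}") from e
        return ScanDataset(
            positions=positions,
            time=df["time"].to_numpy(),
            traces=df.iloc[:, 1:].to_numpy().T,
        )
    if fmt == "hdf5":
        try:
            with h5py.File(path, "r") as f:
                ds = ScanDataset(
                    positions=f["positions"][...],
                    time=f["time"][...],
                    traces=f["traces"][...],
                    meta={
                        k: (int(v) if k == "seed" else v)
                        for k, v in f.attrs.items()
                    },
                )
        except OSError as e:
            raise TraceParseError(f"{path}: not a readable HDF5 file: {e}") from e
        except KeyError as e:
            raise TraceParseError(f"{path}: missing dataset {e}") from e
        return ds
    raise ValueError(f"unknown trace format {fmt!r}")


def write_medium(path, medium: Medium) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("c_map", data=medium.c_map)
        f.create_dataset("rho_map", data=medium.rho_map)
        f.attrs["dx"] = medium.dx
        f.attrs["x0"] = medium.x0
        f.attrs["n_sponge"] = medium.n_sponge
        for edge, kind in medium.boundary_spec.items():
            f.attrs[f"boundary_{edge}"] = kind
    return path


def read_medium(path) -> Medium:
    with h5py.File(path, "r") as f:
        boundary = {
            k.removeprefix("boundary_"): str(v)
            for k, v in f.attrs.items()
            if k.startswith("boundary_")
        }
        return Medium(
            dx=float(f.attrs["dx"]),
            c_map=f["c_map"][...],
            rho_map=f["rho_map"][...],
            x0=float(f.attrs["x0"]),
            n_sponge=int(f.attrs["n_sponge"]),
            boundary_spec=boundary,
        )
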