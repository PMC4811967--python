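"""Recording container (HDF5) and result-table export.

The acquisition system's proprietary file format is out of scope; recordings
travel in a simple documented HDF5 schema instead:

``/traces``
    float32 dataset, shape ``(n_electrodes, n_samples)``, μV.
root attributes
    ``schema_version`` (int), ``sampling_rate`` (Hz), ``n_rows``, ``n_cols``,
    ``pitch``, ``electrode_size`` (μm), ``stim_sites`` (N x 2 int array,
    may be empty), optional ``roi`` (4 ints).

Result tables are pandas DataFrames exported to CSV or JSON with the column
units recorded in a header so the text files are self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import ArrayGeometry, Recording, SchemaError

__all__ = ["write_recording", "read_recording", "export_results", "read_results"]

SCHEMA_VERSION = 1


def write_recording(recording: Recording, path) -> Path:
    """Write a :class:`Recording` to the HDF5 container. Round-trips bit-exactly."""
    path = Path(path)
    geom = recording.geometry
    with h5py.File(path, "w") as fh:
        fh.create_dataset("traces", data=recording.traces.astype(np.float32))
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["sampling_rate"] = float(recording.sampling_rate)
        fh.attrs["n_rows"] = geom.n_rows
        fh.attrs["n_cols"] = geom.n_cols
        fh.attrs["pitch"] = geom.pitch
        fh.attrs["electrode_size"] = geom.electrode_size
        fh.attrs["stim_sites"] = np.asarray(geom.stim_sites, dtype=np.int64).reshape(
            -1, 2
        )
        if recording.roi is not None:
            fh.attrs["roi"] = np.asarray(recording.roi, dtype=np.int64)
    return path


def read_recording(path) -> Recording:
    """Read the HDF5 container back into a :class:`Recording`.

    Raises :class:`SchemaError` naming the offending field on any missing
    dataset/attribute or invariant violation.
    """
    path = Path(path)
    with h5py.File(path, "r") as fh:
        if "traces" not in fh:
            raise SchemaError("missing dataset 'traces'")
        for attr in ("sampling_rate", "n_rows", "n_cols", "pitch", "electrode_size"):
            if attr not in fh.attrs:
                raise SchemaError(f"missing attribute '{attr}'")
        stim = fh.attrs.get("stim_sites", np.empty((0, 2), dtype=np.int64))
        geom = ArrayGeometry(
            n_rows=int(fh.attrs["n_rows"]),
            n_cols=int(fh.attrs["n_cols"]),
            pitch=float(fh.attrs["pitch"]),
            electrode_size=float(fh.attrs["electrode_size"]),
            stim_sites=tuple(map(tuple, np.asarray(stim).reshape(-1, 2))),
        )
        traces = fh["traces"][()]
        roi = tuple(int(v) for v in fh.attrs["roi"]) if "roi" in fh.attrs else None
        rate = float(fh.attrs["sampling_rate"])
    if traces.ndim != 2:
        raise SchemaError("'traces' is not 2-D")
    if traces.shape[0] != geom.n_electrodes:
        raise SchemaError(
            f"'traces' has {traces.shape[0]} rows for a "
            f"{geom.n_rows}x{geom.n_cols} geometry"
        )
    return Recording(geometry=geom, sampling_rate=rate, traces=traces, roi=roi)


def export_results(table: pd.DataFrame, path, format: str = "csv", units=None) -> Path:
    """Export a result table losslessly with units in a header.

    ``units`` maps column name to unit string; unmapped columns are
    dimensionless.
    """
    path = Path(path)
    units = dict(units or {})
    if format == "csv":
        with open(path, "w") as fh:
            for col in table.columns:
                fh.write(f"# {col}: {units.get(col, '-')}\n")
            table.to_csv(fh, index=False)
    elif format == "json":
        payload = {
            "columns": list(table.columns),
            "units": {c: units.get(c, "-") for c in table.columns},
            "data": table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)
    else:
        raise ValueError(f"unsupported format {format!r} (use 'csv' or 'json')")
    return path


def read_results(path, format: str = "csv") -> pd.DataFrame:
    """Read back a table written by :func:`export_results`."""
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path, comment="#")
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return pd.DataFrame(payload["data"], columns=payload["columns"])
    raise ValueError(f"unsupported format {format!r}")
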