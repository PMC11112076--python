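"""Epoched-data container I/O: HDF5 arrays with a JSON sidecar schema."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from ..epochs import EpochedData

__all__ = ["read_epochs", "write_epochs", "SchemaError"]

_REQUIRED = ("data", "fs", "times", "labels", "units")


class SchemaError(ValueError):
    """A required container field is missing or malformed."""


def write_epochs(data: EpochedData, path: str | Path) -> None:
    """Lossless write of the array, time axis and metadata.

    The sidecar ``<path>.json`` mirrors the shape/units/labels plus the full
    ``meta`` map so the file is inspectable without HDF5 tooling.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data.data)
        f.create_dataset("times", data=data.times)
        f.attrs["fs"] = float(data.fs)
        f.attrs["labels"] = json.dumps(list(data.labels))
        f.attrs["units"] = "uV"
        f.attrs["meta"] = json.dumps(data.meta, default=str)
    sidecar = {
        "shape": list(data.data.shape),
        "axes": ["channels", "samples", "trials"],
        "fs": float(data.fs),
        "units": "uV",
        "labels": list(data.labels),
        "meta": data.meta,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_epochs(path: str | Path) -> EpochedData:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        missing = [k for k in _REQUIRED if k not in f and k not in f.attrs]
        if missing:
            raise SchemaError(f"missing required field(s): {', '.join(missing)}")
        data = f["data"][()]
        times = f["times"][()]
        fs = float(f.attrs["fs"])
        labels = tuple(json.loads(f.attrs["labels"]))
        meta = json.loads(f.attrs.get("meta", "{}"))
    return EpochedData(data, fs, times, labels, meta)


def write_array_with_sidecar(arr: np.ndarray, path: str | Path, **sidecar) -> None:
    """Generic array container (e.g. lead fields) with a JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("array", data=np.asarray(arr))
    sidecar = {"shape": list(np.asarray(arr).shape), **sidecar}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_array(path: str | Path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["array"][()]
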