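"""Field storage: exact HDF5 round trips and 16-bit PNG visualization.

HDF5 keeps full float64 precision.  PNG output is quantized to 16 bits
with the original value range stored in a JSON sidecar so a quantized
inverse read is possible (error bounded by range/65535).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np

__all__ = ["write_field", "read_field", "write_png16", "read_png16",
           "write_trajectory", "read_trajectory"]


def write_field(path, field: np.ndarray, name: str = "field",
                attrs: dict | None = None) -> None:
    """Store one float field in an HDF5 dataset (bit-exact round trip)."""
    field = np.asarray(field, dtype=float)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset(name, data=field)
        for k, v in (attrs or {}).items():
            ds.attrs[k] = v


def read_field(path, name: str = "field") -> np.ndarray:
    with h5py.File(path, "r") as f:
        if name not in f:
            raise KeyError(f"dataset {name!r} not in {path}")
        data = f[name][()]
    if data.ndim != 2:
        raise ValueError(f"expected a 2D field in {path}, got shape {data.shape}")
    return np.asarray(data, dtype=float)


def write_png16(path, field: np.ndarray) -> None:
    """16-bit grayscale PNG plus a JSON sidecar holding (min, max)."""
    field = np.asarray(field, dtype=float)
    lo, hi = float(field.min()), float(field.max())
    scale = (hi - lo) or 1.0
    q = np.round((field - lo) / scale * 65535.0).astype(np.uint16)
    iio.imwrite(path, q)
    Path(str(path) + ".json").write_text(json.dumps({"min": lo, "max": hi}))


def read_png16(path) -> np.ndarray:
    """Inverse of :func:`write_png16`, exact up to 1/65535 of the range."""
    q = np.asarray(iio.imread(path), dtype=float)
    meta = json.loads(Path(str(path) + ".json").read_text())
    lo, hi = meta["min"], meta["max"]
    return lo + q / 65535.0 * ((hi - lo) or 1.0)


def write_trajectory(path, traj) -> None:
    """Snapshots and diagnostics of a simulation run as one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=traj.times)
        f.create_dataset("u", data=traj.u_snapshots)
        f.create_dataset("v", data=traj.v_snapshots)
        g = f.create_group("diagnostics")
        for k in ("diag_t", "mean_u", "mean_v", "min_u", "max_u", "min_v",
                  "frac_low", "frac_high"):
            g.create_dataset(k, data=getattr(traj, k))
        f.attrs["seed"] = traj.config.seed
        for k, v in traj.config.params.to_dict().items():
            f.attrs[f"params/{k}"] = v


def read_trajectory(path) -> dict:
    """Raw trajectory payload (arrays + attrs) without reconstructing SimConfig."""
    out = {}
    with h5py.File(path, "r") as f:
        for k in ("t", "u", "v"):
            out[k] = f[k][()]
        out["diagnostics"] = {k: f["diagnostics"][k][()] for k in f["diagnostics"]}
        out["attrs"] = dict(f.attrs)
    return out
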