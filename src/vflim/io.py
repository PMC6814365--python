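"""Readers and writers for the package's on-disk formats.

Photon-count cubes are stored either as multi-page TIFF (one 16-bit page
per time bin) with a JSON sidecar carrying the time axis and ground-truth
record, or as a single NPZ bundle.  IRFs go to NPZ or two-column CSV,
label maps to 16-bit TIFF, tables to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import IRF, TCSPCImage, TimeAxis

__all__ = [
    "write_cube_tiff", "read_cube_tiff",
    "write_cube_npz", "read_cube_npz",
    "write_irf", "read_irf",
    "write_labels_tiff", "read_labels_tiff",
    "write_lifetime_tiff", "read_lifetime_tiff",
]


def _truth_to_json(truth: dict) -> dict:
    out = {}
    for k, v in truth.items():
        if isinstance(v, np.ndarray):
            out[k] = {"__array__": v.tolist(), "dtype": str(v.dtype)}
        elif isinstance(v, dict):
            out[k] = {str(kk): vv for kk, vv in v.items()}
        else:
            out[k] = v
    return out


def _truth_from_json(payload: dict) -> dict:
    out = {}
    for k, v in payload.items():
        if isinstance(v, dict) and "__array__" in v:
            out[k] = np.array(v["__array__"], dtype=v["dtype"])
        elif k == "vmem_mv" and isinstance(v, dict):
            out[k] = {int(kk): vv for kk, vv in v.items()}
        else:
            out[k] = v
    return out


def write_cube_tiff(path: str | Path, cube: TCSPCImage) -> None:
    """Multi-page TIFF (time as pages, uint16) + JSON sidecar."""
    path = Path(path)
    counts = cube.counts
    if counts.max() > np.iinfo(np.uint16).max:
        raise ValueError("counts exceed uint16 range; use NPZ instead")
    pages = np.transpose(np.round(counts).astype(np.uint16), (2, 0, 1))
    tifffile.imwrite(path, pages)
    sidecar = {
        "n_bins": cube.axis.n_bins,
        "period_ns": cube.axis.period,
        "truth": _truth_to_json(cube.truth),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_cube_tiff(path: str | Path) -> TCSPCImage:
    path = Path(path)
    pages = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    axis = TimeAxis(sidecar["n_bins"], sidecar["period_ns"])
    counts = np.transpose(pages, (1, 2, 0))
    return TCSPCImage(counts, axis, _truth_from_json(sidecar.get("truth", {})))


def write_cube_npz(path: str | Path, cube: TCSPCImage) -> None:
    truth_json = json.dumps(_truth_to_json(cube.truth))
    np.savez_compressed(
        path, counts=cube.counts, n_bins=cube.axis.n_bins,
        period_ns=cube.axis.period, truth=truth_json,
    )


def read_cube_npz(path: str | Path) -> TCSPCImage:
    with np.load(path, allow_pickle=False) as data:
        axis = TimeAxis(int(data["n_bins"]), float(data["period_ns"]))
        truth = _truth_from_json(json.loads(str(data["truth"])))
        return TCSPCImage(data["counts"], axis, truth)


def write_irf(path: str | Path, irf: IRF) -> None:
    """NPZ (``.npz``) or two-column CSV (time_ns, value) by extension."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, values=irf.values, n_bins=irf.axis.n_bins,
                 period_ns=irf.axis.period)
    else:
        df = pd.DataFrame({"time_ns": irf.axis.times(), "value": irf.values})
        df.to_csv(path, index=False)


def read_irf(path: str | Path, axis: TimeAxis | None = None) -> IRF:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            axis = TimeAxis(int(data["n_bins"]), float(data["period_ns"]))
            return IRF(axis, data["values"])
    df = pd.read_csv(path)
    if axis is None:
        n = len(df)
        dt = float(df["time_ns"].iloc[1] - df["time_ns"].iloc[0])
        axis = TimeAxis(n, n * dt)
    return IRF(axis, df["value"].to_numpy())


def write_labels_tiff(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels outside uint16 range")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_labels_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_lifetime_tiff(path: str | Path, tau_map: np.ndarray) -> None:
    """Lifetime map as 32-bit float TIFF (NaN where unfit)."""
    tifffile.imwrite(path, np.asarray(tau_map, dtype=np.float32))


def read_lifetime_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)
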