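"""File I/O: NIfTI volumes and masks, rp motion text, TSV timeseries."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .networks import NetworkPair
from .prep import MotionParams, VolumeSeries

__all__ = [
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "save_map",
    "save_motion",
    "load_motion",
    "save_network_pair",
    "load_network_pair",
]


def load_volume(path, tr: float = 2.0) -> VolumeSeries:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    if len(zooms) >= 4 and zooms[3] > 0:
        tr = float(zooms[3])
    return VolumeSeries(np.asarray(img.dataobj, dtype=float), img.affine, tr=tr)


def save_volume(series: VolumeSeries, path) -> Path:
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    img.header.set_zooms((*series.voxel_size_mm(), series.tr))
    nib.save(img, str(path))
    return Path(path)


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0.5


def save_mask(mask: np.ndarray, affine: np.ndarray, path) -> Path:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))
    return Path(path)


def save_map(data: np.ndarray, affine: np.ndarray, path) -> Path:
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))
    return Path(path)


def save_motion(values: np.ndarray, path) -> Path:
    np.savetxt(str(path), np.asarray(values), fmt="%.6f")
    return Path(path)


def load_motion(path) -> MotionParams:
    return MotionParams.from_rp_file(path)


def save_network_pair(pair: NetworkPair, path) -> Path:
    """TSV (frame, dmn, tpn) plus a JSON sidecar with tr/stream/provenance."""
    path = Path(path)
    pd.DataFrame(
        {"frame": np.arange(pair.n_frames), "dmn": pair.dmn_ts, "tpn": pair.tpn_ts}
    ).to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"tr": pair.tr, "stream": pair.stream, "provenance": pair.provenance}
        )
    )
    return path


def load_network_pair(path) -> NetworkPair:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = {"tr": 2.0, "stream": "GSR", "provenance": "seed-derived"}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return NetworkPair(df["dmn"].to_numpy(), df["tpn"].to_numpy(), **meta)
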