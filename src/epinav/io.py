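"""Session containers and standard-format readers/writers.

A simulated session lives in one directory:

    session/
      config.yaml            acquisition + simulation parameters
      provenance.json        config hash, seed, package version
      phantom.nii.gz         ground-truth object (imaging grid)
      mask.nii.gz            brain mask
      coils.npy              receive sensitivities (imaging grid)
      ref_kspace.npy         fully sampled reference-scan k-space
      nav/frame_###.npy      undersampled navigator k-space per frame
      kspace/vol_###.npy     undersampled imaging k-space per volume
      *_truth.tsv            ground-truth motion / field traces
      traces.tsv             estimated motion + field traces
      recon_<mode>.nii.gz    reconstructed 4D series
      metrics/               metric maps (NIfTI) + report.json

Images use NIfTI-1 with the grid's diagonal affine; 4D series store the
volume TR in pixdim[4].  k-space arrays are plain ``.npy`` with a JSON
sidecar describing shape and pattern parameters.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .geometry import Grid3D
from .navigator import FieldState
from .recon import TimeSeries4D

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_series",
    "load_series",
    "write_trace_tsv",
    "read_trace_tsv",
    "save_kspace",
    "load_kspace",
    "load_config",
    "save_config",
    "write_provenance",
]

TRACE_COLUMNS = [
    "frame",
    "trans_x",
    "trans_y",
    "trans_z",
    "rot_x",
    "rot_y",
    "rot_z",
    "g0",
    "gx",
    "gy",
    "gz",
]


def save_nifti(path, vol: np.ndarray, grid: Grid3D, tr_s: float | None = None) -> None:
    vol = np.asarray(vol)
    if np.iscomplexobj(vol):
        vol = np.abs(vol)
    img = nib.Nifti1Image(vol.astype(np.float32), grid.affine())
    zooms = list(grid.voxel_size)
    if vol.ndim == 4 and tr_s is not None:
        zooms.append(tr_s)
        img.header.set_xyzt_units("mm", "sec")
    img.header.set_zooms(tuple(zooms))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, Grid3D]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    aff = img.affine
    voxel = tuple(float(v) for v in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(v) for v in aff[:3, 3])
    grid = Grid3D(tuple(int(s) for s in data.shape[:3]), voxel, origin)
    return data, grid


def save_series(path, series: TimeSeries4D) -> None:
    # NIfTI stores time last; internal layout is (t, x, y, z)
    vol4 = np.moveaxis(np.asarray(series.data), 0, -1)
    save_nifti(path, vol4, series.grid, tr_s=series.tr_volume)


def load_series(path) -> TimeSeries4D:
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj), -1, 0)
    aff = img.affine
    voxel = tuple(float(v) for v in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(v) for v in aff[:3, 3])
    grid = Grid3D(tuple(int(s) for s in data.shape[1:]), voxel, origin)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return TimeSeries4D(data, grid, tr)


def write_trace_tsv(path, transforms, field_states=None) -> None:
    """Motion (+ optional field) trace as a BIDS-style TSV."""
    rows = []
    for i, t in enumerate(transforms):
        f = field_states[i] if field_states is not None else FieldState()
        rows.append([i, *t.parameters.tolist(), *f.parameters.tolist()])
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_trace_tsv(path):
    from .geometry import RigidTransform

    df = pd.read_csv(path, sep="\t")
    transforms = [
        RigidTransform.from_parameters(
            row[["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]].to_numpy(
                float
            )
        )
        for _, row in df.iterrows()
    ]
    fields = [
        FieldState(*row[["g0", "gx", "gy", "gz"]].to_numpy(float).tolist())
        for _, row in df.iterrows()
    ]
    return transforms, fields


def save_kspace(path, samples: np.ndarray, meta: dict) -> None:
    path = Path(path)
    np.save(path, samples)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_kspace(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    samples = np.load(path.with_suffix(".npy"))
    meta = {}
    if path.with_suffix(".json").exists():
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
    return samples, meta


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_provenance(path, config: dict, seed: int) -> None:
    from . import __version__

    with open(path, "w") as fh:
        json.dump(
            {
                "config_sha256": config_hash(config),
                "seed": int(seed),
                "epinav_version": __version__,
            },
            fh,
            indent=1,
        )
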