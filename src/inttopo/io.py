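"""NIfTI and table I/O with a fixed voxel flattening order.

Masked voxels are flattened with the x axis fastest (Fortran ravel order of
the volume), and the same order is used when writing, so a write-then-read
round trip is bit-identical and voxel index ``i`` is stable across stages.
Every written artifact gets a JSON provenance sidecar.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .containers import RegionAtlas, VoxelTimeSeries

_ORDER = "F"  # x fastest


def _flat_mask_indices(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    flat = np.flatnonzero(mask.ravel(order=_ORDER))
    coords = np.stack(np.unravel_index(flat, mask.shape, order=_ORDER), axis=1)
    return flat, coords


def read_timeseries(path, mask_path, tr_seconds: float | None = None,
                    subject_id: str = "", run_id: str = "") -> VoxelTimeSeries:
    """Load a 4D volume and flatten the masked voxels (x fastest).

    TR is taken from the header unless ``tr_seconds`` overrides it; a header
    without a usable TR requires the explicit value.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    if mask.shape != data.shape[:3]:
        raise ValueError(f"mask shape {mask.shape} does not match volume {data.shape[:3]}")
    flat, coords = _flat_mask_indices(mask)
    if flat.size == 0:
        raise ValueError("mask selects no voxels")
    values = data.reshape(-1, data.shape[3], order=_ORDER)[flat]
    tr = tr_seconds
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if not np.isfinite(tr) or tr <= 0:
            raise ValueError(f"{path}: no usable TR in header; pass tr_seconds explicitly")
    return VoxelTimeSeries(values, tr, subject_id, run_id, coords)


def read_atlas(path, mask_path) -> RegionAtlas:
    labels3d = np.asarray(nib.load(str(path)).dataobj).astype(int)
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    if mask.shape != labels3d.shape:
        raise ValueError("atlas and mask shapes differ")
    flat, _ = _flat_mask_indices(mask)
    return RegionAtlas(labels3d.ravel(order=_ORDER)[flat])


def _volume_shape(coords: np.ndarray) -> tuple[int, int, int]:
    return tuple(int(c) + 1 for c in coords.max(axis=0))


def write_timeseries(vts: VoxelTimeSeries, path, mask_path=None) -> None:
    """Write a run as 4D NIfTI (plus its mask) using the voxel coordinates."""
    if vts.voxel_coords is None:
        raise ValueError("voxel coordinates are required to write a volume")
    shape = _volume_shape(vts.voxel_coords)
    vol = np.zeros(shape + (vts.n_timepoints,))
    x, y, z = vts.voxel_coords.T
    vol[x, y, z, :] = vts.values
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, vts.tr_seconds))
    nib.save(img, str(path))
    if mask_path is not None:
        mask = np.zeros(shape, dtype=np.uint8)
        mask[x, y, z] = 1
        nib.save(nib.Nifti1Image(mask, affine=np.eye(4)), str(mask_path))


def write_labels(labels: np.ndarray, coords: np.ndarray, path) -> None:
    """Write per-voxel integer labels as a 3D NIfTI label volume."""
    shape = _volume_shape(coords)
    vol = np.zeros(shape, dtype=np.int16)
    x, y, z = coords.T
    vol[x, y, z] = labels
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def write_scalar_map(values: np.ndarray, coords: np.ndarray, path) -> None:
    """Write a per-voxel scalar map as a 3D NIfTI volume (NaN outside mask)."""
    shape = _volume_shape(coords)
    vol = np.full(shape, np.nan)
    x, y, z = coords.T
    vol[x, y, z] = values
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def write_sidecar(artifact_path, config_dict: dict, stage: str) -> None:
    """JSON provenance sidecar: stage, package version, config hash."""
    from . import __version__

    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    sidecar = {
        "stage": stage,
        "package_version": __version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "voxel_order": "x-fastest (Fortran ravel)",
    }
    Path(str(artifact_path) + ".json").write_text(json.dumps(sidecar, indent=2))
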