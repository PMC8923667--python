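"""Shared in-memory containers for voxelwise analyses.

All stages operate on flat voxel vectors/matrices: a masked 4D volume is
flattened into ``(n_voxels, n_timepoints)`` with a fixed, recorded scan order
(x fastest), so that index ``i`` means the same voxel in every stage.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoxelTimeSeries:
    """One run's BOLD time series for a fixed voxel set.

    Parameters
    ----------
    values : ndarray, shape (n_voxels, n_timepoints)
        Signal in arbitrary units. Must be finite.
    tr_seconds : float
        Sampling interval (repetition time), seconds.
    subject_id, run_id : str
        Identifiers used for aggregation and provenance.
    voxel_coords : ndarray of int, shape (n_voxels, 3), optional
        Voxel-space coordinates, needed only to write volumes.
    """

    values: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    run_id: str = ""
    voxel_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (voxels x timepoints)")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.voxel_coords is not None:
            self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
            if self.voxel_coords.shape != (self.values.shape[0], 3):
                raise ValueError("voxel_coords must be (n_voxels, 3)")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class RegionAtlas:
    """Integer region label per voxel plus a region-id -> name table."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)
    bilateral: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a flat per-voxel vector")

    @property
    def region_ids(self) -> list[int]:
        return sorted(int(r) for r in np.unique(self.labels) if r != 0)

    def voxels_of(self, region_id: int) -> np.ndarray:
        idx = np.flatnonzero(self.labels == region_id)
        if idx.size == 0:
            raise ValueError(f"region {region_id} has no voxels in the atlas")
        return idx


@dataclass
class ScalarMap:
    """Per-voxel scalar field (INT map, gradient component, projection...).

    ``semantics`` tags what the numbers mean: ``"int"`` (unitless ACF sum),
    ``"gradient-position"`` (arbitrary sign/scale) or ``"seconds"``.
    """

    values: np.ndarray
    name: str = ""
    semantics: str = "int"
    voxel_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ScalarMap values must be 1-D")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]
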