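"""Relating INT maps to FC-gradient maps and cross-structure projections.

Gradient components have arbitrary sign, so only the magnitude of a spatial
correlation between an INT map and a gradient map is interpretable; all
comparison helpers therefore report both r and |r|.

Two projection procedures carry maps between structures (e.g. striatum and
cortex) through their mutual FC:

* ``project_gradient`` — each target voxel inherits the gradient value of the
  single source voxel it is most strongly (signed) correlated with.
* ``project_int`` — each target voxel receives the mean INT of its k most
  strongly correlated source voxels (k = 10 by default), reconstructing a
  timescale map purely from connectivity.
"""
from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .containers import ScalarMap
from .gradients import FcMatrix, GradientSet


class MapCorrelation(NamedTuple):
    r: float
    abs_r: float
    n_voxels: int


def _values(m: ScalarMap | np.ndarray) -> np.ndarray:
    return m.values if isinstance(m, ScalarMap) else np.asarray(m, dtype=float)


def map_correlation(a: ScalarMap | np.ndarray, b: ScalarMap | np.ndarray) -> MapCorrelation:
    """Pearson r between two voxel maps over their common finite support."""
    x, y = _values(a), _values(b)
    if x.shape != y.shape:
        raise ValueError("maps cover different voxel sets")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 voxels to correlate maps")
    r = float(np.corrcoef(x, y)[0, 1])
    return MapCorrelation(r=r, abs_r=abs(r), n_voxels=int(x.size))


def best_gradient(int_map: ScalarMap | np.ndarray, grads: GradientSet) -> tuple[int, float]:
    """Gradient component most correlated (by |r|) with the INT map.

    Returns the 1-based component index (1 = G1) and the signed r; ties go to
    the lower index.
    """
    if grads.n_components < 1:
        raise ValueError("need at least one gradient component")
    best_idx, best_r = 1, 0.0
    for i in range(grads.n_components):
        r = map_correlation(int_map, grads.components[i]).r
        if abs(r) > abs(best_r) + 1e-15:
            best_idx, best_r = i + 1, r
    return best_idx, best_r


def project_gradient(gradient: ScalarMap | np.ndarray, fc: FcMatrix) -> ScalarMap:
    """Project a source-structure gradient onto a target structure.

    ``fc`` is source x target; target voxel j takes the gradient value of the
    source voxel with maximal signed FC to j (ties: lowest source index).
    Target voxels with no finite FC are returned as NaN.
    """
    g = _values(gradient)
    v = fc.values
    if v.shape[0] != g.shape[0]:
        raise ValueError("gradient length must match the FC source dimension")
    out = np.full(v.shape[1], np.nan)
    finite_any = np.isfinite(v).any(axis=0)
    cols = np.nan_to_num(v[:, finite_any], nan=-np.inf)
    out[finite_any] = g[np.argmax(cols, axis=0)]
    return ScalarMap(out, name="projected-gradient", semantics="gradient-position")


def project_int(int_map: ScalarMap | np.ndarray, fc: FcMatrix, k: int = 10) -> ScalarMap:
    """Reconstruct target-structure INTs from source INTs through FC.

    ``fc`` is target x source (e.g. striatum x cortex); each target voxel
    gets the mean INT of its k most positively correlated source voxels.
    """
    ints = _values(int_map)
    v = fc.values
    if v.shape[1] != ints.shape[0]:
        raise ValueError("INT map length must match the FC source (column) dimension")
    if not 1 <= k <= v.shape[1]:
        raise ValueError(f"k={k} exceeds the number of source voxels ({v.shape[1]})")
    out = np.full(v.shape[0], np.nan)
    for j in range(v.shape[0]):
        row = v[j]
        ok = np.isfinite(row)
        if ok.sum() < k:
            continue
        # stable sort on -r: ties keep the lower source index
        top = np.argsort(-np.where(ok, row, -np.inf), kind="stable")[:k]
        out[j] = ints[top].mean()
    return ScalarMap(out, name="projected-int", semantics="int")
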