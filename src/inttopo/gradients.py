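"""Functional-connectivity gradients via diffusion-map embedding.

Pipeline: voxel-pair Pearson FC -> row-wise sparsification keeping the
strongest correlations -> cosine-similarity affinity between connectivity
profiles -> anisotropic diffusion-map embedding.  The leading components
("gradients") describe the spatial axes of largest FC variation; their sign
is arbitrary by construction, so downstream comparisons report |r|.

The embedding follows the standard diffusion-maps recipe: with affinity W and
degrees d, the kernel is first renormalised as W_ij / (d_i d_j)^alpha
(alpha = 0.5 discounts sampling-density effects), the resulting matrix is
row-normalised into a Markov operator, and the operator's nontrivial
eigenvectors — scaled by lambda/(1-lambda) at diffusion time 0, or by
lambda^t otherwise — give the component maps.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .containers import VoxelTimeSeries

_FISHER_CLIP = 1.0 - 1e-7


@dataclass
class FcMatrix:
    """Pearson correlations for all source x target voxel pairs.

    ``symmetric`` is true when source and target are the same voxel set.
    Zero-variance voxels are flagged (NaN rows/columns), never dropped, so
    index maps stay aligned with the time-series containers.
    """

    values: np.ndarray
    symmetric: bool = False
    bad_sources: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    bad_targets: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("FC matrix must be 2-D")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class AffinityMatrix:
    """Symmetric nonnegative similarity between connectivity profiles."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("affinity must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("affinity must be symmetric to 1e-12")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-9:
            raise ValueError("affinity entries must lie in [0, 1]")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


@dataclass
class GradientSet:
    """Diffusion-embedding components, eigenvalue-ordered, sign-arbitrary."""

    components: np.ndarray  # (n_components, n_voxels)
    eigenvalues: np.ndarray
    sign_arbitrary: bool = True

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.components.shape[0] != self.eigenvalues.shape[0]:
            raise ValueError("one eigenvalue per component required")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be in descending order")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def component(self, index: int) -> np.ndarray:
        """1-based accessor: component(1) is G1, the principal gradient."""
        if not 1 <= index <= self.n_components:
            raise IndexError(f"component index {index} out of range")
        return self.components[index - 1]


def fc_matrix(source: VoxelTimeSeries, target: VoxelTimeSeries | None = None) -> FcMatrix:
    """Pearson r between every source and target voxel pair.

    With ``target=None`` the matrix is the symmetric within-set FC.
    Zero-variance voxels yield NaN rows/columns and are listed in the flags.
    """
    sym = target is None
    tgt = source if sym else target
    if source.n_timepoints != tgt.n_timepoints:
        raise ValueError("source and target must share the timepoint count")
    xs = _standardise(source.values)
    bad_s = np.flatnonzero(np.isnan(xs[:, 0]))
    if sym:
        xt, bad_t = xs, bad_s
    else:
        xt = _standardise(tgt.values)
        bad_t = np.flatnonzero(np.isnan(xt[:, 0]))
    with np.errstate(invalid="ignore"):
        r = xs @ xt.T / source.n_timepoints
    r = np.clip(r, -1.0, 1.0, out=r)
    r[bad_s, :] = np.nan
    r[:, bad_t] = np.nan
    if sym:
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 1.0)
        r[bad_s, bad_s] = np.nan
    return FcMatrix(r, symmetric=sym, bad_sources=bad_s, bad_targets=bad_t)


def _standardise(x: np.ndarray) -> np.ndarray:
    d = x - x.mean(axis=1, keepdims=True)
    sd = d.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = d / sd
    z[(sd == 0).ravel(), :] = np.nan
    return z


def group_fc(matrices: list[FcMatrix]) -> FcMatrix:
    """Average FC matrices in Fisher-z space (entries clipped at |r|=1-1e-7).

    The clip keeps unit diagonals and perfectly correlated pairs finite; the
    inverse transform returns them at >= 1 - 2e-7.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    shape = matrices[0].shape
    if any(m.shape != shape for m in matrices):
        raise ValueError("all FC matrices must share one shape")
    z = np.zeros(shape)
    for m in matrices:
        z += np.arctanh(np.clip(m.values, -_FISHER_CLIP, _FISHER_CLIP))
    mean = np.tanh(z / len(matrices))
    return FcMatrix(mean, symmetric=all(m.symmetric for m in matrices))


def sparsify(fc: FcMatrix, density: float = 0.10) -> FcMatrix:
    """Keep, per row, the ``ceil(density * n_cols)`` largest signed entries.

    This is the retain-top-fraction reading of "10% sparsity": the strongest
    (overwhelmingly positive) correlations survive, the complement is zeroed.
    Ties at the cutoff keep the lower column index.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    v = fc.values
    n_keep = int(np.ceil(density * v.shape[1]))
    if n_keep >= v.shape[1]:
        return FcMatrix(v.copy(), symmetric=fc.symmetric,
                        bad_sources=fc.bad_sources, bad_targets=fc.bad_targets)
    # stable argsort on -value: equal values keep ascending column order
    order = np.argsort(-np.nan_to_num(v, nan=-np.inf), axis=1, kind="stable")
    out = np.zeros_like(v)
    rows = np.arange(v.shape[0])[:, None]
    keep = order[:, :n_keep]
    out[rows, keep] = v[rows, keep]
    return FcMatrix(np.nan_to_num(out, nan=0.0), symmetric=False,
                    bad_sources=fc.bad_sources, bad_targets=fc.bad_targets)


def cosine_affinity(fc_sparse: FcMatrix) -> AffinityMatrix:
    """Cosine similarity between rows of the sparsified FC matrix.

    Negative similarities (rare after positive sparsification) are clipped to
    zero so the result is a valid diffusion kernel.
    """
    x = fc_sparse.values
    norms = np.linalg.norm(x, axis=1)
    zero_rows = np.flatnonzero(norms == 0)
    if zero_rows.size:
        raise ValueError(f"all-zero connectivity profiles for voxels {zero_rows.tolist()}")
    a = (x @ x.T) / np.outer(norms, norms)
    np.clip(a, 0.0, 1.0, out=a)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return AffinityMatrix(a)


def diffusion_embedding(affinity: AffinityMatrix, n_components: int = 10,
                        alpha: float = 0.5, diffusion_time: float = 0) -> GradientSet:
    """Diffusion-map embedding of a connected nonnegative affinity.

    Anisotropic normalisation with exponent ``alpha``, row-normalised Markov
    operator, eigendecomposition through the symmetric conjugate; the trivial
    stationary component is discarded and components are scaled by
    lambda/(1-lambda) (diffusion_time 0, multiscale convention) or lambda^t.
    """
    w = affinity.values
    n = w.shape[0]
    if not 1 <= n_components <= n - 1:
        raise ValueError("n_components must lie in [1, n_voxels - 1]")
    n_comp_graph, labels = connected_components(csr_matrix(w > 0), directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"affinity graph is disconnected: {n_comp_graph} components with sizes {sizes.tolist()}")
    d = w.sum(axis=1)
    if alpha > 0:
        w = w / np.outer(d**alpha, d**alpha)
    d2 = w.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d2)
    s = w * np.outer(inv_sqrt, inv_sqrt)
    s = (s + s.T) / 2.0
    evals, evecs = np.linalg.eigh(s)
    idx = np.argsort(evals)[::-1][: n_components + 1]
    evals, evecs = evals[idx], evecs[:, idx]
    # eigenvectors of the Markov operator; dividing by the stationary
    # eigenvector makes the trivial component exactly constant
    psi = evecs / evecs[:, [0]]
    lam = evals[1:]
    if diffusion_time == 0:
        with np.errstate(divide="ignore"):
            scale = lam / np.where(1 - lam > 1e-12, 1 - lam, 1e-12)
    else:
        scale = np.sign(lam) * np.abs(lam) ** diffusion_time
    comps = (psi[:, 1:] * scale).T
    return GradientSet(components=comps, eigenvalues=lam)
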