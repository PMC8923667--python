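"""Synthetic multi-subject BOLD-like data with planted timescales and topography.

The generator is a stand-in: the analyses it feeds were designed for real
resting-state fMRI, which has no known generative model, so every choice here
is an explicit simplification with a recoverable ground truth.

Model per voxel v (region r(v), planted axis position a_v in [0, 1]):

1. latent signals L_1..L_K (white noise, shared within a run) are mixed into
   v's innovation with Gaussian-bump weights centred at equally spaced axis
   positions: w_vk ∝ exp(-(a_v - c_k)^2 / (2 bw^2)).  Nearby voxels on the
   axis share latents, so their innovations — and hence their FC profiles —
   are similar, and similarity decays smoothly with axis distance: a planted
   one-dimensional connectivity topography.
2. the mixed innovation (shared fraction + private white noise) is passed
   through an AR(1) filter with the region's coefficient phi, so the signal's
   autocorrelation is exactly the AR(1) closed form phi^k regardless of the
   mixing; phi is the planted timescale, with population INT proxy
   phi / (1 - phi) = sum_k phi^k.
3. white observation noise of scale ``noise_sd`` is added; an optional
   double-gamma HRF convolution (default off) can be applied last.

Randomness is counter-based: one global seed plus (subject, run) indices key
an independent substream, so regeneration is bit-identical and independent of
generation order.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist

from .containers import RegionAtlas, VoxelTimeSeries

SHARED_FRACTION = 0.6  # fraction of innovation variance carried by latents


@dataclass(frozen=True)
class RegionSpec:
    region_id: int
    n_voxels: int
    phi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.phi < 1:
            raise ValueError(f"AR(1) coefficient must lie in [0, 1); got {self.phi}")
        if self.n_voxels < 1:
            raise ValueError("regions need at least one voxel")
        if self.region_id < 1:
            raise ValueError("region ids must be positive (0 is background)")


@dataclass
class SyntheticConfig:
    """Stated world for the generator; defaults mirror the target acquisition.

    700 timepoints per run at TR = 1.1 s, 9 subjects with 5 runs each, and six
    regions whose AR(1) coefficients ascend from 0.1 to 0.85 along the planted
    axis (sensory-like fast end to associative-like slow end).
    """

    n_subjects: int = 9
    n_runs: int = 5
    n_timepoints: int = 700
    tr_seconds: float = 1.1
    regions: tuple[RegionSpec, ...] = (
        RegionSpec(1, 20, 0.10, "r1-fast"),
        RegionSpec(2, 20, 0.25, "r2"),
        RegionSpec(3, 20, 0.40, "r3"),
        RegionSpec(4, 20, 0.55, "r4"),
        RegionSpec(5, 20, 0.70, "r5"),
        RegionSpec(6, 20, 0.85, "r6-slow"),
    )
    gradient_axis: np.ndarray | None = None  # default: regions tile [0, 1] in order
    latent_dim: int = 10
    mixing_bandwidth: float = 0.15
    noise_sd: float = 0.5
    hrf_enabled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.regions = tuple(r if isinstance(r, RegionSpec) else RegionSpec(*r)
                             for r in self.regions)
        if min(self.n_subjects, self.n_runs, self.latent_dim) < 1:
            raise ValueError("counts must be positive")
        if self.n_timepoints < 10:
            raise ValueError("need at least 10 timepoints per run")
        if self.tr_seconds <= 0 or self.noise_sd < 0 or self.mixing_bandwidth <= 0:
            raise ValueError("tr_seconds and mixing_bandwidth must be positive, noise_sd nonnegative")
        if self.n_voxels == 0:
            raise ValueError("region voxel counts sum to zero")
        if self.gradient_axis is not None:
            self.gradient_axis = np.asarray(self.gradient_axis, dtype=float)
            if self.gradient_axis.shape != (self.n_voxels,):
                raise ValueError("gradient_axis must give one position per voxel")
            if self.gradient_axis.min() < 0 or self.gradient_axis.max() > 1:
                raise ValueError("gradient_axis positions must lie in [0, 1]")

    @property
    def n_voxels(self) -> int:
        return sum(r.n_voxels for r in self.regions)

    def resolved_axis(self) -> np.ndarray:
        """Planted axis: regions tile [0, 1] in listed order unless given."""
        if self.gradient_axis is not None:
            return self.gradient_axis
        parts, n_reg = [], len(self.regions)
        for j, reg in enumerate(self.regions):
            within = (np.arange(reg.n_voxels) + 0.5) / reg.n_voxels
            parts.append((j + within) / n_reg)
        return np.concatenate(parts)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regions"] = [asdict(r) for r in self.regions]
        d["gradient_axis"] = None if self.gradient_axis is None else self.gradient_axis.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["regions"] = tuple(RegionSpec(**r) for r in d["regions"])
        if d.get("gradient_axis") is not None:
            d["gradient_axis"] = np.asarray(d["gradient_axis"], dtype=float)
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted parameters every recovery test compares against."""

    phi: np.ndarray                 # per voxel
    gradient_axis: np.ndarray       # per voxel
    region_labels: np.ndarray       # per voxel
    region_int_proxy: pd.DataFrame  # region_id, phi, int_proxy = phi/(1-phi)
    mixing_weights: np.ndarray      # voxels x latents, unit rows

    def __post_init__(self) -> None:
        proxy = self.region_int_proxy.sort_values("phi")["int_proxy"].to_numpy()
        if np.any(np.diff(proxy) <= 0):
            raise ValueError("population INT proxy must increase strictly with phi")


@dataclass
class SyntheticDataset:
    """All runs of all subjects plus the ground truth and atlas."""

    runs: dict[tuple[str, str], VoxelTimeSeries]
    ground_truth: GroundTruth
    atlas: RegionAtlas
    config: SyntheticConfig

    @property
    def subject_ids(self) -> list[str]:
        return sorted({s for s, _ in self.runs})

    def runs_for(self, subject_id: str) -> list[VoxelTimeSeries]:
        return [v for (s, r), v in sorted(self.runs.items()) if s == subject_id]


def ar1_series(phi: float, n: int, sd: float = 1.0,
               seed: int | np.random.Generator = 0) -> np.ndarray:
    """Stationary AR(1) draw: x_t = phi x_{t-1} + e_t, e_t ~ N(0, sd^2).

    The initial state is drawn from the stationary distribution, so the
    population ACF is exactly phi^k from the first sample.
    """
    if not 0 <= phi < 1:
        raise ValueError(f"AR(1) coefficient must lie in [0, 1); got {phi}")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if sd <= 0:
        raise ValueError("innovation scale must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x0 = rng.normal(0.0, sd / np.sqrt(1 - phi**2))
    e = rng.normal(0.0, sd, size=n)
    y, _ = lfilter([1.0], [1.0, -phi], e, zi=np.atleast_1d(phi * x0))
    return y


def mixing_weights(axis: np.ndarray, latent_dim: int, bandwidth: float) -> np.ndarray:
    """Unit-norm Gaussian-bump loadings of each voxel on each latent signal."""
    centers = (np.arange(latent_dim) + 0.5) / latent_dim
    w = np.exp(-((axis[:, None] - centers[None, :]) ** 2) / (2 * bandwidth**2))
    norms = np.linalg.norm(w, axis=1)
    underflow = norms == 0
    if np.any(underflow):  # vanishing bandwidth: load on the nearest centre only
        nearest = np.abs(axis[underflow, None] - centers[None, :]).argmin(axis=1)
        w[underflow] = 0.0
        w[np.flatnonzero(underflow), nearest] = 1.0
        norms = np.linalg.norm(w, axis=1)
    return w / norms[:, None]


def double_gamma_hrf(tr_seconds: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at the TR."""
    t = np.arange(0, duration, tr_seconds)
    peak = gamma_dist.pdf(t, 6)
    undershoot = gamma_dist.pdf(t, 16)
    h = peak - undershoot / 6.0
    return h / h.max()


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate every run of every subject with one recorded ground truth."""
    axis = config.resolved_axis()
    n_vox, n_t = config.n_voxels, config.n_timepoints
    labels = np.concatenate([np.full(r.n_voxels, r.region_id) for r in config.regions])
    phi_vox = np.concatenate([np.full(r.n_voxels, r.phi) for r in config.regions])
    weights = mixing_weights(axis, config.latent_dim, config.mixing_bandwidth)
    coords = _grid_coords(n_vox)
    atlas = RegionAtlas(labels, names={r.region_id: r.name or str(r.region_id)
                                       for r in config.regions})
    proxy = pd.DataFrame({
        "region_id": [r.region_id for r in config.regions],
        "phi": [r.phi for r in config.regions],
        "int_proxy": [r.phi / (1 - r.phi) for r in config.regions],
    })
    truth = GroundTruth(phi=phi_vox, gradient_axis=axis, region_labels=labels,
                        region_int_proxy=proxy, mixing_weights=weights)
    hrf = double_gamma_hrf(config.tr_seconds) if config.hrf_enabled else None
    runs: dict[tuple[str, str], VoxelTimeSeries] = {}
    for s in range(config.n_subjects):
        for r in range(config.n_runs):
            # counter-based substream: independent of generation order
            rng = np.random.default_rng([config.seed, s, r])
            x = _simulate_run(rng, phi_vox, weights, config, n_vox, n_t, hrf)
            sid, rid = f"sub-{s + 1:02d}", f"run-{r + 1:02d}"
            runs[(sid, rid)] = VoxelTimeSeries(x, config.tr_seconds, sid, rid, coords)
    return SyntheticDataset(runs=runs, ground_truth=truth, atlas=atlas, config=config)


def _simulate_run(rng: np.random.Generator, phi_vox: np.ndarray, weights: np.ndarray,
                  config: SyntheticConfig, n_vox: int, n_t: int,
                  hrf: np.ndarray | None) -> np.ndarray:
    latents = rng.standard_normal((config.latent_dim, n_t))
    private = rng.standard_normal((n_vox, n_t))
    x0 = rng.standard_normal(n_vox)
    obs = rng.standard_normal((n_vox, n_t)) if config.noise_sd > 0 else 0.0
    shared = weights @ latents  # unit variance per voxel (unit-norm weights)
    innov = np.sqrt(SHARED_FRACTION) * shared + np.sqrt(1 - SHARED_FRACTION) * private
    x = np.empty_like(innov)
    for phi in np.unique(phi_vox):
        sel = phi_vox == phi
        zi = (phi * x0[sel] / np.sqrt(1 - phi**2))[:, None]
        x[sel], _ = lfilter([1.0], [1.0, -phi], innov[sel], axis=1, zi=zi)
    if hrf is not None:
        full = np.apply_along_axis(np.convolve, 1, x, hrf)
        x = full[:, :n_t]
    return x + config.noise_sd * obs


def _grid_coords(n_vox: int) -> np.ndarray:
    """Lay flat voxel indices on a near-cubic 3-D grid, x fastest."""
    nx = int(np.ceil(n_vox ** (1 / 3)))
    ny = int(np.ceil(np.sqrt(n_vox / nx)))
    nz = int(np.ceil(n_vox / (nx * ny)))
    i = np.arange(n_vox)
    x = i % nx
    y = (i // nx) % ny
    z = i // (nx * ny)
    return np.stack([x, y, z], axis=1)


def save_ground_truth(truth: GroundTruth, json_path, csv_path) -> None:
    """Ground truth as JSON (scalars/arrays) + CSV (per-region table)."""
    payload = {
        "phi": truth.phi.tolist(),
        "gradient_axis": truth.gradient_axis.tolist(),
        "region_labels": truth.region_labels.tolist(),
        "mixing_weights": truth.mixing_weights.tolist(),
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh)
    truth.region_int_proxy.to_csv(csv_path, index=False)
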