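"""Voxelwise intrinsic neural timescales (INTs) from BOLD autocorrelation.

The INT of a voxel is the sum of its sample autocorrelation function (ACF)
over the initial positive period: lags k = 1, 2, ... are accumulated until
the ACF first drops to or below zero.  The statistic is unitless — it mixes
the number of positive lags with their magnitudes — and serves as a proxy for
how slowly spontaneous activity decorrelates.  The lag of the first
zero-crossing times the TR gives a crude time constant in seconds.

The ACF estimator is the biased (length-N normalised) autocovariance ratio
with a single mean subtraction per series, which guarantees |ACF| <= 1 and a
positive-semidefinite curve.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RegionAtlas, VoxelTimeSeries

DEFAULT_MAX_LAG = 100


@dataclass
class AcfCurve:
    """Sample ACF at lags 0..L, with the estimator convention recorded."""

    values: np.ndarray
    estimator_tag: str = "biased-meansub"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.shape[0] < 1:
            raise ValueError("AcfCurve needs at least the lag-0 value")
        if not np.isclose(self.values[0], 1.0):
            raise ValueError("ACF at lag 0 must equal 1")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("ACF values must lie in [-1, 1]")

    @property
    def max_lag(self) -> int:
        return self.values.shape[0] - 1


@dataclass
class IntMap:
    """Per-voxel INT values with zero-crossing lags and censoring flags.

    ``crossing_lags`` is in TR steps (float once averaged across runs);
    ``censored`` marks voxels whose ACF never crossed zero within the maximum
    lag in any usable run — their INT is the truncated sum up to max lag.
    """

    int_values: np.ndarray
    crossing_lags: np.ndarray
    censored: np.ndarray
    tr_seconds: float = 1.0
    n_runs: int = 1
    censored_run_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.int_values = np.asarray(self.int_values, dtype=float)
        self.crossing_lags = np.asarray(self.crossing_lags, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if not (self.int_values.shape == self.crossing_lags.shape == self.censored.shape):
            raise ValueError("IntMap arrays must share one shape")
        if np.any(self.int_values < -1e-12):
            raise ValueError("INT values must be nonnegative")

    @property
    def n_voxels(self) -> int:
        return self.int_values.shape[0]

    def time_constants(self) -> np.ndarray:
        """Zero-crossing lag x TR, seconds; NaN where censored."""
        tc = self.crossing_lags * self.tr_seconds
        tc = tc.copy()
        tc[self.censored] = np.nan
        return tc


@dataclass
class HierarchySpec:
    """Regions ordered ascending by mean INT (fast -> slow)."""

    ordering: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        means = [m for _, m in self.ordering]
        if any(b < a for a, b in zip(means, means[1:])):
            raise ValueError("hierarchy must be sorted ascending by mean INT")

    @property
    def region_ids(self) -> list[int]:
        return [r for r, _ in self.ordering]

    @property
    def means(self) -> np.ndarray:
        return np.array([m for _, m in self.ordering], dtype=float)


def acf_matrix(values: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Biased sample ACF of each row of ``values`` at lags 0..max_lag.

    Returns ``(acf, zero_variance)`` where rows flagged in ``zero_variance``
    are filled with NaN beyond lag 0 rather than raising, so callers can
    censor individual voxels.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    n = x.shape[1]
    if n < 2:
        raise ValueError("series length must be at least 2")
    if not 1 <= max_lag < n:
        raise ValueError("max_lag must satisfy 1 <= max_lag < series length")
    d = x - x.mean(axis=1, keepdims=True)
    denom = np.einsum("ij,ij->i", d, d)
    zero_var = denom <= 0
    # full autocovariance via FFT; biased normalisation = divide by lag-0 term
    nfft = int(2 ** np.ceil(np.log2(2 * n - 1)))
    fd = np.fft.rfft(d, nfft, axis=1)
    acov = np.fft.irfft(fd * np.conj(fd), nfft, axis=1)[:, : max_lag + 1]
    acf = np.empty_like(acov)
    acf[~zero_var] = acov[~zero_var] / denom[~zero_var, None]
    acf[zero_var] = np.nan
    acf[~zero_var, 0] = 1.0
    return acf, zero_var


def sample_acf(series: np.ndarray, max_lag: int) -> AcfCurve:
    """Sample ACF of one series: ACF(k) = sum(d_t d_{t+k}) / sum(d_t^2).

    Raises on a zero-variance (constant) series — a degenerate voxel must be
    flagged by the caller, never silently scored 0.
    """
    acf, zero_var = acf_matrix(np.asarray(series, dtype=float)[None, :], max_lag)
    if zero_var[0]:
        raise ValueError("zero-variance series: ACF undefined")
    return AcfCurve(acf[0])


def int_from_acf(acf: AcfCurve | np.ndarray) -> tuple[float, int, bool]:
    """INT statistic from one ACF curve.

    Returns ``(int_value, zero_crossing_lag, censored)``: the smallest lag
    k >= 1 with ACF(k) <= 0 bounds the sum; INT = sum of ACF(1..k-1).  If the
    ACF stays positive through the last computed lag the voxel is censored
    and the sum runs through all lags.
    """
    values = acf.values if isinstance(acf, AcfCurve) else np.asarray(acf, dtype=float)
    ints, lags, cens = _int_from_acf_rows(values[None, :])
    return float(ints[0]), int(lags[0]), bool(cens[0])


def _int_from_acf_rows(acf: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised INT over rows of an ACF matrix (lag 0 in column 0)."""
    tail = acf[:, 1:]
    nonpos = tail <= 0
    any_cross = nonpos.any(axis=1)
    first = np.where(any_cross, nonpos.argmax(axis=1) + 1, tail.shape[1] + 1)
    lag_idx = np.arange(1, acf.shape[1])
    mask = lag_idx[None, :] < first[:, None]
    ints = np.where(mask, tail, 0.0).sum(axis=1)
    lags = np.where(any_cross, first, tail.shape[1])
    return ints, lags, ~any_cross


def time_constant(zero_crossing_lag: float, tr_seconds: float, censored: bool = False) -> float:
    """Time constant in seconds: zero-crossing lag times the TR."""
    if censored:
        return float("nan")
    if zero_crossing_lag < 1:
        raise ValueError("zero-crossing lag must be >= 1")
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    return float(zero_crossing_lag) * float(tr_seconds)


def int_map(runs: list[VoxelTimeSeries], max_lag: int | None = None,
            include_lag0: bool = False) -> IntMap:
    """Per-voxel INT map: per-run INTs averaged voxelwise across runs.

    A voxel censored (no zero crossing) in a run is excluded from that
    voxel's cross-run mean; a voxel censored in every run keeps its truncated
    sums and is flagged.  Zero-variance voxels are censored with NaN.  Maps
    are never smoothed.  ``include_lag0`` adds the lag-0 term (=1) to the sum
    for sensitivity analyses; default off.
    """
    if not runs:
        raise ValueError("need at least one run")
    n_vox = runs[0].n_voxels
    if any(r.n_voxels != n_vox for r in runs):
        raise ValueError("all runs must share the voxel count and ordering")
    tr = runs[0].tr_seconds
    per_run_int = np.empty((len(runs), n_vox))
    per_run_lag = np.empty((len(runs), n_vox))
    per_run_cens = np.empty((len(runs), n_vox), dtype=bool)
    for i, run in enumerate(runs):
        lag = max_lag if max_lag is not None else min(run.n_timepoints - 1, DEFAULT_MAX_LAG)
        acf, zero_var = acf_matrix(run.values, lag)
        ints, lags, cens = _int_from_acf_rows(np.nan_to_num(acf, nan=-1.0))
        if include_lag0:
            ints = ints + 1.0
        ints[zero_var] = np.nan
        cens = cens | zero_var
        per_run_int[i], per_run_lag[i], per_run_cens[i] = ints, lags, cens
    ok = ~per_run_cens
    n_ok = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_int = np.where(ok, per_run_int, 0.0).sum(axis=0) / np.maximum(n_ok, 1)
        mean_lag = np.where(ok, per_run_lag, 0.0).sum(axis=0) / np.maximum(n_ok, 1)
    all_cens = n_ok == 0
    if np.any(all_cens):
        # keep the truncated sums for fully censored voxels; zero-variance
        # voxels stay NaN rather than being silently scored 0
        with np.errstate(invalid="ignore"):
            mean_int[all_cens] = np.nanmean(per_run_int[:, all_cens], axis=0)
        mean_lag[all_cens] = per_run_lag[:, all_cens].mean(axis=0)
    return IntMap(
        int_values=np.clip(mean_int, 0.0, None),
        crossing_lags=mean_lag,
        censored=all_cens,
        tr_seconds=tr,
        n_runs=len(runs),
        censored_run_counts=per_run_cens.sum(axis=0),
    )


def region_mean(imap: IntMap, atlas: RegionAtlas, region_ids: list[int] | None = None,
                strict: bool = False) -> pd.DataFrame:
    """Mean INT per region (arithmetic mean over voxels).

    ``strict=True`` drops censored voxels from the mean; the default keeps
    them (their INT is the truncated ACF sum) but reports the count.
    """
    if atlas.labels.shape[0] != imap.n_voxels:
        raise ValueError("atlas and map cover different voxel sets")
    ids = region_ids if region_ids is not None else atlas.region_ids
    rows = []
    for rid in ids:
        idx = atlas.voxels_of(int(rid))
        cens = imap.censored[idx]
        use = idx[~cens] if strict else idx
        if use.size == 0:
            raise ValueError(f"region {rid} has no usable voxels (all censored)")
        rows.append({
            "region_id": int(rid),
            "region_name": atlas.names.get(int(rid), str(rid)),
            "mean_int": float(imap.int_values[use].mean()),
            "n_voxels": int(idx.size),
            "n_censored": int(cens.sum()),
        })
    return pd.DataFrame(rows)


def build_hierarchy(region_means: pd.DataFrame | list[tuple[int, float]]) -> HierarchySpec:
    """Order regions ascending by mean INT (ties broken by region id)."""
    if isinstance(region_means, pd.DataFrame):
        pairs = list(zip(region_means["region_id"], region_means["mean_int"]))
    else:
        pairs = list(region_means)
    if len(pairs) < 2:
        raise ValueError("a hierarchy needs at least 2 regions")
    ordered = sorted(((int(r), float(m)) for r, m in pairs), key=lambda p: (p[1], p[0]))
    return HierarchySpec(ordered)
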