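"""Stability and similarity of maps and hierarchies across runs and subjects.

Map-level scores are means of Fisher z-transformed Pearson correlations:
within a subject across runs (intra-subject stability) and between run-averaged
subject maps (inter-subject similarity).  Hierarchy stability re-derives the
region ordering from every subject subset of a fixed size (4 of 9 subjects
gives the 126 combinations) and averages the Spearman rank correlation of each
subset ordering against the full-group ordering.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ScalarMap
from .timescales import HierarchySpec

FISHER_EPS = 1e-7


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher z-transform, atanh(r), with |r| clipped to 1 - 1e-7.

    The clip keeps comparisons of identical maps finite; the inverse maps the
    clipped maximum back to >= 1 - 2e-7.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -(1 - FISHER_EPS), 1 - FISHER_EPS))
    return float(z) if z.ndim == 0 else z


def inverse_fisher_z(z: float | np.ndarray) -> float | np.ndarray:
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def intra_subject_stability(run_maps: list[ScalarMap | np.ndarray]) -> float:
    """Mean Fisher z over all pairwise run-map correlations of one subject."""
    arrs = [m.values if isinstance(m, ScalarMap) else np.asarray(m, float) for m in run_maps]
    if len(arrs) < 2:
        raise ValueError("intra-subject stability needs at least 2 runs")
    zs = [fisher_z(_pearson(a, b)) for a, b in combinations(arrs, 2)]
    return float(np.mean(zs))


def inter_subject_similarity(subject_maps: list[ScalarMap | np.ndarray]) -> np.ndarray:
    """Per-subject mean Fisher z against all other subjects' run-averaged maps."""
    arrs = [m.values if isinstance(m, ScalarMap) else np.asarray(m, float) for m in subject_maps]
    n = len(arrs)
    if n < 2:
        raise ValueError("inter-subject similarity needs at least 2 subjects")
    z = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        z[i, j] = z[j, i] = fisher_z(_pearson(arrs[i], arrs[j]))
    return z.sum(axis=1) / (n - 1)


def hierarchy_stability(per_subject_region_means: pd.DataFrame | np.ndarray,
                        group_order: HierarchySpec | np.ndarray,
                        subset_size: int = 4) -> tuple[float, int]:
    """Mean Spearman rho between subset-derived and group region orderings.

    ``per_subject_region_means`` is subjects x regions (DataFrame columns are
    region ids in the group-table order).  Every subject subset of
    ``subset_size`` is enumerated once, lexicographically; each subset's
    region means are averaged, and their ranking is correlated (Spearman,
    average ranks on ties) with the group-level ordering.
    """
    if isinstance(per_subject_region_means, pd.DataFrame):
        table = per_subject_region_means.to_numpy(dtype=float)
        region_ids = [int(c) for c in per_subject_region_means.columns]
    else:
        table = np.asarray(per_subject_region_means, dtype=float)
        region_ids = list(range(table.shape[1]))
    n_subjects, n_regions = table.shape
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if not 1 <= subset_size < n_subjects:
        raise ValueError("subset_size must be smaller than the number of subjects")
    if isinstance(group_order, HierarchySpec):
        rank_of = {rid: pos for pos, rid in enumerate(group_order.region_ids)}
        group_ranks = np.array([rank_of[r] for r in region_ids], dtype=float)
    else:
        group_ranks = np.asarray(group_order, dtype=float)
    rhos = []
    for subset in combinations(range(n_subjects), subset_size):
        subset_means = table[list(subset)].mean(axis=0)
        rho = stats.spearmanr(subset_means, group_ranks).statistic
        rhos.append(rho)
    count = comb(n_subjects, subset_size)
    assert len(rhos) == count
    return float(np.mean(rhos)), count


@dataclass
class ReliabilityReport:
    """Bundle of map- and hierarchy-level reliability scores."""

    intra_subject_stability: dict[str, float]
    inter_subject_similarity: dict[str, float]
    hierarchy_stability_score: float
    subset_size: int
    subset_count: int

    def to_dict(self) -> dict:
        return asdict(self)


def reliability_report(run_maps_by_subject: dict[str, list[np.ndarray]],
                       per_subject_region_means: pd.DataFrame,
                       group_order: HierarchySpec,
                       subset_size: int = 4) -> ReliabilityReport:
    """Compute the full reliability bundle for a multi-subject dataset."""
    intra = {s: intra_subject_stability(maps) for s, maps in run_maps_by_subject.items()
             if len(maps) >= 2}
    subjects = list(run_maps_by_subject)
    subj_maps = [np.mean(np.stack(run_maps_by_subject[s]), axis=0) for s in subjects]
    if len(subjects) >= 2:
        inter_scores = inter_subject_similarity(subj_maps)
        inter = {s: float(v) for s, v in zip(subjects, inter_scores)}
    else:
        inter = {}
    score, count = hierarchy_stability(per_subject_region_means, group_order, subset_size)
    return ReliabilityReport(
        intra_subject_stability=intra,
        inter_subject_similarity=inter,
        hierarchy_stability_score=score,
        subset_size=subset_size,
        subset_count=count,
    )
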