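"""End-to-end orchestration: INT maps -> hierarchy -> FC gradients -> coupling.

The pipeline reproduces the analysis order of the method: per-run voxelwise
INT maps averaged up run -> subject -> group; region means and the INT
hierarchy; per-run FC combined in Fisher-z space to subject and group level;
sparsified cosine-affinity diffusion gradients; the gradient most correlated
with the INT map; and the reliability bundle (intra-subject stability,
inter-subject similarity, combinatorial hierarchy stability).

``analyze`` is the in-memory core; ``run_pipeline`` wraps it with NIfTI/CSV
I/O, provenance sidecars and a JSON summary for shell use.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gradients as gr
from . import io as nio
from . import reliability as rel
from . import timescales as ts
from . import topography as topo
from .containers import RegionAtlas, VoxelTimeSeries

log = logging.getLogger("inttopo")


@dataclass
class StageParams:
    max_lag: int | None = None
    density: float = 0.10
    n_components: int = 10
    alpha: float = 0.5
    diffusion_time: float = 0.0
    top_k: int = 10
    subset_size: int = 4

    def validate(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.n_components < 1 or self.top_k < 1 or self.subset_size < 1:
            raise ValueError("counts must be positive")
        if self.max_lag is not None and self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")


@dataclass
class PipelineConfig:
    """File-level configuration: per-subject run paths plus stage parameters."""

    runs: dict[str, list[str]]
    mask: str
    atlas: str
    out_dir: str
    tr_seconds: float | None = None
    params: StageParams = field(default_factory=StageParams)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = StageParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def validate(self) -> None:
        self.params.validate()
        missing = [p for p in [self.mask, self.atlas, *sum(self.runs.values(), [])]
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if not self.runs:
            raise ValueError("no runs configured")

    def to_dict(self) -> dict:
        return asdict(self)


def analyze(runs_by_subject: dict[str, list[VoxelTimeSeries]], atlas: RegionAtlas,
            params: StageParams | None = None) -> dict:
    """Run every analysis stage in memory and return objects + summary.

    Returns a dict with the group ``IntMap``, region table, ``HierarchySpec``,
    group FC, ``GradientSet``, best-gradient coupling, the
    ``ReliabilityReport`` (when >= 2 subjects with >= 2 runs), and a
    JSON-serialisable ``summary``.
    """
    params = params or StageParams()
    params.validate()
    subjects = sorted(runs_by_subject)
    if not subjects:
        raise ValueError("no subjects provided")

    log.info("INT stage: %d subjects", len(subjects))
    subj_int_maps: dict[str, ts.IntMap] = {}
    run_int_values: dict[str, list[np.ndarray]] = {}
    for s in subjects:
        runs = runs_by_subject[s]
        subj_int_maps[s] = ts.int_map(runs, max_lag=params.max_lag)
        run_int_values[s] = [ts.int_map([r], max_lag=params.max_lag).int_values for r in runs]
    group_int = ts.IntMap(
        int_values=np.mean([m.int_values for m in subj_int_maps.values()], axis=0),
        crossing_lags=np.mean([m.crossing_lags for m in subj_int_maps.values()], axis=0),
        censored=np.logical_and.reduce([m.censored for m in subj_int_maps.values()]),
        tr_seconds=runs_by_subject[subjects[0]][0].tr_seconds,
        n_runs=sum(len(v) for v in runs_by_subject.values()),
    )

    region_table = ts.region_mean(group_int, atlas)
    hierarchy = ts.build_hierarchy(region_table)

    log.info("FC stage")
    subj_fc = [gr.group_fc([gr.fc_matrix(r) for r in runs_by_subject[s]]) for s in subjects]
    fc_group = gr.group_fc(subj_fc)
    affinity = gr.cosine_affinity(gr.sparsify(fc_group, params.density))
    n_comp = min(params.n_components, affinity.n_voxels - 1)
    grads = gr.diffusion_embedding(affinity, n_comp, params.alpha, params.diffusion_time)

    best_idx, best_r = topo.best_gradient(group_int.int_values, grads)
    coupling = topo.map_correlation(group_int.int_values, grads.component(best_idx))

    report = None
    if len(subjects) >= 2:
        per_subject_means = pd.DataFrame(
            {int(rid): [float(ts.region_mean(subj_int_maps[s], atlas)
                              .set_index("region_id").loc[rid, "mean_int"]) for s in subjects]
             for rid in atlas.region_ids})
        subset_size = min(params.subset_size, len(subjects) - 1)
        report = rel.reliability_report(
            {s: run_int_values[s] for s in subjects if len(run_int_values[s]) >= 2},
            per_subject_means, hierarchy, subset_size)

    summary = {
        "n_subjects": len(subjects),
        "n_voxels": int(group_int.n_voxels),
        "hierarchy": [{"region_id": r, "mean_int": m} for r, m in hierarchy.ordering],
        "censored_voxels": int(group_int.censored.sum()),
        "best_gradient": {"component": best_idx, "r": coupling.r, "abs_r": coupling.abs_r,
                          "n_voxels": coupling.n_voxels},
        "eigenvalues": grads.eigenvalues.tolist(),
        "reliability": report.to_dict() if report else None,
    }
    return {
        "group_int": group_int,
        "subject_int_maps": subj_int_maps,
        "region_table": region_table,
        "hierarchy": hierarchy,
        "fc_group": fc_group,
        "affinity": affinity,
        "gradients": grads,
        "summary": summary,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Validate, load volumes, run ``analyze`` and write all artifacts."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    runs_by_subject: dict[str, list[VoxelTimeSeries]] = {}
    for s, paths in config.runs.items():
        runs_by_subject[s] = [
            nio.read_timeseries(p, config.mask, config.tr_seconds, s, f"run-{i + 1:02d}")
            for i, p in enumerate(paths)]
    atlas = nio.read_atlas(config.atlas, config.mask)
    res = analyze(runs_by_subject, atlas, config.params)

    coords = runs_by_subject[sorted(runs_by_subject)[0]][0].voxel_coords
    cfg = config.to_dict()
    gi: ts.IntMap = res["group_int"]
    nio.write_scalar_map(gi.int_values, coords, out / "int_map.nii.gz")
    nio.write_scalar_map(gi.time_constants(), coords, out / "time_constant_map.nii.gz")
    nio.write_scalar_map(gi.crossing_lags, coords, out / "crossing_lag_map.nii.gz")
    for name in ("int_map", "time_constant_map", "crossing_lag_map"):
        nio.write_sidecar(out / f"{name}.nii.gz", cfg, "timescales")
    res["region_table"].to_csv(out / "region_means.csv", index=False)
    grads: gr.GradientSet = res["gradients"]
    for i in range(min(2, grads.n_components)):
        p = out / f"gradient_{i + 1}.nii.gz"
        nio.write_scalar_map(grads.components[i], coords, p)
        nio.write_sidecar(p, cfg, "gradients")
    pd.DataFrame({"component": np.arange(1, grads.n_components + 1),
                  "eigenvalue": grads.eigenvalues}).to_csv(out / "eigenvalues.csv", index=False)
    (out / "summary.json").write_text(json.dumps(res["summary"], indent=2))
    nio.write_sidecar(out / "summary.json", cfg, "pipeline")
    return res["summary"]
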