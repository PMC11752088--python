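"""End-to-end orchestration: simulate -> fit -> regions -> stats.

Each subject is processed in a streaming fashion (simulate the DWI, fit the
maps, aggregate the regional means, release the volumes) so a full cohort
fits comfortably in memory.  All randomness derives from the master seed:
phantom construction uses per-subject spawned seed sequences and the DWI
noise stream is derived from the stored subject seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dictfit import FitConfig, fit_volume
from .phantom import CohortConfig, PhantomSubject, generate_cohort, simulate_dwi
from .regions import regional_table
from .scheme import GradientScheme, build_default_scheme
from .stats import (group_comparison_table, regression_battery,
                    within_subject_battery)

__all__ = ["RunConfig", "run_subject", "run_cohort_analysis", "cohort_summary"]

MEASURES = ("f_is", "f_in", "f_ec", "r_s")


@dataclass
class RunConfig:
    """Full-pipeline configuration with provenance-friendly serialization."""

    master_seed: int = 1
    cohort: CohortConfig = None
    fit: FitConfig = None
    delta_ms: float = 8.0
    Delta_ms: float = 19.0
    min_region_voxels: int = 3

    def __post_init__(self) -> None:
        if self.cohort is None:
            self.cohort = CohortConfig(master_seed=self.master_seed)
        if self.fit is None:
            # fixed default diffusivities for the analysis fit
            self.fit = FitConfig.pipeline_default()

    def to_dict(self) -> dict:
        d = {"master_seed": self.master_seed,
             "delta_ms": self.delta_ms, "Delta_ms": self.Delta_ms,
             "min_region_voxels": self.min_region_voxels,
             "cohort": asdict(self.cohort), "fit": asdict(self.fit)}
        return json.loads(json.dumps(d, default=float))


def _sim_rng(subject: PhantomSubject) -> np.random.Generator:
    """The subject's DWI-noise stream, derived from its stored seed."""
    return np.random.default_rng(np.random.SeedSequence([subject.seed, 1]))


def run_subject(subject: PhantomSubject, scheme: GradientScheme,
                cohort_cfg: CohortConfig, fit_cfg: FitConfig,
                min_region_voxels: int = 3,
                keep_volumes: bool = False) -> pd.DataFrame:
    """Simulate, fit and aggregate one subject; returns its regional rows."""
    simulate_dwi(subject, scheme, cohort_cfg, _sim_rng(subject))
    mask = subject.cortex_pv > 0
    maps = fit_volume(subject.dwi, scheme, mask, fit_cfg)
    icv_ml = float(subject.brain_pv.sum()) * \
        subject.geometry_config.analysis_voxel_mm ** 3 / 1000.0
    table = regional_table(
        maps, subject.masks,
        {"subject_id": subject.subject_id, "group": subject.group,
         "age": subject.age, "sex": subject.sex},
        min_voxels=min_region_voxels, icv_ml=icv_ml)
    if keep_volumes:
        subject.maps = maps            # type: ignore[attr-defined]
    else:
        subject.dwi = None
    return table


def cohort_summary(region_table: pd.DataFrame,
                   subjects: list[PhantomSubject]) -> dict:
    """Cohort-level quantities: region-mean averages and lesion burden."""
    out = {"regions": {}, "lesions": {}}
    for group in ("MS", "HC"):
        gt = region_table[(region_table.group == group) & region_table["valid"]]
        for region in gt.region.unique():
            for measure in MEASURES:
                v = gt[(gt.region == region) & (gt.measure == measure)]["mean"]
                if v.size:
                    out["regions"][f"{group}:{region}:{measure}"] = {
                        "mean": float(v.mean()), "sd": float(v.std(ddof=1)),
                        "n": int(v.size)}
    ms = [s for s in subjects if s.group == "MS"]
    if ms:
        counts = [s.n_lesions for s in ms]
        vols = [s.total_lesion_volume_ml for s in ms]
        out["lesions"] = {
            "count_median": float(np.median(counts)),
            "count_iqr": [float(np.percentile(counts, 25)),
                          float(np.percentile(counts, 75))],
            "volume_ml_median": float(np.median(vols)),
            "volume_ml_iqr": [float(np.percentile(vols, 25)),
                              float(np.percentile(vols, 75))]}
    return out


def run_cohort_analysis(config: RunConfig | None = None,
                        out_dir: str | Path | None = None,
                        verbose: bool = False) -> dict:
    """The full pipeline on a fresh synthetic cohort.

    Returns a dict with the regional table, the group-comparison and
    within-subject statistics and the machine-readable summary; optionally
    writes everything (TSV + JSON) into ``out_dir``.
    """
    config = config or RunConfig()
    scheme = build_default_scheme(delta=config.delta_ms, Delta=config.Delta_ms)
    t0 = time.time()
    subjects, manifest = generate_cohort(config.cohort)
    tables = []
    for i, subject in enumerate(subjects):
        tables.append(run_subject(subject, scheme, config.cohort, config.fit,
                                  config.min_region_voxels))
        # release the per-subject volumes; burden records and the regional
        # rows carry everything the cohort statistics need
        subject.dwi = None
        subject.truth = None
        subject.labels = None
        subject.pv = None
        if verbose and (i + 1) % 10 == 0:
            print(f"  fitted {i + 1}/{len(subjects)} subjects "
                  f"({time.time() - t0:.0f}s)")
    region_table = pd.concat(tables, ignore_index=True)
    group_stats = group_comparison_table(region_table)
    entire_cortex = group_comparison_table(
        region_table, regions=("cortex",), family="group_entire")
    within = within_subject_battery(region_table)
    lesion_volumes = pd.Series({s.subject_id: s.total_lesion_volume_ml
                                for s in subjects if s.group == "MS"})
    regressions = regression_battery(region_table, lesion_volumes)
    summary = cohort_summary(region_table, subjects)
    summary["config"] = config.to_dict()
    summary["runtime_s"] = round(time.time() - t0, 1)
    result = {"region_table": region_table, "group_stats": group_stats,
              "entire_cortex_stats": entire_cortex,
              "within_anova": within["anova"],
              "within_posthoc": within["posthoc"],
              "regression_stats": regressions,
              "summary": summary, "manifest": manifest,
              "subjects": subjects}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        region_table.to_csv(out / "region_table.tsv", sep="\t", index=False)
        group_stats.to_csv(out / "group_stats.tsv", sep="\t", index=False)
        entire_cortex.to_csv(out / "entire_cortex_stats.tsv", sep="\t", index=False)
        within["anova"].to_csv(out / "within_anova.tsv", sep="\t", index=False)
        within["posthoc"].to_csv(out / "within_posthoc.tsv", sep="\t", index=False)
        regressions.to_csv(out / "regression_stats.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        with open(out / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=1)
    return result
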