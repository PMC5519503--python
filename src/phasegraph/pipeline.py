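"""End-to-end pipeline: BOLD time series -> phase FC -> graph metrics -> PET association.

`run_pipeline` wires the library stages together for one or more subjects,
persists every intermediate as delimited text plus a JSON manifest, and is
what the command-line interface wraps.  Stage order:

1. multiscale phase decomposition of each subject's regional time series;
2. dynamic and static pairwise phase-synchrony FC per scale;
3. cost-efficiency threshold selection (per subject, averaged across the
   threshold cohort in ``group_mean`` mode) and thresholding;
4. static node metrics per subject, averaged to a population table;
5. per-timepoint node metrics, temporal CV per subject, averaged;
6. repeated-measures GLM of each metric (static and CV) on the PET
   covariates, single-covariate and combined models, plus per-scale
   post-hoc (partial) correlations with Bonferroni control.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import dynamic_fc, static_fc
from .graph import (METRICS, NodeMetricTable, ThresholdSpec, apply_threshold,
                    compute_dynamic_metrics, compute_metric_table,
                    cost_efficiency_threshold, group_mean_threshold)
from .io import RegionalPetVector, RoiTimeSeries, read_pet_tsv, \
    read_timeseries_tsv, write_matrix_tsv
from .stability import stability_from_dynamic, subject_average
from .stats import posthoc_correlations, rm_glm
from .wavelets import max_scales, multiscale_phase

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """The pipeline configuration is incomplete or inconsistent."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``bold`` may be in-memory :class:`RoiTimeSeries` objects or TSV paths
    (region-by-time matrices written by :func:`~phasegraph.io.write_matrix_tsv`);
    likewise the PET vectors.  ``threshold_bold`` optionally names an
    independent cohort used only for threshold selection (``group_mean``
    mode); if absent the analysis cohort doubles as the threshold cohort.
    """

    out_dir: str | Path = "phasegraph_out"
    bold: Sequence = ()
    tr_seconds: float | None = None
    pet_rcps: object = None
    pet_suv: object = None
    threshold_bold: Sequence = ()
    n_scales: int | None = None
    design_order: int = 3
    decimation_factor: int = 4
    threshold_mode: str = "group_mean"  # group_mean | per_subject | fixed
    fixed_threshold: float | None = None
    cost_grid: Sequence[float] | None = None
    dynamic_scales: Sequence[int] | None = None
    dynamic_metrics: Sequence[str] = METRICS
    exclude_boundary: bool = True
    bonferroni_family: int | None = None
    seed: int = 0
    write_static_fc: bool = True

    def echo(self) -> dict:
        d = asdict(self)
        d["bold"] = [str(b) if isinstance(b, (str, Path)) else "<in-memory>"
                     for b in self.bold]
        d["threshold_bold"] = [str(b) if isinstance(b, (str, Path))
                               else "<in-memory>" for b in self.threshold_bold]
        for key in ("pet_rcps", "pet_suv"):
            v = d[key]
            d[key] = str(v) if isinstance(v, (str, Path)) else (
                None if v is None else "<in-memory>")
        d["out_dir"] = str(self.out_dir)
        d["cost_grid"] = None if self.cost_grid is None else list(
            map(float, self.cost_grid))
        d["dynamic_metrics"] = list(self.dynamic_metrics)
        d["dynamic_scales"] = None if self.dynamic_scales is None else list(
            map(int, self.dynamic_scales))
        return d


def _load_bold(entry, tr_seconds) -> RoiTimeSeries:
    if isinstance(entry, RoiTimeSeries):
        return entry
    if tr_seconds is None:
        raise ConfigurationError("tr_seconds required for TSV inputs")
    return read_timeseries_tsv(entry, tr_seconds)


def _load_pet(entry, tracer: str) -> RegionalPetVector | None:
    if entry is None:
        return None
    if isinstance(entry, RegionalPetVector):
        return entry
    return read_pet_tsv(entry, tracer)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts under ``out_dir``.

    Returns a results dictionary with the in-memory tables (static metric
    table, stability table, association results and post-hoc frames) plus
    the manifest.  Raises :class:`ConfigurationError` before any computation
    if required inputs are missing.
    """
    if not config.bold:
        raise ConfigurationError("no BOLD inputs configured")
    if config.threshold_mode not in ("group_mean", "per_subject", "fixed"):
        raise ConfigurationError(
            f"unknown threshold mode {config.threshold_mode!r}")
    if config.threshold_mode == "fixed" and config.fixed_threshold is None:
        raise ConfigurationError("fixed threshold mode needs fixed_threshold")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timing: dict[str, float] = {}
    t0 = time.perf_counter()

    subjects = [_load_bold(b, config.tr_seconds) for b in config.bold]
    tr = subjects[0].tr_seconds
    region_ids = subjects[0].region_ids
    for s in subjects:
        if not np.array_equal(s.region_ids, region_ids):
            raise ConfigurationError("subjects have different region orders")
    pet_rcps = _load_pet(config.pet_rcps, "rCPS")
    pet_suv = _load_pet(config.pet_suv, "SUV")
    n_scales = config.n_scales or max_scales(subjects[0].n_timepoints)
    scales = list(range(1, n_scales + 1))
    dynamic_scales = list(config.dynamic_scales or scales)
    timing["load"] = time.perf_counter() - t0

    # --- stage 1-2: phase decomposition and FC ----------------------------
    t0 = time.perf_counter()
    phases = [multiscale_phase(s, n_scales, config.design_order,
                               config.decimation_factor) for s in subjects]
    static_by_subject = []  # list of dict scale -> StaticFC
    for ph in phases:
        fcs = {}
        for j in scales:
            fcs[j] = static_fc(dynamic_fc(ph, j))
        static_by_subject.append(fcs)
    timing["phase_fc"] = time.perf_counter() - t0
    logger.info("phase + FC stage: %.1fs", timing["phase_fc"])

    # --- stage 3: thresholds ----------------------------------------------
    t0 = time.perf_counter()
    specs: dict[int, ThresholdSpec] = {}
    if config.threshold_mode == "fixed":
        for j in scales:
            specs[j] = ThresholdSpec(scale_index=j,
                                     threshold_value=config.fixed_threshold,
                                     cost_at_threshold=np.nan,
                                     provenance="fixed")
    else:
        if config.threshold_bold:
            thr_subjects = [_load_bold(b, config.tr_seconds)
                            for b in config.threshold_bold]
            thr_fcs = []
            for s in thr_subjects:
                ph = multiscale_phase(s, n_scales, config.design_order,
                                      config.decimation_factor)
                thr_fcs.append({j: static_fc(dynamic_fc(ph, j))
                                for j in scales})
        else:
            thr_fcs = static_by_subject
        for j in scales:
            per_subject = [cost_efficiency_threshold(f[j], config.cost_grid)
                           for f in thr_fcs]
            specs[j] = (per_subject[0] if config.threshold_mode == "per_subject"
                        and len(per_subject) == 1
                        else group_mean_threshold(per_subject))
    pd.DataFrame(
        [(j, specs[j].threshold_value, specs[j].cost_at_threshold,
          specs[j].provenance) for j in scales],
        columns=["scale", "threshold", "cost", "provenance"],
    ).to_csv(out / "thresholds.tsv", sep="\t", index=False)
    timing["thresholds"] = time.perf_counter() - t0

    # --- stage 4: static metrics -------------------------------------------
    t0 = time.perf_counter()
    static_tables = [
        compute_metric_table(fcs, specs, region_ids=region_ids)
        for fcs in static_by_subject
    ]
    static_table: NodeMetricTable = subject_average(static_tables)
    static_table.to_long_dataframe().to_csv(
        out / "node_metrics_static.tsv", sep="\t", index=False)
    if config.write_static_fc:
        for j in scales:
            mean_fc = np.mean([f[j].matrix for f in static_by_subject], axis=0)
            write_matrix_tsv(out / f"static_fc_scale{j:02d}.tsv",
                             mean_fc, region_ids)
    timing["static_metrics"] = time.perf_counter() - t0

    # --- stage 5: dynamic metrics and stability ----------------------------
    t0 = time.perf_counter()
    cv_tables = []
    for ph in phases:
        stack = np.stack([
            compute_dynamic_metrics(dynamic_fc(ph, j), specs[j],
                                    config.dynamic_metrics)
            for j in dynamic_scales
        ])
        valid = (~ph.boundary[[j - 1 for j in dynamic_scales]]
                 if config.exclude_boundary else None)
        cv_tables.append(
            stability_from_dynamic(stack, valid,
                                   metrics=tuple(config.dynamic_metrics),
                                   scales=dynamic_scales))
    cv_table = subject_average(cv_tables)
    cv_long = []
    for si, scale in enumerate(dynamic_scales):
        for mi, metric in enumerate(cv_table.metrics):
            for ri, region in enumerate(region_ids):
                cv_long.append((region, scale, metric,
                                cv_table.cv[ri, mi, si]))
    pd.DataFrame(cv_long, columns=["region", "scale", "metric", "value"]) \
        .to_csv(out / "stability_cv.tsv", sep="\t", index=False)
    timing["dynamic_stability"] = time.perf_counter() - t0
    logger.info("dynamic + stability stage: %.1fs", timing["dynamic_stability"])

    # --- stage 6: association statistics -----------------------------------
    t0 = time.perf_counter()
    covariate_sets = []
    if pet_rcps is not None:
        covariate_sets.append(("rCPS", [pet_rcps]))
    if pet_suv is not None:
        covariate_sets.append(("SUV", [pet_suv]))
    if pet_rcps is not None and pet_suv is not None:
        covariate_sets.append(("rCPS+SUV", [pet_rcps, pet_suv]))

    family = config.bonferroni_family or n_scales * len(METRICS)
    associations, posthocs = {}, {}
    for table_name, table, metric_set, table_scales in (
        ("static", static_table, METRICS, scales),
        ("cv", cv_table, tuple(config.dynamic_metrics), dynamic_scales),
    ):
        frames = []
        for metric in metric_set:
            y = (table.metric_by_scale(metric) if table_name == "static"
                 else table.metric_by_scale(metric))
            y = np.nan_to_num(y, nan=0.0)
            for set_name, covs in covariate_sets:
                res = rm_glm(y, covs, metric=metric)
                associations[(table_name, metric, set_name)] = res
                frame = res.to_dataframe()
                frame.insert(0, "model", set_name)
                frame.insert(0, "table", table_name)
                frames.append(frame)
            if pet_rcps is not None:
                ph_frame = posthoc_correlations(
                    y, pet_rcps, control=pet_suv,
                    n_comparisons=family, scales=table_scales)
                ph_frame.insert(0, "metric", metric)
                ph_frame.insert(0, "table", table_name)
                posthocs[(table_name, metric)] = ph_frame
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out / f"associations_{table_name}.tsv", sep="\t", index=False)
    if posthocs:
        pd.concat(posthocs.values(), ignore_index=True).to_csv(
            out / "posthoc_correlations.tsv", sep="\t", index=False)
    timing["associations"] = time.perf_counter() - t0

    # --- manifest -----------------------------------------------------------
    import networkx
    import scipy

    manifest = {
        "phasegraph_version": __version__,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__,
                     "networkx": networkx.__version__},
        "seed": config.seed,
        "config": config.echo(),
        "n_subjects": len(subjects),
        "n_regions": int(len(region_ids)),
        "region_order": [int(r) for r in region_ids],
        "tr_seconds": float(tr),
        "n_scales": int(n_scales),
        "bands_hz": [[b.f_lo, b.f_hi] for b in phases[0].bands],
        "timing_seconds": {k: round(v, 3) for k, v in timing.items()},
    }
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))

    return {
        "manifest": manifest,
        "thresholds": specs,
        "static_table": static_table,
        "cv_table": cv_table,
        "associations": associations,
        "posthoc": posthocs,
    }
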