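"""Temporal stability of node metrics across dynamic-FC timepoints.

Stability is quantified as the coefficient of variation (population standard
deviation divided by mean) of each node metric's time course, computed per
region, metric and scale, then averaged across subjects.  A small CV means
the metric -- e.g. a region's hub status -- persists over time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import DimensionError
from .graph import METRICS, NodeMetricTable
from .wavelets import ParameterError

#: |mean| below this floor makes the CV undefined; such entries are NaN.
MEAN_FLOOR = 1e-12


@dataclass
class StabilityTable:
    """Temporal CV per region, metric and scale, shape (n_regions, n_metrics, n_scales).

    Entries are NaN where the temporal mean was below the documented floor.
    """

    cv: np.ndarray
    n_timepoints_used: int
    metrics: tuple = METRICS
    scales: Sequence[int] = None

    def metric_by_scale(self, metric: str) -> np.ndarray:
        return self.cv[:, self.metrics.index(metric), :]


def temporal_cv(metric_series: np.ndarray, axis: int = -1) -> np.ndarray:
    """Population sd / mean along ``axis``; NaN where |mean| < 1e-12."""
    x = np.asarray(metric_series, dtype=float)
    if x.shape[axis] < 2:
        raise ParameterError("need at least 2 timepoints for a CV")
    mean = x.mean(axis=axis)
    sd = x.std(axis=axis)  # population (ddof=0) by convention
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(np.abs(mean) < MEAN_FLOOR, np.nan, sd / mean)
    return cv


def stability_from_dynamic(metric_stack: np.ndarray,
                           valid_timepoints: np.ndarray | None = None,
                           metrics: tuple = METRICS,
                           scales: Sequence[int] | None = None) -> StabilityTable:
    """CV over time of a dynamic metric stack.

    Parameters
    ----------
    metric_stack : ndarray, shape (n_scales, T, n_regions, n_metrics)
        Per-timepoint node metrics per scale.
    valid_timepoints : bool ndarray (n_scales, T), optional
        Timepoints to include (e.g. excluding wavelet/FIR boundary samples).
        If a scale would retain fewer than half its timepoints, all are kept
        for that scale instead.
    """
    stack = np.asarray(metric_stack, dtype=float)
    n_scales, t = stack.shape[0], stack.shape[1]
    cv = np.empty((stack.shape[2], stack.shape[3], n_scales))
    used = t
    for s in range(n_scales):
        keep = np.ones(t, dtype=bool)
        if valid_timepoints is not None:
            cand = np.asarray(valid_timepoints[s], dtype=bool)
            if cand.sum() >= t // 2 and cand.sum() >= 2:
                keep = cand
        used = min(used, int(keep.sum()))
        cv[:, :, s] = temporal_cv(stack[s][keep], axis=0)
    return StabilityTable(cv=cv, n_timepoints_used=used, metrics=metrics,
                          scales=scales)


def subject_average(tables: Sequence) -> object:
    """Elementwise mean of per-subject tables, ignoring NaN entries.

    Accepts a list of :class:`StabilityTable` or
    :class:`~phasegraph.graph.NodeMetricTable` with identical shapes; returns
    a table of the same type.  Entries that are NaN in every subject stay
    NaN.
    """
    if not tables:
        raise ParameterError("no tables to average")
    first = tables[0]
    is_stability = isinstance(first, StabilityTable)
    arrays = [t.cv if is_stability else t.values for t in tables]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise DimensionError(f"table shapes differ: {shapes}")
    stacked = np.stack(arrays)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    if is_stability:
        return StabilityTable(
            cv=mean,
            n_timepoints_used=min(t.n_timepoints_used for t in tables),
            metrics=first.metrics, scales=first.scales,
        )
    return NodeMetricTable(values=mean, metrics=first.metrics,
                           scales=first.scales, region_ids=first.region_ids)
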