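"""Weighted graph metrics on thresholded phase-synchrony networks.

Thresholds are chosen by maximizing cost-efficiency: for each candidate
wiring cost k (fraction of retained edges) the FC matrix is binarized at the
corresponding weight quantile, the binary global efficiency E_glob is
computed, and the score E_glob - k is maximized (ties resolved toward the
sparser graph).  The surviving weights are retained, so all node metrics are
computed on weighted graphs.

Metric conventions (the literature admits several weighted generalizations;
these are fixed here and used throughout):

* node strength: sum of incident edge weights;
* clustering coefficient: geometric-mean (Onnela) triangle intensity over
  connected triples, on weights max-normalized per graph;
* local efficiency: binary-degree neighbourhood, weighted global efficiency
  of the subgraph induced by a node's neighbours;
* betweenness centrality: unnormalized shortest-path counts with fractional
  credit for ties (Brandes);

with shortest-path lengths defined as reciprocal weights (strong synchrony =
short distance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra, shortest_path

from .connectivity import StaticFC, SyncSeries
from .wavelets import ParameterError

logger = logging.getLogger(__name__)

METRICS = (
    "clustering_coefficient",
    "local_efficiency",
    "node_strength",
    "betweenness_centrality",
)

DEFAULT_COST_GRID = np.round(np.arange(0.05, 0.5001, 0.01), 10)


@dataclass
class ThresholdSpec:
    """A weight threshold with the cost it achieves and where it came from."""

    scale_index: int
    threshold_value: float
    cost_at_threshold: float
    provenance: str = "per_subject"  # per_subject | group_mean | fixed


@dataclass
class NodeMetricTable:
    """Per-region, per-metric, per-scale values, shape (n_regions, n_metrics, n_scales)."""

    values: np.ndarray
    metrics: tuple = METRICS
    scales: Sequence[int] = None
    region_ids: Sequence[int] = None

    def __post_init__(self) -> None:
        if self.scales is None:
            self.scales = list(range(1, self.values.shape[2] + 1))
        if self.region_ids is None:
            self.region_ids = list(range(1, self.values.shape[0] + 1))

    def metric_by_scale(self, metric: str) -> np.ndarray:
        """(n_regions, n_scales) slice for one metric."""
        return self.values[:, self.metrics.index(metric), :]

    def to_long_dataframe(self) -> pd.DataFrame:
        rows = []
        for si, scale in enumerate(self.scales):
            for mi, metric in enumerate(self.metrics):
                for ri, region in enumerate(self.region_ids):
                    rows.append((region, scale, metric, self.values[ri, mi, si]))
        return pd.DataFrame(rows, columns=["region", "scale", "metric", "value"])


# ---------------------------------------------------------------------------
# thresholding


def _as_matrix(fc) -> np.ndarray:
    return fc.matrix if isinstance(fc, StaticFC) else np.asarray(fc, dtype=float)


def binary_global_efficiency(adj: np.ndarray) -> float:
    """Mean inverse shortest-path length of a binary graph (1/inf = 0)."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = shortest_path(adj.astype(float), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def cost_efficiency_threshold(fc, cost_grid: Iterable[float] | None = None,
                              scale_index: int | None = None) -> ThresholdSpec:
    """Threshold maximizing cost-efficiency ``E_glob(binary) - cost``.

    For each candidate cost the graph is binarized at the weight quantile
    retaining that fraction of the strongest edges.  Ties are broken toward
    the lower cost (sparser graph).
    """
    w = _as_matrix(fc)
    if scale_index is None:
        scale_index = getattr(fc, "scale_index", 0)
    grid = DEFAULT_COST_GRID if cost_grid is None else np.asarray(
        list(cost_grid), dtype=float)
    if grid.size == 0:
        raise ParameterError("cost grid is empty")
    if np.any(grid <= 0) or np.any(grid >= 1) or np.any(np.diff(grid) <= 0):
        raise ParameterError("cost grid must be ascending within (0, 1)")
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    weights = w[iu]
    scores = np.empty(len(grid))
    thresholds = np.empty(len(grid))
    for i, cost in enumerate(grid):
        thr = np.quantile(weights, 1.0 - cost)
        adj = (w >= thr).astype(float)
        np.fill_diagonal(adj, 0.0)
        scores[i] = binary_global_efficiency(adj) - cost
        thresholds[i] = thr
    best = int(np.argmax(scores))  # first maximum = lowest cost on ties
    thr = float(thresholds[best])
    adj = (w >= thr)
    np.fill_diagonal(adj, False)
    achieved = adj[iu].sum() / len(weights)
    d = shortest_path(adj.astype(float), method="D", unweighted=True)
    if not np.isfinite(d[iu]).all():
        warnings.warn(
            f"cost-efficiency optimum (cost {grid[best]:.2f}) leaves the "
            "graph disconnected"
        )
    return ThresholdSpec(scale_index=scale_index, threshold_value=thr,
                         cost_at_threshold=float(achieved))


def group_mean_threshold(specs: Sequence[ThresholdSpec]) -> ThresholdSpec:
    """Mean of per-subject thresholds, as applied to an independent cohort."""
    if not specs:
        raise ParameterError("no threshold specs to average")
    scale = specs[0].scale_index
    return ThresholdSpec(
        scale_index=scale,
        threshold_value=float(np.mean([s.threshold_value for s in specs])),
        cost_at_threshold=float(np.mean([s.cost_at_threshold for s in specs])),
        provenance="group_mean",
    )


def apply_threshold(fc, spec: ThresholdSpec) -> np.ndarray:
    """Zero weights below the threshold, keep surviving weights, zero diagonal."""
    w = _as_matrix(fc).copy()
    w[w < spec.threshold_value] = 0.0
    np.fill_diagonal(w, 0.0)
    return w


# ---------------------------------------------------------------------------
# node metrics


def node_strength(w: np.ndarray) -> np.ndarray:
    """Sum of incident link weights (diagonal excluded)."""
    w = np.asarray(w, dtype=float)
    s = w.sum(axis=1) - np.diag(w)
    return s


def clustering_coefficient(w: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering: geometric-mean triangle intensity.

    C_i = sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3) / (k_i (k_i - 1)) with weights
    max-normalized per graph and k_i the binary degree; 0 when k_i < 2.
    """
    w = np.asarray(w, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0])
    wn = (w / wmax) ** (1.0 / 3.0)
    triangles = np.diag(wn @ wn @ wn)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def _length_matrix(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = 1.0 / w
    lengths[~np.isfinite(lengths)] = 0.0  # csgraph: 0 = no edge
    return lengths


def local_efficiency(w: np.ndarray) -> np.ndarray:
    """Weighted global efficiency of each node's neighbourhood subgraph.

    Neighbours are defined by the binary adjacency; path lengths within the
    induced subgraph use reciprocal weights (max-normalized per graph so the
    result is bounded by 1 for weights in [0, 1]); 0 for fewer than 2
    neighbours.
    """
    w = np.asarray(w, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    wn = w / wmax
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(wn[i] > 0)
        k = len(nbrs)
        if k < 2:
            continue
        sub = wn[np.ix_(nbrs, nbrs)]
        d = dijkstra(_length_matrix(sub))
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        out[i] = inv.sum() / (k * (k - 1))
    return out


def betweenness_centrality(w: np.ndarray) -> np.ndarray:
    """Unnormalized weighted betweenness (edge length = 1/weight).

    Shortest-path ties share credit fractionally (Brandes accumulation);
    each unordered source-target pair contributes once.
    """
    w = np.asarray(w, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(w, k=1))
    g.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / w[i, j]) for i, j in zip(ii, jj)),
        weight="length",
    )
    bc = nx.betweenness_centrality(g, normalized=False, weight="length")
    return np.array([bc[i] for i in range(n)])


_METRIC_FUNCS = {
    "clustering_coefficient": clustering_coefficient,
    "local_efficiency": local_efficiency,
    "node_strength": node_strength,
    "betweenness_centrality": betweenness_centrality,
}


def compute_node_metrics(w: np.ndarray,
                         metrics: Sequence[str] = METRICS) -> np.ndarray:
    """All requested metrics of one weighted adjacency, shape (n, n_metrics)."""
    return np.column_stack([_METRIC_FUNCS[m](w) for m in metrics])


def compute_metric_table(fc_by_scale, specs, metrics: Sequence[str] = METRICS,
                         region_ids: Sequence[int] | None = None) -> NodeMetricTable:
    """Static metric table over scales.

    Parameters
    ----------
    fc_by_scale : mapping scale_index -> StaticFC (or matrix)
    specs : mapping scale_index -> ThresholdSpec
    """
    scales = sorted(fc_by_scale)
    first = _as_matrix(fc_by_scale[scales[0]])
    values = np.empty((first.shape[0], len(metrics), len(scales)))
    for si, scale in enumerate(scales):
        w = apply_threshold(fc_by_scale[scale], specs[scale])
        if w.max() == 0:
            logger.warning("scale %d: thresholded graph is empty", scale)
        values[:, :, si] = compute_node_metrics(w, metrics)
    return NodeMetricTable(values=values, metrics=tuple(metrics),
                           scales=scales, region_ids=region_ids)


def compute_dynamic_metrics(sync: SyncSeries, spec: ThresholdSpec,
                            metrics: Sequence[str] = METRICS) -> np.ndarray:
    """Per-timepoint metrics of a synchrony series, shape (T, n, n_metrics)."""
    n, _, t = sync.r_xy.shape
    out = np.empty((t, n, len(metrics)))
    for ti in range(t):
        w = apply_threshold(sync.r_xy[:, :, ti], spec)
        if w.max() == 0:
            logger.warning("timepoint %d: thresholded graph is empty", ti)
        out[ti] = compute_node_metrics(w, metrics)
    return out
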