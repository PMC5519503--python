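"""Pairwise phase-synchrony functional connectivity.

For two instantaneous phase series the synchrony at time t is the pairwise
Kuramoto order parameter

    R_xy(t) = | (exp(i*theta_x(t)) + exp(i*theta_y(t))) / 2 |
            = | cos((theta_x(t) - theta_y(t)) / 2) |,

a value in [0, 1]: 1 for identical phases, 0 in antiphase.  The modulus is
taken so that R can serve directly as a nonnegative connectivity weight.
Applying this to every region pair gives a time-resolved (dynamic) FC array;
its temporal mean is the static FC matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DimensionError
from .wavelets import MultiscalePhase


@dataclass
class SyncSeries:
    """Time-resolved pairwise synchrony, shape (n_regions, n_regions, T).

    Symmetric in the first two axes at every timepoint, diagonal 1, entries
    in [0, 1].
    """

    r_xy: np.ndarray
    scale_index: int

    @property
    def n_regions(self) -> int:
        return self.r_xy.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.r_xy.shape[2]


@dataclass
class StaticFC:
    """Time-averaged pairwise synchrony matrix (symmetric, unit diagonal)."""

    matrix: np.ndarray
    scale_index: int

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


def pairwise_kuramoto(theta_x: np.ndarray, theta_y: np.ndarray) -> np.ndarray:
    """Pairwise Kuramoto order parameter |cos((theta_x - theta_y)/2)|."""
    theta_x = np.asarray(theta_x, dtype=float)
    theta_y = np.asarray(theta_y, dtype=float)
    if theta_x.shape != theta_y.shape:
        raise DimensionError("phase series must have equal shapes")
    if not (np.isfinite(theta_x).all() and np.isfinite(theta_y).all()):
        raise ValueError("phases must be finite")
    return np.abs(np.cos((theta_x - theta_y) / 2.0))


def dynamic_fc(phases: MultiscalePhase, scale_index: int) -> SyncSeries:
    """Time-resolved synchrony matrix of one scale.

    Vectorized over all region pairs; symmetry and a unit diagonal hold by
    construction.
    """
    theta = phases.scale(scale_index)  # (n_regions, T)
    diff = theta[:, None, :] - theta[None, :, :]
    r = np.abs(np.cos(diff / 2.0))
    n = r.shape[0]
    r[np.arange(n), np.arange(n), :] = 1.0
    return SyncSeries(r_xy=r, scale_index=scale_index)


def static_fc(sync: SyncSeries) -> StaticFC:
    """Temporal mean of a synchrony series."""
    if sync.r_xy.shape[2] < 1:
        raise DimensionError("need at least one timepoint")
    return StaticFC(matrix=sync.r_xy.mean(axis=2), scale_index=sync.scale_index)
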