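"""Synthetic datasets with the structure the analysis pipeline assumes.

The generator plays the role of the experimental data: regional BOLD-like
signals are produced by a network of Kuramoto phase oscillators whose
coupling matrix contains planted hub regions (rows with systematically
stronger edges), and regional PET vectors (rCPS, SUV) are drawn from a
Gaussian copula so that rCPS correlates with ground-truth hubness and the
two tracers correlate with each other.  Defaults mirror the acquisition the
pipeline targets: 82 regions, TR = 0.72 s, 1200 volumes, intrinsic
oscillation in the 0.04-0.08 Hz band, and a between-tracer correlation of
0.63.

The observable is ``sin(theta) + white noise``; no haemodynamic convolution
is applied (an optional lowpass is available), so the synthetic signals test
the pipeline's numerics, not haemodynamic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .io import RegionalPetVector, RoiTimeSeries
from .wavelets import ParameterError


def make_planted_hub_network(n_regions: int = 82,
                             hub_ids=(0, 1, 2, 3),
                             base_weight: float = 0.1,
                             hub_weight: float = 0.3,
                             density: float = 0.15,
                             weight_jitter: float = 0.2,
                             seed: int | None = 0) -> np.ndarray:
    """Symmetric nonnegative coupling matrix with planted hub rows.

    A sparse background network (edge probability ``density``) carries
    weights around ``base_weight``; edges incident to a hub are both denser
    (probability ``min(1, 3 * density)``) and stronger (around
    ``hub_weight``), so hubs have systematically larger weighted degree, as
    highly connected cortical hub regions do.  ``weight_jitter`` is the
    relative (lognormal) spread of the weight draws.  Diagonal is zero.
    When ``hub_weight == base_weight`` and the densities coincide the
    network is exchangeable (no planted structure).
    """
    rng = np.random.default_rng(seed)
    hub_ids = np.asarray(hub_ids, dtype=int)
    if hub_ids.size and (hub_ids.min() < 0 or hub_ids.max() >= n_regions):
        raise ParameterError("hub_ids out of range")
    if not 0 < density <= 1:
        raise ParameterError("density must be in (0, 1]")
    is_hub = np.zeros(n_regions, dtype=bool)
    is_hub[hub_ids] = True
    hub_density = density if hub_weight == base_weight else min(1.0, 3 * density)
    hub_edge = is_hub[:, None] | is_hub[None, :]
    prob = np.where(hub_edge, hub_density, density)
    mean = np.where(hub_edge, hub_weight, base_weight)
    present = rng.random((n_regions, n_regions)) < prob
    jitter = rng.lognormal(mean=0.0, sigma=weight_jitter,
                           size=(n_regions, n_regions))
    w = np.where(present, mean * jitter, 0.0)
    w = np.triu(w, k=1)
    w = w + w.T
    return w


@dataclass
class SimulationSpec:
    """Parameters of one coupled-oscillator BOLD simulation."""

    n_regions: int = 82
    tr_seconds: float = 0.72
    n_timepoints: int = 1200
    coupling_matrix: np.ndarray | None = None
    global_coupling: float = 0.1
    intrinsic_freq_band: tuple = (0.04, 0.08)
    noise_sd: float = 0.3
    phase_noise_sd: float = 0.4
    hub_ids: tuple = (0, 1, 2, 3)
    seed: int = 0
    substeps: int = 10
    lowpass_hz: float | None = None

    def __post_init__(self) -> None:
        if self.coupling_matrix is None:
            self.coupling_matrix = make_planted_hub_network(
                self.n_regions, self.hub_ids, seed=self.seed)
        self.coupling_matrix = np.asarray(self.coupling_matrix, dtype=float)
        if self.coupling_matrix.shape != (self.n_regions, self.n_regions):
            raise ParameterError("coupling matrix shape mismatch")
        if np.any(np.diag(self.coupling_matrix) != 0):
            raise ParameterError("coupling matrix must have zero diagonal")
        if np.any(self.coupling_matrix < 0):
            raise ParameterError("coupling matrix must be nonnegative")
        if self.global_coupling < 0:
            raise ParameterError("global coupling must be >= 0")
        lo, hi = self.intrinsic_freq_band
        if not 0 < lo < hi <= 0.5 / self.tr_seconds:
            raise ParameterError(
                "intrinsic frequency band must lie within (0, Nyquist)")


def simulate_coupled_bold(spec: SimulationSpec) -> RoiTimeSeries:
    """Euler-Maruyama integration of network-coupled Kuramoto phases.

    d theta_i = [omega_i + K * sum_j W_ij sin(theta_j - theta_i)] dt
                + sigma_phase dB_i,

    with omega_i uniform in ``2*pi*intrinsic_freq_band`` and internal step
    ``dt = TR / substeps``.  The emitted signal is ``sin(theta_i(t))`` plus
    white Gaussian observation noise, sampled at the TR.
    """
    rng = np.random.default_rng(spec.seed)
    n, w = spec.n_regions, spec.coupling_matrix
    dt = spec.tr_seconds / spec.substeps
    max_degree = w.sum(axis=1).max()
    if spec.global_coupling * max_degree * dt > 0.5:
        raise ParameterError(
            "unstable integration: K * max weighted degree * dt = "
            f"{spec.global_coupling * max_degree * dt:.3f} > 0.5; "
            "reduce the step (increase substeps) or the coupling"
        )
    lo, hi = spec.intrinsic_freq_band
    omega = 2.0 * np.pi * rng.uniform(lo, hi, size=n)
    theta = rng.uniform(-np.pi, np.pi, size=n)
    sqrt_dt = np.sqrt(dt)
    out = np.empty((n, spec.n_timepoints))
    k = spec.global_coupling
    for t in range(spec.n_timepoints):
        for _ in range(spec.substeps):
            sin_t, cos_t = np.sin(theta), np.cos(theta)
            # sum_j W_ij sin(theta_j - theta_i), expanded for vectorization
            coupling = cos_t * (w @ sin_t) - sin_t * (w @ cos_t)
            theta = theta + (omega + k * coupling) * dt
            if spec.phase_noise_sd > 0:
                theta = theta + spec.phase_noise_sd * sqrt_dt * rng.standard_normal(n)
        out[:, t] = np.sin(theta)
    if spec.noise_sd > 0:
        out = out + spec.noise_sd * rng.standard_normal(out.shape)
    if spec.lowpass_hz is not None:
        taps = sp_signal.firwin(65, spec.lowpass_hz, fs=1.0 / spec.tr_seconds)
        out = sp_signal.filtfilt(taps, [1.0], out, axis=-1)
    return RoiTimeSeries(values=out,
                         region_ids=np.arange(1, n + 1),
                         tr_seconds=spec.tr_seconds)


def synth_pet_vectors(hubness: np.ndarray,
                      rho_hub: float = 0.6,
                      rho_between: float = 0.63,
                      seed: int | None = 0,
                      rcps_mean: float = 2.0, rcps_sd: float = 0.35,
                      suv_mean: float = 6.0, suv_sd: float = 1.2,
                      ) -> tuple[RegionalPetVector, RegionalPetVector]:
    """Regional rCPS and SUV vectors tied to hubness by a Gaussian copula.

    The latent rCPS score correlates ``rho_hub`` with the normal scores of
    ``hubness``; the latent SUV score correlates ``rho_between`` with the
    rCPS score (and hence ``rho_hub * rho_between`` with hubness).  Both are
    mapped affinely to positive physiological ranges, which preserves the
    correlations exactly; a final shift guarantees positivity.
    """
    if not (abs(rho_hub) < 1 and abs(rho_between) < 1):
        raise ParameterError("|rho| must be < 1")
    rng = np.random.default_rng(seed)
    hubness = np.asarray(hubness, dtype=float)
    n = len(hubness)
    # rank-based normal scores: copula-robust to the hubness marginal
    ranks = sp_stats.rankdata(hubness, method="average")
    z_hub = sp_stats.norm.ppf(ranks / (n + 1))
    z_hub = (z_hub - z_hub.mean()) / z_hub.std()
    e1, e2 = rng.standard_normal(n), rng.standard_normal(n)
    z_rcps = rho_hub * z_hub + np.sqrt(1 - rho_hub ** 2) * e1
    z_suv = rho_between * z_rcps + np.sqrt(1 - rho_between ** 2) * e2

    def positive(z: np.ndarray, mean: float, sd: float) -> np.ndarray:
        v = mean + sd * (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
        if v.min() <= 0:
            v = v - v.min() + 0.05 * mean
        return v

    region_ids = np.arange(1, n + 1)
    rcps = RegionalPetVector(values=positive(z_rcps, rcps_mean, rcps_sd),
                             tracer="rCPS", region_ids=region_ids)
    suv = RegionalPetVector(values=positive(z_suv, suv_mean, suv_sd),
                            tracer="SUV", region_ids=region_ids)
    return rcps, suv


def region_volume_pair(ts: RoiTimeSeries,
                       voxels_per_region: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Pack a RoiTimeSeries into a toy (4-D BOLD, 3-D atlas) volume pair.

    Each region occupies ``voxels_per_region`` voxels along the x axis, all
    holding the regional time course, so ROI extraction recovers the series
    exactly.  Used to exercise the imaging inputs without real scans.
    """
    n, t = ts.values.shape
    bold = np.zeros((n * voxels_per_region, 1, 1, t))
    atlas = np.zeros((n * voxels_per_region, 1, 1), dtype=int)
    for r in range(n):
        sl = slice(r * voxels_per_region, (r + 1) * voxels_per_region)
        bold[sl, 0, 0, :] = ts.values[r]
        atlas[sl, 0, 0] = ts.region_ids[r]
    return bold, atlas
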