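"""Multiscale analytic decomposition of regional time series.

Each regional signal is decomposed into dyadic frequency bands by running two
parallel maximal-overlap (undecimated) discrete wavelet transforms whose
filter banks form an approximate Hilbert wavelet pair (HWP): the wavelet of
the second bank is approximately the Hilbert transform of the first.  The
complex combination ``w_h + i*w_g`` of the two banks' coefficients is then an
approximately analytic band-limited signal, whose argument gives the
instantaneous phase of the input within that band.

Filter design
-------------
The HWP is built with the common-factor construction: both scaling filters
share a factor ``F(z) = (1+z^-1)^K Q(z)`` and differ by a maximally flat
(Lagrange) fractional-delay factor ``D(z)`` of order ``L``,

    H0(z) = F(z) D(z),        G0(z) = F(z) z^{-L} D(1/z),

so that ``G0`` equals ``H0`` delayed by half a sample to within the flatness
of ``D``.  ``Q`` is obtained by solving the orthonormality (halfband)
condition linearly in the autocorrelation of ``Q`` and spectrally factorizing
the result.  Both banks are exactly orthonormal and have identical magnitude
responses; analyticity of the complex combination is approximate and improves
with cascade depth (see :func:`analytic_quality`).

Scale indexing
--------------
Scale ``j`` of ``J`` is labelled with the band ``(fs/2^j, fs/2^(j-1))`` for
``j < J`` and ``(0, fs/2^(J-1))`` for ``j = J``, where ``fs = 1/TR``.  These
labels tile ``(0, fs]``; the top half of scale 1's label lies above the
Nyquist frequency, and the scale is flagged accordingly (its coefficients are
the anti-analytic combination of the first-level detail, i.e. the aliased
image of the top octave).  Scales ``2..J-1`` are the level ``j-1`` wavelet
details and scale ``J`` is the level ``J-2`` smooth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb, floor, log2

import numpy as np
from scipy import signal as sp_signal

logger = logging.getLogger(__name__)

SUPPORTED_ORDERS = (2, 3, 4)

#: Cascade depth at which the reported analytic-quality figure is evaluated.
#: Depth 3 corresponds to the shallowest band used for inference (scale 4);
#: shallower equivalent filters are necessarily less one-sided because the
#: half-sample-delay phase relation cannot hold at the Nyquist frequency.
QUALITY_REFERENCE_DEPTH = 3


class ParameterError(ValueError):
    """A parameter is outside its supported range."""


# ---------------------------------------------------------------------------
# filter design


def _lagrange_delay(order: int, tau: float) -> np.ndarray:
    """Maximally flat FIR approximation of a delay of ``tau`` samples."""
    n = np.arange(order + 1)
    d = np.ones(order + 1)
    for i in range(order + 1):
        for k in range(order + 1):
            if k != i:
                d[i] *= (tau - k) / (i - k)
    return d


def _autocorr(x: np.ndarray) -> np.ndarray:
    """Full autocorrelation sequence, lags -(len-1)..(len-1)."""
    return np.convolve(x, x[::-1])


def _qmf(h0: np.ndarray) -> np.ndarray:
    """Conjugate quadrature (wavelet) filter of an even-length scaling filter."""
    n = np.arange(len(h0))
    return ((-1.0) ** n) * h0[::-1]


@dataclass
class HwpFilterPair:
    """Approximate Hilbert wavelet pair.

    ``h``/``g`` are the wavelet (highpass) filters of the two banks and
    ``scaling_h``/``scaling_g`` the matching scaling (lowpass) filters;
    ``g``'s bank is the approximate half-sample-delayed partner of ``h``'s.
    ``quality`` maps cascade depth to the fraction of the equivalent analytic
    detail filter's energy at negative frequencies (0 = perfectly analytic).
    """

    h: np.ndarray
    g: np.ndarray
    scaling_h: np.ndarray
    scaling_g: np.ndarray
    design_order: int
    quality: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.h)


def design_hwp_filters(design_order: int = 3) -> HwpFilterPair:
    """Design an approximate Hilbert wavelet pair (common-factor method).

    Parameters
    ----------
    design_order : int
        Number of vanishing moments ``K`` and fractional-delay order ``L``
        (``K = L = design_order``).  Supported: 2, 3, 4.  Filter length is
        ``2 * (K + L)``.

    Returns
    -------
    HwpFilterPair
        Orthonormal pair with identical magnitude responses; the ``quality``
        attribute reports negative-frequency energy fractions per depth.
    """
    if design_order not in SUPPORTED_ORDERS:
        raise ParameterError(
            f"design_order {design_order} unsupported; choose from {SUPPORTED_ORDERS}"
        )
    K = L = design_order
    tau = (2 * L - 1) / 4.0
    d = _lagrange_delay(L, tau)
    b = np.array([comb(K, n) for n in range(K + 1)], dtype=float)

    # Solve the halfband condition  a(0)=1, a(2m)=0  for the autocorrelation
    # s of the residual factor Q, where a = beta * s * r (polynomial
    # convolution of autocorrelations).
    c = np.convolve(_autocorr(b), _autocorr(d))
    c0 = len(c) // 2
    M = K + L - 1
    n_constraints = K + L

    def cval(lag: int) -> float:
        idx = c0 + lag
        return c[idx] if 0 <= idx < len(c) else 0.0

    A = np.zeros((n_constraints, M + 1))
    rhs = np.zeros(n_constraints)
    rhs[0] = 1.0
    for m in range(n_constraints):
        lag = 2 * m
        A[m, 0] = cval(lag)
        for j in range(1, M + 1):
            A[m, j] = cval(lag - j) + cval(lag + j)
    s = np.linalg.solve(A, rhs)

    # spectral factorization of S(w) >= 0
    w_grid = np.linspace(0.0, np.pi, 4096)
    S_w = s[0] + 2.0 * np.cos(np.outer(w_grid, np.arange(1, M + 1))) @ s[1:]
    if S_w.min() < -1e-10:
        raise ParameterError(
            f"design_order {design_order}: non-factorizable spectrum "
            f"(min S = {S_w.min():.3e})"
        )
    poly = np.concatenate([s[::-1], s[1:]])
    roots = np.roots(poly)
    inside = list(roots[np.abs(roots) < 1.0 - 1e-9])
    on_circle = sorted(
        roots[np.abs(np.abs(roots) - 1.0) <= 1e-9],
        key=lambda z: (np.angle(z), np.abs(z)),
    )
    q = np.real(np.poly(inside + on_circle[::2]))
    aq = _autocorr(q)
    q *= np.sqrt(s[0] / aq[len(aq) // 2])

    f = np.convolve(b, q)
    h0 = np.convolve(f, d)
    g0 = np.convolve(f, d[::-1])
    h0 *= np.sqrt(2.0) / h0.sum()
    g0 *= np.sqrt(2.0) / g0.sum()

    pair = HwpFilterPair(
        h=_qmf(h0), g=_qmf(g0), scaling_h=h0, scaling_g=g0,
        design_order=design_order,
    )
    pair.quality = {depth: analytic_quality(pair, depth) for depth in range(1, 7)}
    logger.debug(
        "HWP order %d: analytic quality at depth %d = %.4f",
        design_order, QUALITY_REFERENCE_DEPTH,
        pair.quality[QUALITY_REFERENCE_DEPTH],
    )
    return pair


def _freq_response(filt: np.ndarray, omega: np.ndarray, upsample: int = 1) -> np.ndarray:
    n = np.arange(len(filt))
    return np.exp(-1j * np.outer(omega * upsample, n)) @ filt


def analytic_quality(pair: HwpFilterPair, depth: int, n_grid: int = 1024) -> float:
    """Negative-frequency energy fraction of the equivalent analytic filter.

    Evaluates the cascade equivalent of the level-``depth`` detail branch for
    both banks on an ``n_grid``-point frequency grid and returns
    ``sum |E_h + i E_g|^2 over omega < 0  /  total``.
    """
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    omega = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    root2 = np.sqrt(2.0)
    eh = _freq_response(pair.h / root2, omega, 2 ** (depth - 1))
    eg = _freq_response(pair.g / root2, omega, 2 ** (depth - 1))
    for k in range(1, depth):
        eh = eh * _freq_response(pair.scaling_h / root2, omega, 2 ** (k - 1))
        eg = eg * _freq_response(pair.scaling_g / root2, omega, 2 ** (k - 1))
    combined = eh + 1j * eg
    total = np.sum(np.abs(combined) ** 2)
    negative = np.sum(np.abs(combined[omega < 0]) ** 2)
    return float(negative / total)


# ---------------------------------------------------------------------------
# scale bands


@dataclass(frozen=True)
class ScaleBand:
    """Dyadic frequency band label of one scale.

    ``f_hi = 2 * f_lo`` for all scales but the last, whose ``f_lo`` is 0; the
    bands of scales ``1..J`` tile ``(0, fs]``.  ``above_nyquist`` marks the
    first scale, whose labelled band exceeds ``fs/2``.
    """

    scale_index: int
    f_lo: float
    f_hi: float

    @property
    def above_nyquist(self) -> bool:
        return self.scale_index == 1


def max_scales(n_timepoints: int) -> int:
    """Largest supported number of scales: floor(log2(T)) + 1."""
    if n_timepoints < 8:
        raise ParameterError("series too short")
    return floor(log2(n_timepoints)) + 1


def scale_band_edges(scale_index: int, tr_seconds: float,
                     n_scales: int = 11) -> ScaleBand:
    """Frequency-band label of one scale.

    With ``fs = 1/tr_seconds``, scale ``j < J`` is labelled
    ``(fs/2^j, fs/2^(j-1))`` and scale ``J`` is ``(0, fs/2^(J-1))``.  The
    upper half of scale 1's band lies above the Nyquist frequency and is kept
    only for completeness.
    """
    if tr_seconds <= 0:
        raise ParameterError("tr_seconds must be positive")
    if not 1 <= scale_index <= n_scales:
        raise ParameterError(
            f"scale_index {scale_index} outside 1..{n_scales}"
        )
    fs = 1.0 / tr_seconds
    if scale_index == n_scales:
        return ScaleBand(scale_index, 0.0, fs / 2 ** (n_scales - 1))
    return ScaleBand(scale_index, fs / 2 ** scale_index,
                     fs / 2 ** (scale_index - 1))


# ---------------------------------------------------------------------------
# MODWT (one filter bank)


def _stage_responses(filt: np.ndarray, level: int, n: int) -> np.ndarray:
    """DFT of the level-``level`` upsampled MODWT filter on an n-point grid."""
    omega = 2.0 * np.pi * np.fft.fftfreq(n)
    return _freq_response(filt / np.sqrt(2.0), omega, 2 ** (level - 1))


def modwt(x: np.ndarray, scaling: np.ndarray, wavelet: np.ndarray,
          depth: int) -> tuple[np.ndarray, np.ndarray]:
    """Maximal-overlap DWT of ``x`` along its last axis (circular boundary).

    Returns ``(details, smooth)`` where ``details`` has shape
    ``(depth,) + x.shape`` and ``smooth`` has ``x``'s shape.  Implemented in
    the frequency domain; equivalent to circular convolution with the
    upsampled, 1/sqrt(2)-rescaled filters.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if depth < 1 or 2 ** depth > n:
        raise ParameterError(f"depth {depth} too deep for length {n}")
    v_hat = np.fft.fft(x, axis=-1)
    details = np.empty((depth,) + x.shape)
    for j in range(1, depth + 1):
        h_hat = _stage_responses(wavelet, j, n)
        g_hat = _stage_responses(scaling, j, n)
        details[j - 1] = np.real(np.fft.ifft(v_hat * h_hat, axis=-1))
        v_hat = v_hat * g_hat
    smooth = np.real(np.fft.ifft(v_hat, axis=-1))
    return details, smooth


def imodwt(details: np.ndarray, smooth: np.ndarray, scaling: np.ndarray,
           wavelet: np.ndarray) -> np.ndarray:
    """Inverse MODWT (adjoint filtering); exact for orthonormal filters."""
    depth = details.shape[0]
    n = details.shape[-1]
    v_hat = np.fft.fft(np.asarray(smooth, dtype=float), axis=-1)
    for j in range(depth, 0, -1):
        h_hat = _stage_responses(wavelet, j, n)
        g_hat = _stage_responses(scaling, j, n)
        w_hat = np.fft.fft(details[j - 1], axis=-1)
        v_hat = np.conj(h_hat) * w_hat + np.conj(g_hat) * v_hat
    return np.real(np.fft.ifft(v_hat, axis=-1))


def boundary_width(filter_length: int, level: int, n_timepoints: int) -> int:
    """Number of leading coefficients affected by the circular boundary."""
    return int(min((2 ** level - 1) * (filter_length - 1), n_timepoints))


# ---------------------------------------------------------------------------
# analytic per-scale decomposition


def modwt_packet_decompose(series: np.ndarray, filters: HwpFilterPair,
                           n_scales: int) -> np.ndarray:
    """Per-scale complex analytic coefficients of ``series`` (last axis time).

    Runs both filter banks of the Hilbert pair as parallel MODWTs and forms
    the analytic combination ``w_h + i*w_g`` per scale.  Scales ``2..J-1``
    are wavelet details at levels ``1..J-2``, scale ``J`` is the level
    ``J-2`` smooth, and scale 1 (above Nyquist) is the anti-analytic
    combination ``w_h - i*w_g`` of the level-1 detail, representing the
    aliased top-octave image.

    Returns a complex array of shape ``(n_scales,) + series.shape``.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if not 3 <= n_scales <= max_scales(n):
        raise ParameterError(
            f"n_scales must be in 3..{max_scales(n)} for length {n}"
        )
    depth = n_scales - 2
    det_h, smooth_h = modwt(series, filters.scaling_h, filters.h, depth)
    det_g, smooth_g = modwt(series, filters.scaling_g, filters.g, depth)
    out = np.empty((n_scales,) + series.shape, dtype=complex)
    out[0] = det_h[0] - 1j * det_g[0]
    for j in range(2, n_scales):
        out[j - 1] = det_h[j - 2] + 1j * det_g[j - 2]
    out[n_scales - 1] = smooth_h + 1j * smooth_g
    return out


def extract_phase(coefficients: np.ndarray) -> np.ndarray:
    """Elementwise argument of complex analytic coefficients, in (-pi, pi].

    Zero-magnitude samples have undefined phase; they are set to 0 with a
    warning.
    """
    coefficients = np.asarray(coefficients, dtype=complex)
    zero = coefficients == 0
    if zero.all():
        warnings.warn("all-zero coefficients: phase undefined, set to 0")
    phase = np.angle(coefficients)
    phase[zero] = 0.0
    return phase


def decimate_phase(phase: np.ndarray, factor: int) -> np.ndarray:
    """Anti-aliased decimation of a phase series (last axis time).

    The phase is mapped to the unit circle ``exp(i*theta)`` before lowpass
    filtering so that wrap discontinuities do not produce filter artefacts; a
    linear-phase FIR (order ``8*factor``, cutoff ``0.8/factor`` of Nyquist)
    is applied forward-backward for zero net phase, every ``factor``-th
    sample is kept and the argument is taken again.  Output length is
    ``floor(T / factor)``.
    """
    phase = np.asarray(phase, dtype=float)
    n = phase.shape[-1]
    if factor < 1:
        raise ParameterError("factor must be >= 1")
    if factor == 1:
        return phase.copy()
    if n < 8 * factor:
        raise ParameterError(f"series length {n} < 8 * factor ({8 * factor})")
    z = np.exp(1j * phase)
    taps = sp_signal.firwin(8 * factor + 1, 0.8 / factor)
    z_f = (sp_signal.filtfilt(taps, [1.0], z.real, axis=-1)
           + 1j * sp_signal.filtfilt(taps, [1.0], z.imag, axis=-1))
    keep = n - (n % factor)
    return np.angle(z_f[..., :keep:factor])


# ---------------------------------------------------------------------------
# high-level composition


@dataclass
class MultiscalePhase:
    """Instantaneous phase per scale, region and (decimated) timepoint.

    ``phases`` has shape ``(n_scales, n_regions, n_decimated_timepoints)``
    with entries in ``(-pi, pi]``.  ``boundary`` is a boolean mask of the
    same time length per scale marking samples affected by the circular
    wavelet boundary (True = boundary-affected).
    """

    phases: np.ndarray
    bands: list[ScaleBand]
    decimation_factor: int
    tr_seconds: float
    boundary: np.ndarray = None

    @property
    def n_scales(self) -> int:
        return self.phases.shape[0]

    @property
    def n_regions(self) -> int:
        return self.phases.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.phases.shape[2]

    def scale(self, scale_index: int) -> np.ndarray:
        """Phase matrix (regions x time) of one 1-based scale."""
        return self.phases[scale_index - 1]


def multiscale_phase(timeseries, n_scales: int | None = None,
                     design_order: int = 3,
                     decimation_factor: int = 4) -> MultiscalePhase:
    """Full phase decomposition of a :class:`~phasegraph.io.RoiTimeSeries`.

    Decomposes every regional series into ``n_scales`` dyadic bands (default:
    the maximum the series length supports), extracts instantaneous phase
    from the analytic coefficients and decimates it.
    """
    values = timeseries.values
    tr = timeseries.tr_seconds
    if n_scales is None:
        n_scales = max_scales(values.shape[-1])
    pair = design_hwp_filters(design_order)
    coeffs = modwt_packet_decompose(values, pair, n_scales)
    phase = extract_phase(coeffs)
    phase_d = decimate_phase(phase, decimation_factor)
    bands = [scale_band_edges(j, tr, n_scales) for j in range(1, n_scales + 1)]

    n_dec = phase_d.shape[-1]
    boundary = np.zeros((n_scales, n_dec), dtype=bool)
    n_full = values.shape[-1]
    for j in range(1, n_scales + 1):
        level = 1 if j == 1 else (j - 1 if j < n_scales else n_scales - 2)
        width = boundary_width(len(pair), level, n_full)
        boundary[j - 1, : min(width // decimation_factor + 1, n_dec)] = True
    return MultiscalePhase(phases=phase_d, bands=bands,
                           decimation_factor=decimation_factor,
                           tr_seconds=tr, boundary=boundary)
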