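"""Continuous Morlet wavelet transform and the wavelet modulus ratio.

The wavelet modulus ratio rho(t, s) resolves community synchrony in both
time and scale.  With w_i(t, s) the Morlet wavelet coefficient of unit i,

    rho(t, s) = [G_s * |sum_i w_i(., s)|](t) / [G_s * sum_i |w_i(., s)|](t)

where G_s is a Gaussian kernel in time with standard deviation s.  The
numerator tracks the fluctuation of the community *total* at scale s around
time t; the denominator the summed fluctuation amplitudes of the individual
units.  By the triangle inequality 0 <= rho <= 1: rho -> 0 when units cancel
(compensation), rho -> 1 when they rise and fall together (synchrony).

The CWT follows the standard frequency-domain implementation with
Torrence-Compo normalization, zero padding to the next power of two and a
cone-of-influence (COI) mask at the e-folding time sqrt(2)*s of the wavelet
envelope.  Significance of high/low rho is assessed pointwise against IAAFT
surrogates, which keep each unit's spectrum and value distribution but
scramble the phase relationships between units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .surrogates import as_generator, iaaft_matrix

__all__ = [
    "WaveletField",
    "WMRMap",
    "SignificanceMask",
    "morlet_cwt",
    "default_scales",
    "fourier_period",
    "scale_for_period",
    "wavelet_modulus_ratio",
    "wmr_significance",
]

OMEGA0_DEFAULT = 6.0


def fourier_period(scale, omega0: float = OMEGA0_DEFAULT):
    """Equivalent Fourier period of a Morlet wavelet scale."""
    return np.asarray(scale) * (4 * np.pi) / (omega0 + np.sqrt(2 + omega0**2))


def scale_for_period(period, omega0: float = OMEGA0_DEFAULT):
    """Morlet scale whose equivalent Fourier period is ``period``."""
    return np.asarray(period) * (omega0 + np.sqrt(2 + omega0**2)) / (4 * np.pi)


def default_scales(
    n_times: int,
    dt: float = 1.0,
    s0: float = 2.0,
    voices_per_octave: int = 12,
    max_fraction: float = 0.25,
) -> np.ndarray:
    """Dyadic scale grid: s0 * 2^(j / voices) up to ``max_fraction * T``.

    Defaults resolve sub-seasonal (2-4 month) through multi-year scales on a
    multi-decade monthly series.
    """
    s_max = max_fraction * n_times * dt
    if s_max < s0:
        raise ValueError("series too short for the requested scale grid")
    n = int(np.floor(voices_per_octave * np.log2(s_max / s0))) + 1
    return s0 * 2.0 ** (np.arange(n) / voices_per_octave)


@dataclass(frozen=True)
class WaveletField:
    """Complex Morlet coefficients of one unit over a (scale, time) grid."""

    unit: str
    coefficients: np.ndarray  # (n_scales, n_times) complex
    scales: np.ndarray  # months (or dt units), strictly increasing
    coi: np.ndarray  # (n_times,) largest reliable scale per time
    omega0: float = OMEGA0_DEFAULT
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.coefficients.shape != (len(self.scales), len(self.coi)):
            raise ValueError("coefficient grid inconsistent with scales/times")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")

    @property
    def n_times(self) -> int:
        return self.coefficients.shape[1]

    def inside_coi(self) -> np.ndarray:
        """Boolean (n_scales, n_times) grid, True where boundary-safe."""
        return self.scales[:, None] <= self.coi[None, :]


@dataclass(frozen=True)
class WMRMap:
    """Wavelet modulus ratio over a (scale, time) grid.

    ``rho`` is NaN where the map is unreliable: inside the cone of influence
    or where the denominator vanishes.  ``valid`` marks the usable cells.
    """

    rho: np.ndarray  # (n_scales, n_times), NaN where invalid
    scales: np.ndarray
    coi: np.ndarray
    n_units: int
    dt: float = 1.0

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.rho)

    @property
    def n_times(self) -> int:
        return self.rho.shape[1]


@dataclass(frozen=True)
class SignificanceMask:
    """Pointwise two-sided surrogate flags for a :class:`WMRMap`."""

    low_mask: np.ndarray  # significantly lower synchrony than the null
    high_mask: np.ndarray  # significantly higher
    alpha: float
    n_surrogates: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.low_mask.shape != self.high_mask.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.low_mask & self.high_mask):
            raise ValueError("a cell cannot be both significantly low and high")


def morlet_cwt(
    series: np.ndarray,
    scales: np.ndarray | None = None,
    dt: float = 1.0,
    omega0: float = OMEGA0_DEFAULT,
    unit: str = "series",
) -> WaveletField:
    """Continuous Morlet wavelet transform of a regularly sampled series.

    Frequency-domain implementation: the series (mean-removed, zero-padded
    to the next power of two) is multiplied by the analytic Morlet window
    pi^(-1/4) * sqrt(2 pi s / dt) * exp(-(s w - omega0)^2 / 2) on positive
    frequencies and inverse-transformed, one scale at a time.  The COI is
    the e-folding time sqrt(2)*s of the Gaussian envelope.
    """
    x = np.asarray(series, dtype=float).ravel()
    T = x.size
    if T < 16:
        raise ValueError("need at least 16 time points for a wavelet analysis")
    if scales is None:
        scales = default_scales(T, dt)
    scales = np.asarray(scales, dtype=float)
    if scales.min() < 2 * dt - 1e-12 or scales.max() > T * dt / 2 + 1e-12:
        raise ValueError(
            f"scales must lie within [2*dt, T*dt/2] = [{2*dt}, {T*dt/2}]"
        )

    n_pad = int(2 ** np.ceil(np.log2(T)))
    xz = np.zeros(n_pad)
    xz[:T] = x - x.mean()
    xhat = sp_fft.fft(xz)
    omega = 2 * np.pi * sp_fft.fftfreq(n_pad, d=dt)

    pos = omega > 0
    W = np.empty((len(scales), T), dtype=complex)
    norm = np.pi**-0.25
    for k, s in enumerate(scales):
        window = np.zeros(n_pad)
        window[pos] = norm * np.sqrt(2 * np.pi * s / dt) * np.exp(
            -0.5 * (s * omega[pos] - omega0) ** 2
        )
        W[k] = sp_fft.ifft(xhat * window)[:T]

    dist = np.minimum(np.arange(T), T - 1 - np.arange(T)) * dt
    coi = dist / np.sqrt(2.0)
    return WaveletField(unit=unit, coefficients=W, scales=scales, coi=coi,
                        omega0=omega0, dt=dt)


def _gaussian_smooth(rows: np.ndarray, scales: np.ndarray, dt: float,
                     width_factor: float) -> np.ndarray:
    """Scale-adapted Gaussian smoothing along time, one kernel per scale.

    The kernel at scale s has standard deviation ``width_factor * s``,
    truncated at +/- 4 sd.  Zero padding at the series edges cancels in the
    modulus-ratio quotient (both numerator and denominator lose the same
    mass), which is equivalent to renormalizing the truncated kernel.
    """
    out = np.empty_like(rows)
    for k, s in enumerate(scales):
        sigma = width_factor * s / dt  # in samples
        half = int(np.ceil(4 * sigma))
        kern = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
        out[k] = ndimage.convolve1d(rows[k], kern, mode="constant", cval=0.0)
    return out


def wavelet_modulus_ratio(
    fields: list[WaveletField] | np.ndarray,
    kernel_width_factor: float = 1.0,
    scales: np.ndarray | None = None,
    coi: np.ndarray | None = None,
    dt: float = 1.0,
) -> WMRMap:
    """Wavelet modulus ratio across units sharing one (scale, time) grid.

    Accepts either a list of :class:`WaveletField` or a raw complex array of
    shape (n_units, n_scales, n_times) with explicit ``scales``/``coi``.
    """
    if isinstance(fields, np.ndarray):
        coeffs = fields
        if scales is None or coi is None:
            raise ValueError("raw coefficient input requires scales and coi")
    else:
        if len(fields) < 1:
            raise ValueError("need at least one wavelet field")
        scales = fields[0].scales
        coi = fields[0].coi
        dt = fields[0].dt
        for f in fields[1:]:
            if f.coefficients.shape != fields[0].coefficients.shape or not np.allclose(
                f.scales, scales
            ):
                raise ValueError("wavelet fields are not on a common grid")
        coeffs = np.stack([f.coefficients for f in fields])

    mod_of_sum = np.abs(coeffs.sum(axis=0))  # |sum_i w_i|
    sum_of_mod = np.abs(coeffs).sum(axis=0)  # sum_i |w_i|
    num = _gaussian_smooth(mod_of_sum, scales, dt, kernel_width_factor)
    den = _gaussian_smooth(sum_of_mod, scales, dt, kernel_width_factor)

    tiny = np.finfo(float).tiny * 1e4
    floor = max(tiny, den.max() * 1e-14)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > floor, num / den, np.nan)
    rho[scales[:, None] > coi[None, :]] = np.nan  # inside the cone of influence
    return WMRMap(rho=rho, scales=np.asarray(scales), coi=np.asarray(coi),
                  n_units=coeffs.shape[0], dt=dt)


def _community_wmr(values: np.ndarray, scales: np.ndarray | None, dt: float,
                   omega0: float, kernel_width_factor: float) -> WMRMap:
    fields = [
        morlet_cwt(values[:, j], scales=scales, dt=dt, omega0=omega0, unit=f"u{j}")
        for j in range(values.shape[1])
    ]
    return wavelet_modulus_ratio(fields, kernel_width_factor=kernel_width_factor)


def wmr_significance(
    matrix,
    scales: np.ndarray | None = None,
    n_surrogates: int = 1000,
    alpha: float = 0.10,
    seed: int | np.random.Generator | None = None,
    dt: float = 1.0,
    omega0: float = OMEGA0_DEFAULT,
    kernel_width_factor: float = 1.0,
) -> tuple[WMRMap, SignificanceMask]:
    """Observed rho plus pointwise two-sided IAAFT significance masks.

    Each surrogate replicate applies IAAFT independently to every unit's
    monthly series and recomputes rho.  A cell is flagged high (low) when
    the count-based surrogate p-value (#{rho_surr >= rho_obs} + 1)/(n + 1)
    (resp. <=) is at most alpha/2 -- the observed value sits outside the
    central 1 - alpha band of its surrogate distribution, with the
    attainable floor 1/(n + 1) respected (a single surrogate can never
    flag).  Flags are only raised outside the cone of influence.
    Significance is pointwise per cell; no areawise correction is applied.
    """
    values = matrix.values if hasattr(matrix, "values") and not isinstance(matrix, np.ndarray) else np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a (n_times, n_units) matrix with >= 2 units")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if scales is None:
        scales = default_scales(values.shape[0], dt)

    rng = as_generator(seed)
    observed = _community_wmr(values, scales, dt, omega0, kernel_width_factor)

    surr_rho = np.empty((n_surrogates,) + observed.rho.shape)
    for k in range(n_surrogates):
        sv = iaaft_matrix(values, rng)
        surr_rho[k] = _community_wmr(sv, scales, dt, omega0, kernel_width_factor).rho

    with np.errstate(invalid="ignore"):
        n_valid = np.isfinite(surr_rho).sum(axis=0)
        n_ge = np.nansum(surr_rho >= observed.rho[None], axis=0)
        n_le = np.nansum(surr_rho <= observed.rho[None], axis=0)
    p_high = (n_ge + 1.0) / (n_valid + 1.0)
    p_low = (n_le + 1.0) / (n_valid + 1.0)
    if alpha >= 1.0:
        # degenerate level: every valid cell counts as extreme on its side
        low = observed.valid & (p_low <= p_high)
        high = observed.valid & ~low
    else:
        low = observed.valid & (p_low <= alpha / 2)
        high = observed.valid & (p_high <= alpha / 2) & ~low
    mask = SignificanceMask(
        low_mask=low, high_mask=high, alpha=alpha,
        n_surrogates=n_surrogates,
        seed=seed if isinstance(seed, int) else None,
    )
    return observed, mask
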