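"""Kirkeby regularized inverse filtering for transducer equalization.

Bone transducers have resonant, non-flat responses; driving them through a
regularized inverse filter flattens the effective response over a working
band (200-4000 Hz here) without the unbounded boosts a naive inverse would
demand where the transducer is weak.  The inverse is computed per FFT bin as

    C(w) = conj(T(w)) / (conj(T(w)) * T(w) + eps(w))

where ``eps(w)`` is a frequency-dependent regularization weight: small inside
the equalization band (so the inverse is accurate) and large outside (so the
filter gain collapses instead of boosting).  The bin-wise gain is bounded by
``|C| <= 1/(2*sqrt(eps))`` regardless of how small ``|T|`` gets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, fftfreq, ifft

from .errors import SingularInversionError, ValidationError
from .signals import TimeSignal

__all__ = [
    "RegularizationProfile",
    "EqualizationFilter",
    "regularization_vector",
    "kirkeby_inverse",
    "apply_equalization",
    "flatness_metric",
]


@dataclass(frozen=True)
class RegularizationProfile:
    """Frequency-dependent regularization eps(w).

    ``eps_min`` holds strictly inside [f_low, f_high]; ``eps_max`` holds far
    outside; the transition is a raised cosine in log-frequency spanning
    ``transition_octaves`` on each side.  Values are absolute (same units as
    ``|T|^2``); use :meth:`scaled_to` to express them relative to a measured
    response's peak power.
    """

    eps_min: float = 1e-4
    eps_max: float = 1.0
    f_low_hz: float = 200.0
    f_high_hz: float = 4000.0
    transition_octaves: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.eps_min < self.eps_max):
            raise ValidationError("need 0 <= eps_min < eps_max")
        if not (0 < self.f_low_hz < self.f_high_hz):
            raise ValidationError("need 0 < f_low < f_high")
        if not (self.transition_octaves > 0):
            raise ValidationError("transition_octaves must be > 0")

    def scaled_to(self, peak_power: float) -> "RegularizationProfile":
        """Return a copy with eps values multiplied by ``peak_power``
        (typically ``max|T|^2`` of the response being inverted)."""
        return RegularizationProfile(
            eps_min=self.eps_min * peak_power,
            eps_max=self.eps_max * peak_power,
            f_low_hz=self.f_low_hz,
            f_high_hz=self.f_high_hz,
            transition_octaves=self.transition_octaves,
        )


@dataclass(frozen=True)
class EqualizationFilter:
    """Time-domain inverse filter with its modeling delay."""

    taps: np.ndarray
    rate_hz: float
    modeling_delay: int

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=np.float64)
        if taps.ndim != 1 or taps.size < 1 or not np.all(np.isfinite(taps)):
            raise ValidationError("taps must be a finite 1-D sequence")
        if not (0 <= self.modeling_delay < taps.size):
            raise ValidationError("modeling_delay must lie in [0, len(taps))")
        object.__setattr__(self, "taps", taps)


def regularization_vector(profile: RegularizationProfile, n_bins: int, rate_hz: float) -> np.ndarray:
    """Evaluate eps(w) on an ``n_bins``-point FFT grid (Hermitian layout).

    DC maps to ``eps_max``; magnitudes depend only on ``|f|`` so the result
    is symmetric about Nyquist.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if not (profile.f_high_hz < rate_hz / 2):
        raise ValidationError(
            f"profile band edge {profile.f_high_hz} Hz is at/above Nyquist ({rate_hz / 2} Hz)"
        )
    f = np.abs(fftfreq(n_bins, d=1.0 / rate_hz))
    eps = np.full(n_bins, profile.eps_max)
    t = profile.transition_octaves
    lo, hi = profile.f_low_hz, profile.f_high_hz
    with np.errstate(divide="ignore"):
        logf = np.log2(np.where(f > 0, f, np.nan))
    in_band = (f >= lo) & (f <= hi)
    eps[in_band] = profile.eps_min

    # Raised-cosine ramps in log2-frequency on either side of the band.
    lo_ramp = (f > 0) & (f < lo) & (logf > np.log2(lo) - t)
    x = (np.log2(lo) - logf[lo_ramp]) / t  # 0 at f_low -> 1 at f_low/2^t
    eps[lo_ramp] = profile.eps_min + (profile.eps_max - profile.eps_min) * 0.5 * (1 - np.cos(np.pi * x))
    hi_ramp = (f > hi) & (logf < np.log2(hi) + t)
    x = (logf[hi_ramp] - np.log2(hi)) / t
    eps[hi_ramp] = profile.eps_min + (profile.eps_max - profile.eps_min) * 0.5 * (1 - np.cos(np.pi * x))
    return eps


def kirkeby_inverse(ir: TimeSignal, profile: RegularizationProfile | None = None,
                    n_fft: int = 4096, modeling_delay: int | None = None) -> EqualizationFilter:
    """Design the regularized inverse of an impulse response.

    Parameters
    ----------
    ir : TimeSignal
        Response to invert (e.g. a measured transducer response).
    profile : RegularizationProfile, optional
        Regularization shape with *absolute* eps values.  When omitted, the
        default profile is scaled to the response's peak spectral power
        (eps_min = 1e-4 * max|T|^2, eps_max = max|T|^2).
    n_fft : int
        FFT size; must be at least twice the response length to avoid
        circular wrap of the inverse.
    modeling_delay : int, optional
        Circular shift applied to the inverse to render it causal.  Defaults
        to ``n_fft // 2``, appropriate for mixed-phase responses.
    """
    if n_fft < 2 * len(ir):
        raise ValidationError(f"n_fft ({n_fft}) must be >= 2 * len(ir) ({2 * len(ir)})")
    if modeling_delay is None:
        modeling_delay = n_fft // 2
    if not (0 <= modeling_delay < n_fft):
        raise ValidationError("modeling_delay must lie in [0, n_fft)")

    spectrum = fft(ir.samples, n_fft)
    power = np.abs(spectrum) ** 2
    if profile is None:
        profile = RegularizationProfile().scaled_to(float(power.max()))
    eps = regularization_vector(profile, n_fft, ir.rate_hz)
    denom = power + eps
    if np.any(denom == 0):
        raise SingularInversionError(
            "inverse is singular: |T|^2 + eps vanishes at some bin "
            "(all-zero response with eps_min = 0?)"
        )
    inverse_spectrum = np.conj(spectrum) / denom
    taps = np.real(ifft(inverse_spectrum))
    taps = np.roll(taps, modeling_delay)
    return EqualizationFilter(taps=taps, rate_hz=ir.rate_hz, modeling_delay=int(modeling_delay))


def apply_equalization(ir: TimeSignal, eq: EqualizationFilter) -> TimeSignal:
    """Convolve a response with an equalization filter (full linear
    convolution; output length ``len(ir) + len(taps) - 1``)."""
    if ir.rate_hz != eq.rate_hz:
        raise ValidationError("impulse response and filter rates differ")
    out = np.convolve(ir.samples, eq.taps, mode="full")
    return TimeSignal(out, ir.rate_hz)


def flatness_metric(ir: TimeSignal, f_lo_hz: float, f_hi_hz: float) -> float:
    """Peak-to-peak magnitude ripple (dB) over a band, after third-octave
    power smoothing of the magnitude spectrum."""
    if not (0 < f_lo_hz < f_hi_hz <= ir.rate_hz / 2):
        raise ValidationError("need 0 < f_lo < f_hi <= Nyquist")
    n_fft = max(4096, 2 * len(ir))
    f = np.abs(fftfreq(n_fft, d=1.0 / ir.rate_hz))[: n_fft // 2 + 1]
    power = np.abs(fft(ir.samples, n_fft)[: n_fft // 2 + 1]) ** 2

    band = (f >= f_lo_hz) & (f <= f_hi_hz)
    if not np.any(band):
        raise ValidationError("no FFT bins inside the requested band")
    centers = f[band]
    smoothed = np.empty(centers.size)
    for i, fc in enumerate(centers):
        sel = (f >= fc * 2 ** (-1 / 6)) & (f <= fc * 2 ** (1 / 6))
        smoothed[i] = power[sel].mean()
    smoothed_db = 10.0 * np.log10(smoothed)
    return float(smoothed_db.max() - smoothed_db.min())
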