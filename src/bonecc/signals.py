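"""Waveform generation and processing for crosstalk-cancellation measurements.

This module is the waveform layer of the toolkit: time-stretched pulse (TSP)
sweeps and their analytic inverses for impulse-response measurement by
deconvolution, band-limited noise maskers, the measurement high-pass, and the
three-interval forced-choice (3IFC) stimulus used for threshold measurement.

All levels follow one convention: ``level_db(x) = 20*log10(RMS(x) / 1.0)``,
i.e. dB re 1 V RMS of the electrical drive signal.  A unit-amplitude sine
therefore sits at -3.0103 dB re 1 V RMS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import irfft, next_fast_len, rfft

from .errors import ValidationError

__all__ = [
    "TimeSignal",
    "TspPair",
    "StereoSignal",
    "IfcStimulus",
    "generate_tsp",
    "deconvolve",
    "extract_ir",
    "find_ir_onset",
    "bandpass_noise",
    "highpass",
    "third_octave_band",
    "build_3ifc_stimulus",
    "level_db",
    "rms",
]


def rms(x: np.ndarray) -> float:
    """Root-mean-square of a sample array."""
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean(np.square(x))))


def level_db(x: np.ndarray) -> float:
    """Signal level in dB re 1 V RMS."""
    r = rms(x)
    if r == 0.0:
        return -np.inf
    return 20.0 * np.log10(r)


@dataclass(frozen=True)
class TimeSignal:
    """A uniformly sampled real waveform with its sampling rate.

    Parameters
    ----------
    samples : array-like of float
        Amplitude sequence, dimensionless (interpreted as volts when levels
        are computed).
    rate_hz : float
        Sampling rate in Hz, strictly positive.
    """

    samples: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("samples must all be finite")
        if not (self.rate_hz > 0):
            raise ValidationError(f"rate_hz must be > 0, got {self.rate_hz}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate_hz", float(self.rate_hz))

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate_hz

    def rms(self) -> float:
        return rms(self.samples)

    def level_db(self) -> float:
        return level_db(self.samples)


@dataclass(frozen=True)
class TspPair:
    """A TSP sweep together with its exact circular inverse."""

    sweep: TimeSignal
    inverse: TimeSignal
    n_samples: int
    stretch: int

    def __post_init__(self) -> None:
        if len(self.sweep) != len(self.inverse):
            raise ValidationError("sweep and inverse must have identical length")
        if self.sweep.rate_hz != self.inverse.rate_hz:
            raise ValidationError("sweep and inverse must share one rate")


@dataclass(frozen=True)
class StereoSignal:
    """Left/right channel pair with matching length and rate."""

    left: TimeSignal
    right: TimeSignal

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValidationError("stereo channels must have equal length")
        if self.left.rate_hz != self.right.rate_hz:
            raise ValidationError("stereo channels must have equal rate")

    @property
    def rate_hz(self) -> float:
        return self.left.rate_hz


@dataclass(frozen=True)
class IfcStimulus:
    """Three-interval forced-choice stimulus: masker in all intervals, probe
    tone in exactly one."""

    intervals: tuple[TimeSignal, TimeSignal, TimeSignal]
    target_interval: int
    probe_freq_hz: float
    probe_level_db: float
    masker_level_db: float

    def __post_init__(self) -> None:
        if len(self.intervals) != 3:
            raise ValidationError("a 3IFC stimulus needs exactly 3 intervals")
        if self.target_interval not in (0, 1, 2):
            raise ValidationError("target_interval must be in {0, 1, 2}")


def generate_tsp(n_samples: int, stretch: int | None = None, rate_hz: float = 16000.0) -> TspPair:
    """Generate an optimized time-stretched pulse and its exact inverse.

    The sweep is defined in the frequency domain as ``H(k) =
    exp(-j*4*pi*m*k^2/N^2)`` for ``k <= N/2`` (Hermitian symmetry for the
    rest), where ``m`` is the stretch parameter controlling how far the
    energy is spread in time (group delay runs from 0 at DC to ``2*m``
    samples at Nyquist).  Since ``|H(k)| = 1`` at every bin, the complex
    conjugate spectrum is an exact circular inverse and the sweep has a
    perfectly flat magnitude spectrum.

    Parameters
    ----------
    n_samples : int
        Sweep length N; must be even and >= 2.
    stretch : int, optional
        Time-stretch parameter m >= 1.  Defaults to ``n_samples // 4`` so the
        sweep occupies roughly the first half of the buffer, leaving a guard
        interval for the response tail.
    rate_hz : float
        Sampling rate in Hz.
    """
    if not isinstance(n_samples, (int, np.integer)) or n_samples < 2:
        raise ValidationError(f"n_samples must be an integer >= 2, got {n_samples!r}")
    if n_samples % 2 != 0:
        raise ValidationError(f"n_samples must be even, got {n_samples}")
    if not (rate_hz > 0):
        raise ValidationError(f"rate_hz must be > 0, got {rate_hz}")
    if stretch is None:
        stretch = n_samples // 4
    if not isinstance(stretch, (int, np.integer)) or stretch < 1:
        raise ValidationError(f"stretch must be an integer >= 1, got {stretch!r}")

    n = int(n_samples)
    m = int(stretch)
    k = np.arange(n // 2 + 1, dtype=np.float64)
    spectrum = np.exp(-1j * 4.0 * np.pi * m * k**2 / n**2)
    sweep = irfft(spectrum, n)
    peak = float(np.max(np.abs(sweep)))
    sweep = sweep / peak
    # Inverse carries the reciprocal scale so circular convolution is exactly
    # a unit impulse at lag 0.
    inverse = irfft(np.conj(spectrum), n) * peak
    return TspPair(
        sweep=TimeSignal(sweep, rate_hz),
        inverse=TimeSignal(inverse, rate_hz),
        n_samples=n,
        stretch=m,
    )


def deconvolve(recorded: TimeSignal, inverse: TimeSignal) -> TimeSignal:
    """Deconvolve a recording by convolving it with the inverse TSP.

    Returns the full linear convolution (length ``len(recorded) +
    len(inverse) - 1``).  A sweep that starts at sample ``o`` in the
    recording yields its impulse response starting at ``o + N`` in the
    output, where N is the TSP length.
    """
    if recorded.rate_hz != inverse.rate_hz:
        raise ValidationError("recorded and inverse rates differ")
    if len(recorded) < len(inverse):
        raise ValidationError("recorded must be at least as long as the inverse")
    n_out = len(recorded) + len(inverse) - 1
    n_fft = next_fast_len(n_out)
    out = irfft(rfft(recorded.samples, n_fft) * rfft(inverse.samples, n_fft), n_fft)[:n_out]
    return TimeSignal(out, recorded.rate_hz)


def extract_ir(full: TimeSignal, start_index: int, length: int = 512) -> TimeSignal:
    """Extract a contiguous impulse-response slice from a deconvolved signal.

    The default length of 512 samples corresponds to 32 ms at 16 kHz, which
    is sufficient for transducer-to-sensor paths across the head.
    """
    if start_index < 0 or length < 1:
        raise ValidationError("start_index must be >= 0 and length >= 1")
    if start_index + length > len(full):
        raise ValidationError(
            f"slice [{start_index}, {start_index + length}) exceeds signal length {len(full)}"
        )
    return TimeSignal(full.samples[start_index : start_index + length].copy(), full.rate_hz)


def find_ir_onset(full: TimeSignal, search_start: int = 0, search_stop: int | None = None,
                  threshold_frac: float = 0.1, pre_roll: int = 0) -> int:
    """Heuristic onset locator for an impulse response buried in a
    deconvolved signal: the first sample in the search window whose
    magnitude reaches ``threshold_frac`` of the window peak, minus
    ``pre_roll`` samples of leader."""
    stop = len(full) if search_stop is None else min(search_stop, len(full))
    if not (0 <= search_start < stop):
        raise ValidationError("empty search window")
    if not (0 < threshold_frac <= 1):
        raise ValidationError("threshold_frac must be in (0, 1]")
    seg = np.abs(full.samples[search_start:stop])
    onset = int(np.argmax(seg >= threshold_frac * seg.max())) + search_start
    return max(onset - pre_roll, 0)


def bandpass_noise(rate_hz: float, duration_s: float, f_lo_hz: float = 224.0,
                   f_hi_hz: float = 1122.0, seed: int = 0) -> TimeSignal:
    """Seeded white noise band-limited by an 8th-order Butterworth bandpass.

    The default band, 224-1122 Hz, spans the third-octave edges of the
    250-1000 Hz cancellation target range.  Output is normalized to unit RMS.
    """
    if not (0 < f_lo_hz < f_hi_hz < rate_hz / 2):
        raise ValidationError(
            f"band ({f_lo_hz}, {f_hi_hz}) must satisfy 0 < lo < hi < Nyquist ({rate_hz / 2})"
        )
    if not (duration_s > 0):
        raise ValidationError("duration_s must be > 0")
    n = int(round(duration_s * rate_hz))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    sos = sps.butter(8, [f_lo_hz, f_hi_hz], btype="bandpass", fs=rate_hz, output="sos")
    out = sps.sosfilt(sos, white)
    return TimeSignal(out / rms(out), rate_hz)


def highpass(signal: TimeSignal, cutoff_hz: float = 100.0) -> TimeSignal:
    """Zero-phase 4th-order Butterworth high-pass (applied forward-backward).

    Used on sensor recordings to remove DC drift and sub-audio rumble before
    deconvolution; the 100 Hz default matches the measurement chain.
    """
    if not (0 < cutoff_hz < signal.rate_hz / 2):
        raise ValidationError(f"cutoff {cutoff_hz} Hz outside (0, Nyquist)")
    sos = sps.butter(4, cutoff_hz, btype="highpass", fs=signal.rate_hz, output="sos")
    out = sps.sosfiltfilt(sos, signal.samples)
    return TimeSignal(out, signal.rate_hz)


def third_octave_band(center_hz: float) -> tuple[float, float]:
    """Lower/upper edges of the third-octave band centred at ``center_hz``.

    ``f_lo = fc * 2**(-1/6)``, ``f_hi = fc * 2**(1/6)``; for 1000 Hz this
    gives (890.9, 1122.5) Hz, and the 250/1000 Hz edges 222.7/1122.5 Hz frame
    the 224-1122 Hz cancellation band.
    """
    if not (center_hz > 0):
        raise ValidationError("center frequency must be > 0")
    return center_hz * 2.0 ** (-1.0 / 6.0), center_hz * 2.0 ** (1.0 / 6.0)


def _raised_cosine_envelope(n: int, n_fade: int) -> np.ndarray:
    """Unit envelope with cos^2 (raised-cosine) fade-in/out ramps."""
    env = np.ones(n)
    if n_fade > 0:
        t = np.linspace(0.0, np.pi / 2.0, n_fade, endpoint=False)
        ramp = np.sin(t) ** 2
        env[:n_fade] = ramp
        env[-n_fade:] = ramp[::-1]
    return env


MASKER_DURATION_S = 0.8
TONE_DURATION_S = 0.5
FADE_S = 0.075


def build_3ifc_stimulus(probe_freq_hz: float, probe_level_db: float, masker_level_db: float,
                        rate_hz: float = 16000.0, seed: int = 0) -> IfcStimulus:
    """Assemble one 3IFC trial stimulus.

    Each of the three intervals carries an 800 ms third-octave noise masker
    centred at the probe frequency; exactly one interval (chosen uniformly at
    random under ``seed``) additionally carries a 500 ms probe tone that is
    temporally centred in the masker (onset at 150 ms).  Tone and masker both
    get 75 ms raised-cosine fades, and each component is scaled so the RMS of
    its own segment hits the requested dB re 1 V RMS level after windowing.
    """
    if not (probe_freq_hz > 0):
        raise ValidationError("probe_freq_hz must be > 0")
    if not (np.isfinite(probe_level_db) and np.isfinite(masker_level_db)):
        raise ValidationError("levels must be finite")

    n_masker = int(round(MASKER_DURATION_S * rate_hz))
    n_tone = int(round(TONE_DURATION_S * rate_hz))
    n_fade = int(round(FADE_S * rate_hz))
    onset = int(round((MASKER_DURATION_S - TONE_DURATION_S) / 2 * rate_hz))

    rng = np.random.default_rng(seed)
    target = int(rng.integers(0, 3))

    t = np.arange(n_tone) / rate_hz
    tone = np.sin(2.0 * np.pi * probe_freq_hz * t) * _raised_cosine_envelope(n_tone, n_fade)
    tone *= 10.0 ** (probe_level_db / 20.0) / rms(tone)

    f_lo, f_hi = third_octave_band(probe_freq_hz)
    intervals = []
    for i in range(3):
        masker = bandpass_noise(
            rate_hz, MASKER_DURATION_S, f_lo, f_hi,
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31),
        ).samples
        masker = masker * _raised_cosine_envelope(n_masker, n_fade)
        masker *= 10.0 ** (masker_level_db / 20.0) / rms(masker)
        if i == target:
            masker[onset : onset + n_tone] += tone
        intervals.append(TimeSignal(masker, rate_hz))

    return IfcStimulus(
        intervals=tuple(intervals),
        target_interval=target,
        probe_freq_hz=float(probe_freq_hz),
        probe_level_db=float(probe_level_db),
        masker_level_db=float(masker_level_db),
    )
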