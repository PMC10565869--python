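"""Synthetic head-path and transducer fixture generator.

Every downstream stage of the toolkit (TSP measurement, equalization, FxLMS,
verification, simulated listening tests) is exercised against this module
instead of measurement hardware.  It produces:

* a :class:`PathPair` — the transcranial *primary* path ``h_RL``
  (contralateral transducer -> error sensor, the crosstalk to be cancelled)
  and the ipsilateral *secondary* path ``h_LL`` (the route of the
  anti-signal).  Each path is a delayed sum of exponentially damped skull
  modes; both paths share one seeded set of mode frequencies and decay times
  (same skull) but differ in per-mode weights, delay and overall gain.  The
  primary path is longer and attenuated (transcranial attenuation).
* a :class:`TransducerModel` — a minimum-phase, band-limited (200-4000 Hz)
  response with seeded resonance structure standing in for an audiometric
  bone transducer; left/right pairs differ by less than 1.5 dB.
* :func:`simulate_measurement` — the virtual sensor: stereo drive signals
  convolved with the two paths plus seeded Gaussian sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import fft, ifft

from .errors import ValidationError
from .signals import StereoSignal, TimeSignal

__all__ = [
    "PathPair",
    "HeadConfig",
    "TransducerModel",
    "generate_paths",
    "generate_transducer",
    "generate_transducer_pair",
    "simulate_measurement",
]

PATH_LENGTH = 512  # taps; 32 ms at 16 kHz, matching the extraction window


@dataclass(frozen=True)
class PathPair:
    """Primary (h_RL) and secondary (h_LL) transducer-to-sensor paths."""

    h_primary: TimeSignal
    h_secondary: TimeSignal

    def __post_init__(self) -> None:
        if self.h_primary.rate_hz != self.h_secondary.rate_hz:
            raise ValidationError("path rates differ")

    @property
    def rate_hz(self) -> float:
        return self.h_primary.rate_hz


@dataclass(frozen=True)
class HeadConfig:
    """Parameters of the synthetic head model.

    Defaults emulate a plausible adult head at 16 kHz: the transcranial
    (primary) route arrives ~0.3 ms later than the ipsilateral (secondary)
    route and is 10 dB weaker broadband; both paths ring through six shared
    skull modes between 200 and 3000 Hz with 1-5 ms decay times.
    """

    rate_hz: float = 16000.0
    primary_delay_ms: float = 0.4
    secondary_delay_ms: float = 0.1
    transcranial_attenuation_db: float = 10.0
    n_modes: int = 6
    mode_band_hz: tuple[float, float] = (250.0, 3000.0)
    sensor_noise_db: float = -80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.primary_delay_ms < 0 or self.secondary_delay_ms < 0:
            raise ValidationError("delays must be >= 0")
        if self.secondary_delay_ms > self.primary_delay_ms:
            raise ValidationError("secondary delay must not exceed primary delay")
        if self.n_modes < 1:
            raise ValidationError("n_modes must be >= 1")
        lo, hi = self.mode_band_hz
        if not (0 < lo < hi < self.rate_hz / 2):
            raise ValidationError("mode_band must lie inside (0, Nyquist)")


@dataclass(frozen=True)
class TransducerModel:
    """Synthetic bone-transducer impulse response."""

    ir: TimeSignal
    label: str


def _coupling_sos(rate_hz: float) -> np.ndarray:
    """Steep causal high-pass modelling the transducer-skin-skull coupling
    roll-off: bone-conducted energy below ~200 Hz is negligible (>50 dB
    down), which also keeps the 100 Hz measurement high-pass transparent."""
    return sps.cheby2(8, 50, 195.0, btype="highpass", fs=rate_hz, output="sos")


def _modal_path(freqs: np.ndarray, decays_s: np.ndarray, amps: np.ndarray,
                delay_samples: int, rate_hz: float) -> np.ndarray:
    """Delayed sum of exponentially damped sinusoids (sine onsets, so the
    waveform starts from zero), band-limited by the coupling roll-off."""
    n = PATH_LENGTH
    t = np.arange(n - delay_samples) / rate_hz
    h = np.zeros(n)
    for f, tau, a in zip(freqs, decays_s, amps):
        h[delay_samples:] += a * np.exp(-t / tau) * np.sin(2 * np.pi * f * t)
    return sps.sosfilt(_coupling_sos(rate_hz), h)


def generate_paths(config: HeadConfig) -> PathPair:
    """Generate the primary/secondary path pair for one synthetic head.

    Both paths share one seeded set of mode frequencies and decay constants
    (the same skull) but carry independent per-mode amplitudes; the primary
    path is delayed further and scaled so its broadband energy sits exactly
    ``transcranial_attenuation_db`` below the secondary path's.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    lo, hi = config.mode_band_hz
    freqs = rng.uniform(lo, hi, size=config.n_modes)
    decays = rng.uniform(1e-3, 5e-3, size=config.n_modes)

    d_primary = int(round(config.primary_delay_ms * 1e-3 * config.rate_hz))
    d_secondary = int(round(config.secondary_delay_ms * 1e-3 * config.rate_hz))

    amps_sec = rng.uniform(0.5, 1.0, size=config.n_modes)
    amps_pri = rng.uniform(0.5, 1.0, size=config.n_modes)
    h_sec = _modal_path(freqs, decays, amps_sec, d_secondary, config.rate_hz)
    h_pri = _modal_path(freqs, decays, amps_pri, d_primary, config.rate_hz)

    # Normalize secondary to unit energy, then enforce the exact broadband
    # energy ratio between the two routes.
    h_sec = h_sec / np.linalg.norm(h_sec)
    h_pri = h_pri / np.linalg.norm(h_pri)
    h_pri = h_pri * 10.0 ** (-config.transcranial_attenuation_db / 20.0)

    return PathPair(
        h_primary=TimeSignal(h_pri, config.rate_hz),
        h_secondary=TimeSignal(h_sec, config.rate_hz),
    )


def _minimum_phase_from_magnitude(mag: np.ndarray, n_taps: int) -> np.ndarray:
    """Minimum-phase impulse response matching a magnitude spectrum, via the
    real-cepstrum (homomorphic) construction."""
    n_fft = mag.size
    log_mag = np.log(mag)
    cep = np.real(ifft(log_mag))
    fold = np.zeros_like(cep)
    fold[0] = cep[0]
    fold[1 : n_fft // 2] = 2.0 * cep[1 : n_fft // 2]
    fold[n_fft // 2] = cep[n_fft // 2]
    h = np.real(ifft(np.exp(fft(fold))))
    return h[:n_taps]


def generate_transducer(label: str, seed: int, rate_hz: float = 16000.0,
                        n_taps: int = 512) -> TransducerModel:
    """Generate one synthetic bone-transducer response.

    The magnitude target is a 200-4000 Hz bandpass shelf (raised-cosine
    skirts in log-frequency, floored 60 dB below peak) with 2-3 seeded
    resonance bumps of up to +/-3 dB, converted to a causal minimum-phase
    impulse response.  ``seed`` and ``seed + 1`` form a matched left/right
    pair whose magnitude responses differ by well under 1.5 dB in-band.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    n_fft = 4096
    f = np.abs(np.fft.fftfreq(n_fft, d=1.0 / rate_hz))
    f = np.where(f > 0, f, f[1] / 2)  # keep log() finite at DC
    logf = np.log2(f)

    lo, hi, skirt = 200.0, 4000.0, 1.0  # octaves of raised-cosine skirt
    gain_db = np.full(n_fft, -60.0)
    in_band = (f >= lo) & (f <= hi)
    gain_db[in_band] = 0.0
    lo_sel = (f < lo) & (logf > np.log2(lo) - skirt)
    x = (np.log2(lo) - logf[lo_sel]) / skirt  # 0 at the band edge -> 1 an octave out
    gain_db[lo_sel] = -60.0 * 0.5 * (1 - np.cos(np.pi * x))
    hi_sel = (f > hi) & (logf < np.log2(hi) + skirt)
    x = (logf[hi_sel] - np.log2(hi)) / skirt
    gain_db[hi_sel] = -60.0 * 0.5 * (1 - np.cos(np.pi * x))

    # Seeded resonance structure: smooth bumps in log-frequency.  The base
    # structure uses the *pair* seed (seed - seed % 2) so left/right share
    # resonances; the per-unit perturbation (below) stays within +/-0.6 dB.
    pair_rng = np.random.default_rng(np.random.SeedSequence([seed - seed % 2, 203]))
    for _ in range(3):
        fc = pair_rng.uniform(np.log2(300), np.log2(3000))
        width = pair_rng.uniform(0.3, 0.8)
        height = pair_rng.uniform(-3.0, 3.0)
        gain_db += height * np.exp(-0.5 * ((logf - fc) / width) ** 2)
    perturb_fc = rng.uniform(np.log2(250), np.log2(3500))
    perturb = rng.uniform(-0.6, 0.6) * np.exp(-0.5 * ((logf - perturb_fc) / 0.7) ** 2)
    gain_db += perturb

    mag = 10.0 ** (gain_db / 20.0)
    h = _minimum_phase_from_magnitude(mag, n_taps)
    return TransducerModel(ir=TimeSignal(h, rate_hz), label=label)


def generate_transducer_pair(seed: int, rate_hz: float = 16000.0) -> tuple[TransducerModel, TransducerModel]:
    """Matched left/right transducer pair (spectral difference < 1.5 dB)."""
    seed = seed - seed % 2
    return (
        generate_transducer("left", seed, rate_hz),
        generate_transducer("right", seed + 1, rate_hz),
    )


def simulate_measurement(paths: PathPair, stereo: StereoSignal, sensor_noise_db: float = -80.0,
                         seed: int = 0) -> TimeSignal:
    """Virtual error-sensor recording of a stereo drive signal.

    Output = right ch * h_primary + left ch * h_secondary + Gaussian noise at
    ``sensor_noise_db`` (dB re 1 V RMS); length is the full linear
    convolution length.
    """
    if paths.rate_hz != stereo.rate_hz:
        raise ValidationError("path and signal rates differ")
    y = (
        np.convolve(stereo.right.samples, paths.h_primary.samples, mode="full")
        + np.convolve(stereo.left.samples, paths.h_secondary.samples, mode="full")
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    noise = rng.standard_normal(y.size) * 10.0 ** (sensor_noise_db / 20.0)
    return TimeSignal(y + noise, paths.rate_hz)
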