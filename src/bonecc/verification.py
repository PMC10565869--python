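"""Quantify the cancellation a CTC filter achieves at the error sensor.

The verification experiment plays band-limited noise through the crosstalk
(primary) path alone, then again with the anti-noise — the same noise run
through the CTC filter and the secondary path — added.  The drop in
band-limited sensor level is the crosstalk reduction; per-third-octave
reductions resolve it across the 250-1000 Hz target range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ValidationError
from .fxlms import CTCFilter, FxLMSConfig, estimate_ctc_filter
from .signals import bandpass_noise, level_db, third_octave_band
from .synthetic_head import PathPair

__all__ = [
    "ReductionReport",
    "THIRD_OCTAVE_CENTERS_HZ",
    "measure_reduction",
    "reestimate_if_shifted",
    "write_reduction_csv",
]

# Third-octave centers spanning the 250-1000 Hz cancellation range
# (250 * 2**(k/3), k = 0..6, rounded to the conventional test frequencies).
THIRD_OCTAVE_CENTERS_HZ = (250.0, 315.0, 397.0, 500.0, 630.0, 794.0, 1000.0)

EDGE_TRIM_S = 0.1  # steady-state window excludes 100 ms at each end


@dataclass(frozen=True)
class ReductionReport:
    """Band-limited sensor levels with and without the anti-noise."""

    level_without_db: float
    level_with_db: float
    reduction_db: float
    band: tuple[float, float]
    per_third_octave: dict[float, float]
    level_without_broadband_db: float = np.nan
    level_with_broadband_db: float = np.nan

    def __post_init__(self) -> None:
        if not np.isclose(self.reduction_db, self.level_without_db - self.level_with_db):
            raise ValidationError("reduction_db must equal level_without - level_with")


def _band_level(x: np.ndarray, rate_hz: float, f_lo: float, f_hi: float) -> float:
    sos = sps.butter(4, [f_lo, f_hi], btype="bandpass", fs=rate_hz, output="sos")
    return level_db(sps.sosfiltfilt(sos, x))


def measure_reduction(paths: PathPair, ctc: CTCFilter, noise_duration_s: float = 6.0,
                      band: tuple[float, float] = (224.0, 1122.0), seed: int = 0) -> ReductionReport:
    """Simulate the verification experiment and report the level reduction.

    A ``noise_duration_s``-second noise burst band-limited to ``band`` drives
    the primary path; the anti-noise (noise -> CTC filter -> secondary path)
    is added for the "with cancellation" condition.  Levels are computed over
    the steady-state window (first/last 100 ms excluded) after zero-phase
    band-limiting, and per-third-octave reductions are filled for the
    centers covered by the requested band.
    """
    if paths.rate_hz != ctc.rate_hz:
        raise ValidationError("path and CTC filter rates differ")
    rate = paths.rate_hz
    if not (0 < band[0] < band[1] < rate / 2):
        raise ValidationError("band must lie inside (0, Nyquist)")

    noise = bandpass_noise(rate, noise_duration_s, band[0], band[1], seed=seed).samples
    without = np.convolve(noise, paths.h_primary.samples, mode="full")
    anti = np.convolve(np.convolve(noise, ctc.taps, mode="full"),
                       paths.h_secondary.samples, mode="full")
    with_ = without.copy()
    with_[: anti.size] += anti[: with_.size]

    trim = int(round(EDGE_TRIM_S * rate))
    w0 = without[trim:-trim]
    w1 = with_[trim:-trim]

    lvl_without = _band_level(w0, rate, band[0], band[1])
    lvl_with = _band_level(w1, rate, band[0], band[1])

    per_band: dict[float, float] = {}
    for fc in THIRD_OCTAVE_CENTERS_HZ:
        f_lo, f_hi = third_octave_band(fc)
        if f_lo < band[0] * 0.99 or f_hi > band[1] * 1.01:
            continue
        per_band[fc] = (_band_level(w0, rate, f_lo, f_hi)
                        - _band_level(w1, rate, f_lo, f_hi))

    return ReductionReport(
        level_without_db=lvl_without,
        level_with_db=lvl_with,
        reduction_db=lvl_without - lvl_with,
        band=band,
        per_third_octave=per_band,
        level_without_broadband_db=level_db(w0),
        level_with_broadband_db=level_db(w1),
    )


def write_reduction_csv(path, report: ReductionReport) -> None:
    """Write the per-third-octave reductions as ``center_hz,reduction_db``."""
    with open(path, "w") as fh:
        fh.write("center_hz,reduction_db\n")
        for fc, r in sorted(report.per_third_octave.items()):
            fh.write(f"{fc},{r!r}\n")


def reestimate_if_shifted(paths_new: PathPair, ctc_old: CTCFilter,
                          config: FxLMSConfig = FxLMSConfig(),
                          threshold_db: float = 10.0,
                          seed: int = 0) -> tuple[CTCFilter, ReductionReport]:
    """Keep the old CTC filter if it still cancels on the (possibly shifted)
    paths; otherwise re-run the FxLMS estimation and return the new filter.

    Mirrors the re-measurement step taken when transducers move: a filter is
    retained only while its in-band reduction stays at or above
    ``threshold_db``.
    """
    report = measure_reduction(paths_new, ctc_old, seed=seed)
    if report.reduction_db >= threshold_db:
        return ctc_old, report
    ctc_new, _ = estimate_ctc_filter(paths_new, config)
    return ctc_new, measure_reduction(paths_new, ctc_new, seed=seed)
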