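"""End-to-end pipeline: TSP measurement -> equalization -> FxLMS -> verification
-> simulated threshold evaluation.

The pipeline mirrors the full experimental procedure on the synthetic head:

1. generate transducer and head-path fixtures;
2. measure the combined transducer+head impulse responses with a staggered
   stereo TSP (sweeps at 1 s and 5.1 s), high-pass the virtual sensor
   recording at 100 Hz, deconvolve, and extract 512-tap responses;
3. design Kirkeby inverse filters from the transducer responses and equalize
   the measured impulse responses;
4. estimate the CTC filter with FxLMS on the equalized responses;
5. verify cancellation on the *unequalized* physical chain (the estimate
   survives because the two transducers differ by < 1.5 dB);
6. run simulated 2-down/1-up 3IFC staircases with and without cancellation.

The "with cancellation" listening condition models the anti-noise as a
per-frequency attenuation of the crosstalk masker at the cochlea equal to
the sensor-measured third-octave reduction, derated by a configurable
factor (default 0.35) reflecting that cancellation at the sensor does not
transfer fully to the cochlea; the effective release is capped at the
masker's 30 dB sensation level.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .equalization import RegularizationProfile, apply_equalization, flatness_metric, kirkeby_inverse
from .errors import ValidationError
from .fxlms import FxLMSConfig, estimate_ctc_filter
from .io import write_taps_csv
from .psychoacoustics import (
    SimulatedListener,
    StaircaseConfig,
    StaircaseTrack,
    run_staircase,
    threshold_improvement,
)
from .signals import StereoSignal, TimeSignal, deconvolve, extract_ir, generate_tsp, highpass
from .synthetic_head import (
    HeadConfig,
    PathPair,
    generate_paths,
    generate_transducer_pair,
    simulate_measurement,
)
from .verification import measure_reduction, write_reduction_csv

__all__ = [
    "RunConfig",
    "run_pipeline",
    "measure_paths_tsp",
    "child_seed",
]

log = logging.getLogger("bonecc")

LEFT_ONSET_S = 1.0
RIGHT_ONSET_S = 5.1


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic per-stage child seed derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of one pipeline run."""

    master_seed: int = 1
    rate_hz: float = 16000.0
    head: HeadConfig = field(default_factory=HeadConfig)
    equalization: RegularizationProfile = field(default_factory=RegularizationProfile)
    fxlms: FxLMSConfig = field(default_factory=FxLMSConfig)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    listener: SimulatedListener = field(default_factory=lambda: SimulatedListener(true_threshold_db=-50.0))
    output_dir: str = "bonecc_out"
    tsp_samples: int = 32728
    derating: float = 0.35
    sensation_level_db: float = 30.0
    test_freqs_hz: tuple[float, ...] = (250.0, 315.0, 397.0, 500.0, 630.0, 794.0, 1000.0)
    use_transducers: bool = True

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build a RunConfig from a plain mapping, validating sub-configs."""
        sub = {
            "head": HeadConfig,
            "equalization": RegularizationProfile,
            "fxlms": FxLMSConfig,
            "staircase": StaircaseConfig,
            "listener": SimulatedListener,
        }
        kwargs: dict = {}
        for key, value in data.items():
            if key in sub:
                if not isinstance(value, dict):
                    raise ValidationError(f"config section '{key}' must be a mapping")
                try:
                    kwargs[key] = sub[key](**value)
                except TypeError as exc:
                    raise ValidationError(f"config section '{key}': {exc}") from exc
            elif key in {f.name for f in dataclasses.fields(cls)}:
                kwargs[key] = tuple(value) if key == "test_freqs_hz" else value
            else:
                raise ValidationError(f"unknown config key '{key}'")
        if "listener" in data and "true_threshold_db" not in data["listener"]:
            raise ValidationError("config section 'listener' is missing required key 'true_threshold_db'")
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ValidationError(f"invalid run config: {exc}") from exc


def measure_paths_tsp(paths: PathPair, tsp_samples: int = 32728, sensor_noise_db: float = -80.0,
                      seed: int = 0, ir_length: int = 512,
                      highpass_cutoff_hz: float | None = 100.0,
                      onsets_s: tuple[float, float] = (LEFT_ONSET_S, RIGHT_ONSET_S)) -> PathPair:
    """Measure a PathPair through the staggered-TSP procedure.

    Builds a stereo signal with the left-channel sweep at ``onsets_s[0]``
    (default 1 s) and the right-channel sweep at ``onsets_s[1]`` (default
    5.1 s), records it through the virtual sensor, high-passes at 100 Hz,
    deconvolves with the inverse TSP, and extracts ``ir_length``-tap
    responses.  Extraction sums the three alias windows of each deconvolved
    sweep (offsets ``o``, ``o + N`` and ``o + 2N``), which reconstructs the
    exact circular deconvolution and cancels the sweep's linear-convolution
    leakage.  With the default onsets the two sweeps' windows overlap by a
    few hundred samples of leakage tail, leaving a ~5e-4 relative residual;
    a right onset of ``>= onsets_s[0] + (2 * tsp_samples + ir_length) /
    rate`` removes the overlap entirely.
    """
    rate = paths.rate_hz
    tsp = generate_tsp(tsp_samples, rate_hz=rate)
    n = tsp.n_samples
    o_left = int(round(onsets_s[0] * rate))
    o_right = int(round(onsets_s[1] * rate))
    if o_left >= o_right:
        raise ValidationError("left sweep onset must precede the right sweep onset")
    total = o_right + 3 * n + ir_length + int(0.1 * rate)

    left = np.zeros(total)
    right = np.zeros(total)
    # Sweep playback level: -20 dB re 1 V RMS over the sweep segment.
    gain = 10.0 ** (-20.0 / 20.0) / tsp.sweep.rms()
    left[o_left : o_left + n] = tsp.sweep.samples * gain
    right[o_right : o_right + n] = tsp.sweep.samples * gain
    stereo = StereoSignal(left=TimeSignal(left, rate), right=TimeSignal(right, rate))

    recorded = simulate_measurement(paths, stereo, sensor_noise_db=sensor_noise_db, seed=seed)
    filtered = highpass(recorded, highpass_cutoff_hz) if highpass_cutoff_hz else recorded
    dec = deconvolve(filtered, tsp.inverse)

    def fold(onset: int) -> TimeSignal:
        ir = np.zeros(ir_length)
        for j in range(3):
            start = onset + j * n
            ir += dec.samples[start : start + ir_length]
        return TimeSignal(ir / gain, rate)

    return PathPair(h_primary=fold(o_right), h_secondary=fold(o_left))


def _staircase_rows(track: StaircaseTrack) -> list[tuple[int, float, int, int]]:
    rev = set(track.reversal_trials)
    return [(i, lvl, int(ok), int(i in rev)) for i, (lvl, ok) in enumerate(track.trials)]


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute the full crosstalk-cancellation pipeline; returns the summary
    dict (and writes CSV/JSON artifacts unless ``write_outputs=False``)."""
    out_dir = Path(config.output_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)

    rate = config.rate_hz
    seed = config.master_seed
    log.info("pipeline start: master_seed=%d rate=%g Hz", seed, rate)

    # --- stage 1: fixtures -------------------------------------------------
    head = dataclasses.replace(config.head, rate_hz=rate)
    paths = generate_paths(head)
    log.info("generated head paths: seed=%d attenuation=%g dB", head.seed,
             head.transcranial_attenuation_db)

    t_left, t_right = generate_transducer_pair(child_seed(seed, 1), rate)

    if config.use_transducers:
        chain = PathPair(
            h_primary=TimeSignal(np.convolve(t_right.ir.samples, paths.h_primary.samples), rate),
            h_secondary=TimeSignal(np.convolve(t_left.ir.samples, paths.h_secondary.samples), rate),
        )
    else:
        chain = paths

    # --- stage 2: TSP measurement -----------------------------------------
    measured = measure_paths_tsp(
        chain, tsp_samples=config.tsp_samples, sensor_noise_db=head.sensor_noise_db,
        seed=child_seed(seed, 2),
    )
    log.info("measured impulse responses via staggered TSP (N=%d, noise=%g dB)",
             config.tsp_samples, head.sensor_noise_db)

    # --- stage 3: transducer equalization ----------------------------------
    if config.use_transducers:
        eq_left = kirkeby_inverse(t_left.ir, config.equalization.scaled_to(
            float(np.max(np.abs(np.fft.fft(t_left.ir.samples, 4096))) ** 2)))
        eq_right = kirkeby_inverse(t_right.ir, config.equalization.scaled_to(
            float(np.max(np.abs(np.fft.fft(t_right.ir.samples, 4096))) ** 2)))
        eq_rl = apply_equalization(measured.h_primary, eq_right)
        eq_ll = apply_equalization(measured.h_secondary, eq_left)
        d = eq_left.modeling_delay
        est_paths = PathPair(
            h_primary=extract_ir(eq_rl, d, 512),
            h_secondary=extract_ir(eq_ll, d, 512),
        )
        flat_left = flatness_metric(
            apply_equalization(t_left.ir, eq_left), 200.0, 4000.0)
        flat_right = flatness_metric(
            apply_equalization(t_right.ir, eq_right), 200.0, 4000.0)
        log.info("equalized transducer flatness: left=%.2f dB right=%.2f dB",
                 flat_left, flat_right)
    else:
        est_paths = measured
        flat_left = flat_right = None

    # --- stage 4: FxLMS CTC estimation -------------------------------------
    fx_cfg = dataclasses.replace(config.fxlms, seed=child_seed(seed, 3))
    ctc, trace = estimate_ctc_filter(est_paths, fx_cfg)
    log.info("FxLMS finished: %d taps, converged_at=%s s", ctc.p, trace.converged_at_s)

    # --- stage 5: verification on the physical chain -----------------------
    report = measure_reduction(chain, ctc, seed=child_seed(seed, 4))
    log.info("in-band reduction %.2f dB (without %.2f / with %.2f dB re 1 V RMS)",
             report.reduction_db, report.level_without_db, report.level_with_db)

    # --- stage 6: simulated threshold evaluation ---------------------------
    improvements: dict[float, float] = {}
    thresholds: dict[float, dict[str, float]] = {}
    tracks: dict[str, StaircaseTrack] = {}
    for i, fc in enumerate(config.test_freqs_hz):
        base = config.listener.true_threshold_db
        release = min(config.derating * report.per_third_octave.get(fc, report.reduction_db),
                      config.sensation_level_db)
        without = run_staircase(config.listener, config.staircase,
                                seed=child_seed(seed, 10 + 2 * i))
        with_listener = dataclasses.replace(config.listener, true_threshold_db=base - release)
        with_ = run_staircase(with_listener, config.staircase,
                              seed=child_seed(seed, 11 + 2 * i))
        improvements[fc] = threshold_improvement(without.threshold_db, with_.threshold_db)
        thresholds[fc] = {"without_db": without.threshold_db, "with_db": with_.threshold_db}
        tracks[f"staircase_{int(fc)}Hz_without"] = without
        tracks[f"staircase_{int(fc)}Hz_with"] = with_
        log.info("%g Hz: threshold %.2f -> %.2f dB (improvement %.2f dB)",
                 fc, without.threshold_db, with_.threshold_db, improvements[fc])

    summary = {
        "master_seed": seed,
        "rate_hz": rate,
        "reduction_db": report.reduction_db,
        "level_without_db": report.level_without_db,
        "level_with_db": report.level_with_db,
        "per_third_octave_reduction_db": {str(k): v for k, v in report.per_third_octave.items()},
        "equalized_flatness_db": {"left": flat_left, "right": flat_right},
        "fxlms_converged_at_s": trace.converged_at_s,
        "threshold_improvements_db": {str(k): v for k, v in improvements.items()},
        "thresholds_db": {str(k): v for k, v in thresholds.items()},
        "mean_threshold_improvement_db": float(np.mean(list(improvements.values()))),
    }

    if write_outputs:
        write_taps_csv(out_dir / "h_primary.csv", paths.h_primary)
        write_taps_csv(out_dir / "h_secondary.csv", paths.h_secondary)
        write_taps_csv(out_dir / "h_primary_measured.csv", est_paths.h_primary)
        write_taps_csv(out_dir / "h_secondary_measured.csv", est_paths.h_secondary)
        write_taps_csv(out_dir / "ctc_filter.csv", ctc.taps)
        write_reduction_csv(out_dir / "reduction_per_band.csv", report)
        if config.use_transducers:
            write_taps_csv(out_dir / "eq_left.csv", eq_left.taps)
            write_taps_csv(out_dir / "eq_right.csv", eq_right.taps)
        with open(out_dir / "error_trace.csv", "w") as fh:
            fh.write("sample,error\n")
            step = max(1, trace.error_history.size // 10000)
            for i in range(0, trace.error_history.size, step):
                fh.write(f"{i},{trace.error_history[i]!r}\n")
        for name, track in tracks.items():
            with open(out_dir / f"{name}.csv", "w") as fh:
                fh.write("trial,level_db,correct,is_reversal\n")
                for row in _staircase_rows(track):
                    fh.write(",".join(map(str, row)) + "\n")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        log.info("wrote artifacts to %s", out_dir)

    return summary
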