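"""Adaptive psychophysics: 2-down/1-up 3IFC staircases, bracketing
audiometry, simulated listeners, and the threshold-difference measures.

The transformed up-down staircase converges to the level where the
probability of a correct response is sqrt(1/2) ~ 70.7% — the "2-down/1-up
point" of the psychometric function.  Human observers are replaced by a
:class:`SimulatedListener` with a logistic psychometric function

    p(L) = guess + (1 - guess - lapse) * logistic((L - threshold) / slope)

with guess rate 1/3 for a three-interval forced choice.  All randomness is
seeded, so a (listener, config, seed) triple maps to exactly one track.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .errors import NonConvergenceError, ValidationError

__all__ = [
    "StaircaseConfig",
    "SimulatedListener",
    "StaircaseTrack",
    "BracketingConfig",
    "staircase_update",
    "simulate_response",
    "run_staircase",
    "run_bracketing",
    "threshold_improvement",
    "occlusion_effect",
    "two_down_one_up_point",
    "AUDIOMETRIC_FREQS_HZ",
]

AUDIOMETRIC_FREQS_HZ = (1000.0, 250.0, 500.0, 2000.0, 4000.0)  # measured starting at 1 kHz

TRIAL_CAP = 500


@dataclass(frozen=True)
class StaircaseConfig:
    """2-down/1-up transformed up-down staircase parameters.

    Defaults follow the standard adaptive 3IFC threshold procedure: start at
    -20 dB re 1 V RMS, 4 dB steps shrinking to 2 dB after the 4th reversal,
    stop at 12 reversals, threshold = mean of the last 8 reversal levels.
    """

    initial_level_db: float = -20.0
    step_large_db: float = 4.0
    step_small_db: float = 2.0
    reversals_to_small_step: int = 4
    total_reversals: int = 12
    reversals_averaged: int = 8
    n_intervals: int = 3
    down_rule: int = 2
    up_rule: int = 1

    def __post_init__(self) -> None:
        if not (self.step_large_db > 0 and self.step_small_db > 0):
            raise ValidationError("step sizes must be > 0")
        if self.reversals_averaged > self.total_reversals:
            raise ValidationError("reversals_averaged must be <= total_reversals")
        if self.down_rule < 1 or self.up_rule < 1:
            raise ValidationError("down/up rules must be >= 1")


@dataclass(frozen=True)
class SimulatedListener:
    """Logistic-psychometric virtual observer.

    ``true_threshold_db`` is the psychometric midpoint (50% of the
    guess-to-ceiling range); ``slope_db`` is the inverse steepness in dB.
    """

    true_threshold_db: float
    slope_db: float = 1.0
    guess_rate: float = 1.0 / 3.0
    lapse_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.slope_db > 0):
            raise ValidationError("slope_db must be > 0")
        if not (0 <= self.guess_rate < 1 and 0 <= self.lapse_rate <= 0.1):
            raise ValidationError("guess_rate in [0,1), lapse_rate in [0, 0.1]")

    def p_correct(self, level_db: float) -> float:
        psi = expit((level_db - self.true_threshold_db) / self.slope_db)
        return float(self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * psi)


@dataclass(frozen=True)
class StaircaseTrack:
    """Complete trial/reversal history of one staircase run."""

    config: StaircaseConfig
    trials: tuple[tuple[float, bool], ...] = ()
    reversal_levels: tuple[float, ...] = ()
    reversal_trials: tuple[int, ...] = ()
    threshold_db: float | None = None
    finished: bool = False
    current_level_db: float = 0.0
    consecutive_correct: int = 0
    last_direction: int = 0  # -1 down, +1 up, 0 none yet

    @classmethod
    def fresh(cls, config: StaircaseConfig) -> "StaircaseTrack":
        return cls(config=config, current_level_db=config.initial_level_db)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _current_step(config: StaircaseConfig, n_reversals: int) -> float:
    if n_reversals >= config.reversals_to_small_step:
        return config.step_small_db
    return config.step_large_db


def staircase_update(track: StaircaseTrack, correct: bool,
                     config: StaircaseConfig | None = None) -> StaircaseTrack:
    """Apply one trial outcome to a staircase track.

    The level drops by the current step after ``down_rule`` consecutive
    correct responses and rises after any incorrect one; a reversal is
    logged at the trial where the prescribed direction flips (standard
    transformed up-down bookkeeping).  The consecutive-correct counter
    resets on any incorrect response and on every level change.  The track
    finishes at ``total_reversals`` reversals, with the threshold set to the
    exact arithmetic mean of the last ``reversals_averaged`` reversal
    levels.
    """
    if config is None:
        config = track.config
    if track.finished:
        raise ValidationError("cannot update a finished track")

    level = track.current_level_db
    trials = track.trials + ((level, bool(correct)),)
    reversals = track.reversal_levels
    reversal_trials = track.reversal_trials
    consecutive = track.consecutive_correct
    direction = track.last_direction

    move = 0
    if correct:
        consecutive += 1
        if consecutive >= config.down_rule:
            move = -1
            consecutive = 0
    else:
        move = +1
        consecutive = 0

    new_level = level
    if move != 0:
        if direction != 0 and move != direction:
            reversals = reversals + (level,)
            reversal_trials = reversal_trials + (len(trials) - 1,)
        step = _current_step(config, len(reversals))
        new_level = level + move * step
        direction = move

    finished = len(reversals) >= config.total_reversals
    threshold = None
    if finished:
        tail = reversals[-config.reversals_averaged:]
        threshold = float(np.mean(tail))

    return replace(
        track,
        trials=trials,
        reversal_levels=reversals,
        reversal_trials=reversal_trials,
        threshold_db=threshold,
        finished=finished,
        current_level_db=new_level,
        consecutive_correct=consecutive,
        last_direction=direction,
    )


def simulate_response(listener: SimulatedListener, stimulus_level_db: float,
                      trial_index: int, seed: int | None = None) -> bool:
    """One Bernoulli response from the virtual observer, deterministic in
    ((seed or listener.seed), trial_index)."""
    base = listener.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([base, trial_index]))
    return bool(rng.random() < listener.p_correct(stimulus_level_db))


def run_staircase(listener: SimulatedListener, config: StaircaseConfig = StaircaseConfig(),
                  seed: int = 0) -> StaircaseTrack:
    """Run one full 2-down/1-up staircase against a simulated listener."""
    track = StaircaseTrack.fresh(config)
    combined = int(np.random.SeedSequence([seed, listener.seed]).generate_state(1)[0] % 2**31)
    for trial in range(TRIAL_CAP):
        correct = simulate_response(listener, track.current_level_db, trial, seed=combined)
        track = staircase_update(track, correct, config)
        if track.finished:
            return track
    raise NonConvergenceError(
        f"staircase did not reach {config.total_reversals} reversals within {TRIAL_CAP} trials"
    )


@dataclass(frozen=True)
class BracketingConfig:
    """Bracketing (descending/ascending) audiometry parameters: 10 dB down
    from a clearly audible start, 5 dB up after inaudible, threshold = the
    lowest level detected in at least 2 of 3 presentations."""

    start_level_db: float = 30.0
    down_step_db: float = 10.0
    up_step_db: float = 5.0
    detections_required: int = 2
    presentations: int = 3

    def __post_init__(self) -> None:
        if not (self.down_step_db > 0 and self.up_step_db > 0):
            raise ValidationError("steps must be > 0")
        if not (1 <= self.detections_required <= self.presentations):
            raise ValidationError("detections_required must be in [1, presentations]")


def _bracket_one(listener: SimulatedListener, config: BracketingConfig, rng_seed: int,
                 floor_db: float = -120.0) -> float:
    """One-frequency bracketing run; returns the threshold on the 5 dB grid."""
    def detected(level: float, trial: int) -> bool:
        return simulate_response(listener, level, trial, seed=rng_seed)

    trial = 0
    level = config.start_level_db
    # Descend in 10 dB steps until a presentation goes unheard.
    while level > floor_db:
        if not detected(level, trial):
            trial += 1
            break
        trial += 1
        level -= config.down_step_db
    else:
        return floor_db

    best: float | None = None
    # Alternate 5-dB ascents and 10-dB descents, scoring 2-of-3 at each level.
    for _ in range(TRIAL_CAP):
        hits = sum(detected(level, trial + k) for k in range(config.presentations))
        trial += config.presentations
        if hits >= config.detections_required:
            best = level if best is None else min(best, level)
            level -= config.down_step_db
        else:
            level += config.up_step_db
            if best is not None and level >= best:
                return best
        if level <= floor_db:
            return floor_db if best is None else best
    raise NonConvergenceError("bracketing did not settle within the trial cap")


def run_bracketing(listener: SimulatedListener, config: BracketingConfig = BracketingConfig(),
                   freqs_hz: tuple[float, ...] = AUDIOMETRIC_FREQS_HZ, seed: int = 0,
                   threshold_by_freq: dict[float, float] | None = None) -> dict[float, float]:
    """Bracketing audiometry across frequencies (1000 Hz first, then the
    remaining octave frequencies).

    Bracketing audiometry is a yes/no detection task, so the listener's
    forced-choice guess rate does not apply: responses use a zero guess rate
    regardless of the listener's ``guess_rate`` field.

    ``threshold_by_freq`` optionally overrides the listener's true threshold
    per frequency (e.g. to model occlusion); otherwise the listener's single
    ``true_threshold_db`` applies everywhere.
    """
    out: dict[float, float] = {}
    for i, f in enumerate(freqs_hz):
        lst = replace(listener, guess_rate=0.0)
        if threshold_by_freq is not None:
            if f not in threshold_by_freq:
                raise ValidationError(f"no threshold override for {f} Hz")
            lst = replace(lst, true_threshold_db=threshold_by_freq[f])
        rng_seed = int(np.random.SeedSequence([seed, listener.seed, i]).generate_state(1)[0] % 2**31)
        out[f] = _bracket_one(lst, config, rng_seed)
    return out


def threshold_improvement(without_db: float, with_db: float) -> float:
    """Threshold improvement = threshold without minus threshold with
    cancellation (positive means cancellation lowered the threshold)."""
    if not (np.isfinite(without_db) and np.isfinite(with_db)):
        raise ValidationError("thresholds must be finite")
    return float(without_db - with_db)


def occlusion_effect(occluded_thresholds: dict[float, float],
                     unoccluded_thresholds: dict[float, float]) -> dict[float, float]:
    """Per-frequency occlusion effect: unoccluded minus occluded BC
    threshold (positive = occlusion makes BC sounds easier to hear)."""
    if set(occluded_thresholds) != set(unoccluded_thresholds):
        raise ValidationError("occluded/unoccluded frequency sets differ")
    return {f: unoccluded_thresholds[f] - occluded_thresholds[f]
            for f in occluded_thresholds}


def two_down_one_up_point(listener: SimulatedListener, bracket_db: float = 200.0) -> float:
    """Level at which p(correct) = sqrt(1/2), the asymptotic convergence
    point of the 2-down/1-up rule, found by root-finding on the listener's
    psychometric function."""
    target = np.sqrt(0.5)
    ceiling = 1.0 - listener.lapse_rate
    if not (listener.guess_rate < target < ceiling):
        raise ValidationError("70.7% point lies outside the psychometric range")
    f = lambda L: listener.p_correct(L) - target
    lo = listener.true_threshold_db - bracket_db
    hi = listener.true_threshold_db + bracket_db
    return float(brentq(f, lo, hi))
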