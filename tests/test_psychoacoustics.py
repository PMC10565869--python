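"""Adaptive staircases, bracketing audiometry, simulated listeners."""

import numpy as np
import pytest

from bonecc import (
    BracketingConfig,
    NonConvergenceError,
    SimulatedListener,
    StaircaseConfig,
    ValidationError,
    occlusion_effect,
    run_bracketing,
    run_staircase,
    simulate_response,
    staircase_update,
    threshold_improvement,
    two_down_one_up_point,
)
from bonecc.psychoacoustics import AUDIOMETRIC_FREQS_HZ, StaircaseTrack


def play_sequence(responses, config=StaircaseConfig()):
    track = StaircaseTrack.fresh(config)
    for r in responses:
        track = staircase_update(track, r, config)
        if track.finished:
            break
    return track


class TestStaircaseUpdate:
    def test_first_incorrect_raises_level_without_reversal(self):
        track = play_sequence([False])
        assert track.current_level_db == -20.0 + 4.0
        assert track.reversal_levels == ()

    def test_single_correct_does_not_move(self):
        track = play_sequence([True])
        assert track.current_level_db == -20.0
        assert track.consecutive_correct == 1

    def test_two_consecutive_correct_move_down(self):
        track = play_sequence([True, True])
        assert track.current_level_db == -24.0
        assert track.reversal_levels == ()  # first move, nothing to reverse

    def test_hand_simulated_track_matches_enumeration(self):
        # Repeating [correct, correct, wrong] from -20 dB, traced by hand:
        # the first down-move happens at trial 1 without a reversal; every
        # subsequent direction flip logs one.  After reversal 4 the step
        # drops from 4 to 2 dB, so the track oscillates -20 <-> -22 and the
        # 12th reversal lands at trial 19 with threshold mean(-22,-20,...)
        # = -21 dB.
        responses = [True, True, False] * 6 + [True, True]
        track = play_sequence(responses)
        assert track.finished
        assert track.reversal_levels == (
            -24.0, -20.0, -24.0, -20.0,
            -22.0, -20.0, -22.0, -20.0, -22.0, -20.0, -22.0, -20.0,
        )
        assert track.threshold_db == -21.0
        assert track.n_trials == 20

    def test_threshold_is_exact_mean_of_last_eight_reversals(self):
        responses = [True, True, False] * 6 + [True, True]
        track = play_sequence(responses)
        assert track.threshold_db == np.mean(track.reversal_levels[-8:])

    def test_update_on_finished_track_rejected(self):
        track = play_sequence([True, True, False] * 6 + [True, True])
        with pytest.raises(ValidationError):
            staircase_update(track, True)


class TestSimulateResponse:
    def test_easy_level_always_correct(self):
        lst = SimulatedListener(true_threshold_db=-50.0, slope_db=1.0, seed=0)
        assert all(simulate_response(lst, 50.0, i) for i in range(100))

    def test_midpoint_probability_is_two_thirds(self):
        lst = SimulatedListener(true_threshold_db=-50.0, slope_db=2.0, seed=9)
        assert lst.p_correct(-50.0) == pytest.approx(2.0 / 3.0)
        hits = sum(simulate_response(lst, -50.0, i) for i in range(10_000))
        assert hits / 10_000 == pytest.approx(2.0 / 3.0, abs=0.015)

    def test_deterministic_in_seed_and_trial(self):
        lst = SimulatedListener(true_threshold_db=-50.0, slope_db=1.0, seed=3)
        a = [simulate_response(lst, -50.0, i) for i in range(50)]
        b = [simulate_response(lst, -50.0, i) for i in range(50)]
        assert a == b


class TestRunStaircase:
    def test_track_has_twelve_reversals_and_exact_threshold(self):
        lst = SimulatedListener(true_threshold_db=-50.0, slope_db=1.0, seed=7)
        track = run_staircase(lst, StaircaseConfig(), seed=1)
        assert track.finished
        assert len(track.reversal_levels) == 12
        assert track.threshold_db == np.mean(track.reversal_levels[-8:])
        # rederive the reversal bookkeeping from the trial log
        replay = play_sequence([ok for _, ok in track.trials])
        assert replay.reversal_levels == track.reversal_levels
        assert replay.threshold_db == track.threshold_db

    def test_mean_estimate_matches_analytic_seventy_point_seven(self):
        # Across 200 seeds the staircase mean lands within 1 dB of the level
        # where p(correct) = sqrt(1/2), computed by root-finding.
        lst = SimulatedListener(true_threshold_db=-50.0, slope_db=0.5, seed=3)
        target = two_down_one_up_point(lst)
        ests = [run_staircase(lst, StaircaseConfig(), seed=s).threshold_db for s in range(200)]
        assert abs(np.mean(ests) - target) < 1.0

    def test_bias_bounded_for_shallow_listener_with_lapses(self):
        lst = SimulatedListener(true_threshold_db=-45.0, slope_db=2.0, lapse_rate=0.02, seed=5)
        target = two_down_one_up_point(lst)
        ests = [run_staircase(lst, StaircaseConfig(), seed=s).threshold_db for s in range(200)]
        assert abs(np.mean(ests) - target) < 2.0

    def test_infallible_listener_descends_to_trial_cap(self):
        lst = SimulatedListener(true_threshold_db=-1e6, slope_db=1.0, seed=0)
        with pytest.raises(NonConvergenceError):
            run_staircase(lst, StaircaseConfig(), seed=0)

    def test_identical_inputs_identical_track(self):
        lst = SimulatedListener(true_threshold_db=-50.0, slope_db=1.0, seed=2)
        a = run_staircase(lst, StaircaseConfig(), seed=9)
        b = run_staircase(lst, StaircaseConfig(), seed=9)
        assert a.trials == b.trials and a.threshold_db == b.threshold_db


class TestBracketing:
    def test_step_listener_lands_on_grid_threshold(self):
        # Deterministic detection above -42 dB: bracketing reports the
        # lowest 5 dB grid level still detected, i.e. -40 dB.
        lst = SimulatedListener(true_threshold_db=-42.0, slope_db=1e-3, seed=2)
        out = run_bracketing(lst, BracketingConfig(), seed=4)
        assert all(v == -40.0 for v in out.values())

    def test_all_detecting_listener_returns_probe_floor(self):
        lst = SimulatedListener(true_threshold_db=-1e6, slope_db=1.0, seed=2)
        out = run_bracketing(lst, BracketingConfig(), freqs_hz=(1000.0,), seed=4)
        assert out[1000.0] == -120.0

    def test_results_live_on_5_db_grid(self):
        lst = SimulatedListener(true_threshold_db=-37.0, slope_db=2.0, seed=6)
        out = run_bracketing(lst, BracketingConfig(start_level_db=30.0), seed=8)
        for v in out.values():
            assert v % 5.0 == 0.0

    def test_frequency_order_starts_at_1000_hz(self):
        assert AUDIOMETRIC_FREQS_HZ[0] == 1000.0
        assert set(AUDIOMETRIC_FREQS_HZ) == {250.0, 500.0, 1000.0, 2000.0, 4000.0}


class TestThresholdDifferences:
    def test_example_improvement(self):
        # thresholds -50.75 dB without and -65 dB with cancellation give a
        # 14.25 dB improvement
        assert threshold_improvement(-50.75, -65.0) == pytest.approx(14.25)

    def test_zero_and_antisymmetry(self):
        assert threshold_improvement(-40.0, -40.0) == 0.0
        assert threshold_improvement(-40.0, -50.0) == -threshold_improvement(-50.0, -40.0)

    def test_occlusion_effect_identity_and_sign(self):
        freqs = (250.0, 500.0, 1000.0, 2000.0, 4000.0)
        same = {f: -40.0 for f in freqs}
        assert all(v == 0.0 for v in occlusion_effect(same, same).values())

    def test_occlusion_effect_recovers_simulated_shift(self):
        # A listener whose BC threshold drops 15 dB at 250 Hz under
        # occlusion shows a +15 dB effect there (within the 5 dB grid).
        lst = SimulatedListener(true_threshold_db=-42.0, slope_db=1e-3, seed=2)
        unocc = run_bracketing(lst, BracketingConfig(), seed=4)
        occluded_truth = {f: (-57.0 if f == 250.0 else -42.0) for f in AUDIOMETRIC_FREQS_HZ}
        occ = run_bracketing(lst, BracketingConfig(), seed=5, threshold_by_freq=occluded_truth)
        effect = occlusion_effect(occ, unocc)
        assert abs(effect[250.0] - 15.0) <= 5.0
        assert all(abs(v) <= 5.0 for f, v in effect.items() if f != 250.0)

    def test_key_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            occlusion_effect({250.0: -40.0}, {500.0: -40.0})
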