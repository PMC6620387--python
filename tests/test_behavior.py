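"""Pedal-trace parsing and task-performance metrics."""
import numpy as np
import pytest

from lateralize.behavior import (
    NOT_REACHED,
    block_complete,
    choice_rate_series,
    classify_trials,
    detect_release_event,
    find_holding_periods,
    locate_release_onset,
    performance_summary,
    trials_to_criterion,
)
from lateralize.core import BlockSpec, PedalTrace, TrialRecord


def make_trace(right, left, fs=1000.0):
    n = len(right)
    return PedalTrace(times=np.arange(n) / fs, right_pos=np.asarray(right, float),
                      left_pos=np.asarray(left, float))


def flat(value, seconds, fs=1000.0):
    return [value] * int(seconds * fs)


class TestHoldingPeriods:
    def test_two_second_hold_found(self):
        tr = make_trace(flat(10, 2.0), flat(10, 2.0))
        periods = find_holding_periods(tr)
        assert len(periods) == 1
        t0, t1 = periods[0]
        assert t1 - t0 == pytest.approx(2.0, abs=0.002)

    def test_sub_second_hold_rejected(self):
        right = flat(10, 0.8) + flat(50, 0.5)
        left = flat(10, 1.3)
        assert find_holding_periods(make_trace(right, left)) == []

    def test_one_pedal_outside_area(self):
        tr = make_trace(flat(40, 3.0), flat(10, 3.0))
        assert find_holding_periods(tr) == []

    def test_empty_trace_errors(self):
        with pytest.raises(ValueError):
            PedalTrace(times=np.array([]), right_pos=np.array([]),
                       left_pos=np.array([]))


class TestReleaseEvent:
    def test_ramp_crossing(self):
        # right pedal ramps 10 -> 70 over [2.0, 2.3] s: crosses 30 at 2.1
        ramp = list(10 + 200.0 * np.arange(0, 0.3, 0.001))
        right = flat(10, 2.0) + ramp
        left = flat(10, 2.3)
        tr = make_trace(right, left)
        interval = find_holding_periods(tr)[0]
        side, t = detect_release_event(tr, interval)
        assert side == "right"
        assert t == pytest.approx(2.101, abs=0.002)

    def test_simultaneous_crossing_is_bilateral(self):
        ramp = flat(10, 1.5) + flat(50, 0.2)
        tr = make_trace(ramp, list(ramp))
        interval = find_holding_periods(tr)[0]
        assert detect_release_event(tr, interval)[0] == "bilateral"

    def test_trace_ending_in_hold_gives_none(self):
        tr = make_trace(flat(10, 2.0), flat(10, 2.0))
        interval = find_holding_periods(tr)[0]
        assert detect_release_event(tr, interval) is None


class TestReleaseOnset:
    def test_linear_ramp_closed_form(self):
        """Baseline 2%, rise 1%/ms from t0=2.0 s: onset when exceeding
        baseline + 5 -> t0 + 5 ms, event (>30%) at t0 + 28 ms."""
        rise = list(2 + 1.0 * np.arange(0, 60, 1.0))  # 1%/ms for 60 ms
        right = flat(2, 2.0) + rise + flat(62, 0.2)
        left = flat(2, 2.26)
        tr = make_trace(right, left)
        side, event = detect_release_event(tr, find_holding_periods(tr)[0])
        assert event == pytest.approx(2.029, abs=0.002)
        onset = locate_release_onset(tr, side, event)
        assert onset == pytest.approx(2.006, abs=0.002)

    def test_instantaneous_jump(self):
        right = flat(2, 2.0) + flat(60, 0.2)
        tr = make_trace(right, flat(2, 2.2))
        side, event = detect_release_event(tr, find_holding_periods(tr)[0])
        onset = locate_release_onset(tr, side, event)
        assert onset == pytest.approx(event)

    def test_retreat_then_final_rise(self):
        """A rise above the threshold that retreats is ignored: onset sits on
        the final sustained exceedance (brute-force backward-scan oracle)."""
        fs = 1000.0
        base = flat(0, 2.0)
        blip = [6, 6, 6, 0, 0, 0]  # exceeds 5, retreats
        rise = list(np.linspace(0, 60, 40))
        right = base + blip + flat(0, 0.1) + rise
        left = flat(0, (len(right)) / fs)
        tr = make_trace(right, left)
        side, event = detect_release_event(tr, find_holding_periods(tr)[0])
        onset = locate_release_onset(tr, side, event)

        # oracle: walk back from the event while samples exceed baseline + 5
        pos = tr.right_pos
        i_ev = int(np.searchsorted(tr.times, event))
        j = i_ev
        while pos[j - 1] > 5.0:
            j -= 1
        assert onset == pytest.approx(tr.times[j])
        assert onset > 2.1  # beyond the retreating blip


class TestClassifyTrials:
    def test_outcomes_match_generator_truth(self, default_session):
        cfg, session, truth = default_session
        trials = classify_trials(session.pedal, session.blocks)
        assert len(trials) == len(truth.trials)
        got = [t.outcome for t in trials]
        assert got == list(truth.trials.outcome)
        got_sides = [t.chosen_side for t in trials]
        assert got_sides == list(truth.trials.chosen_side)

    def test_onset_recovery_within_one_sample_without_wiggle(self):
        from lateralize.simulate import SimConfig, simulate_session

        cfg = SimConfig(seed=5, n_trials_per_block=10, n_blocks=2,
                        within_hold_wiggle=0.0, emg_enabled=False,
                        lfp_enabled=False, unit_specs=[])
        session, truth = simulate_session(cfg)
        trials = classify_trials(session.pedal, session.blocks)
        dt = 1.0 / session.pedal.sampling_rate
        for rec, (_, row) in zip(trials, truth.trials.iterrows()):
            assert abs(rec.release_onset_time - row.release_onset) <= dt + 1e-9
            assert abs(rec.release_event_time - row.release_event) <= dt + 1e-9
            assert abs(rec.holding_duration - row.holding_duration) <= 2 * dt

    def test_correct_requires_block_side_and_full_hold(self):
        with pytest.raises(ValueError):
            TrialRecord(block_side="right", chosen_side="left", outcome="correct",
                        hold_start_time=0.0, holding_duration=1.5,
                        release_event_time=1.5, release_onset_time=1.45)


def _mk_trials(choices, outcomes=None, block="right"):
    out = []
    for k, c in enumerate(choices):
        outc = outcomes[k] if outcomes else ("correct" if c == block else "error")
        out.append(TrialRecord(block_side=block, chosen_side=c, outcome=outc,
                               hold_start_time=3.0 * k, holding_duration=1.5,
                               release_event_time=3.0 * k + 1.5,
                               release_onset_time=3.0 * k + 1.45))
    return out


class TestPerformance:
    @pytest.mark.parametrize("choices,expected_last", [
        (["right"] * 10, 100.0),
        (["right", "left"] * 5, 50.0),
        (["left"] * 7 + ["right"] * 3, 30.0),
    ])
    def test_choice_rate_series(self, choices, expected_last):
        series = choice_rate_series(_mk_trials(choices))
        assert series[-1] == pytest.approx(expected_last)
        assert np.all((series >= 0) & (series <= 100))

    def test_choice_rate_side_swap_symmetry(self):
        rng = np.random.default_rng(0)
        choices = [("right" if x else "left") for x in rng.integers(0, 2, 30)]
        flipped = [("left" if c == "right" else "right") for c in choices]
        s1 = choice_rate_series(_mk_trials(choices))
        s2 = choice_rate_series(_mk_trials(flipped))
        np.testing.assert_allclose(s1, 100.0 - s2)

    @pytest.mark.parametrize("n_correct,last10_correct,expected", [
        (30, 10, True),
        (29, 10, False),
        (35, 7, False),
    ])
    def test_block_complete(self, n_correct, last10_correct, expected):
        n_err_tail = 10 - last10_correct
        choices = (["right"] * (n_correct - last10_correct)
                   + ["left"] * n_err_tail + ["right"] * last10_correct)
        assert block_complete(_mk_trials(choices)) is expected

    def test_trials_to_criterion_immediate(self):
        trials = _mk_trials(["right"] * 5)
        assert trials_to_criterion(trials, 0) == 1

    def test_trials_to_criterion_never(self):
        trials = _mk_trials(["left"] * 20)
        assert trials_to_criterion(trials, 0) == NOT_REACHED

    def test_trials_to_criterion_matches_trailing_scan_oracle(self):
        rng = np.random.default_rng(3)
        choices = [("right" if x else "left") for x in rng.integers(0, 2, 40)]
        trials = _mk_trials(choices)
        got = trials_to_criterion(trials, 0)
        # brute-force oracle over trailing <=10 windows
        correct = [t.outcome == "correct" for t in trials]
        expect = NOT_REACHED
        for k in range(len(correct)):
            w = correct[max(0, k - 9):k + 1]
            if sum(w) / len(w) >= 0.5:
                expect = k + 1
                break
        assert got == expect

    def test_performance_summary_fields(self, default_session):
        _, session, truth = default_session
        trials = classify_trials(session.pedal, session.blocks)
        perf = performance_summary(trials)
        n_completed = (truth.trials.outcome != "immature").sum()
        assert perf["completed_trials"] == n_completed
        assert 0 <= perf["correct_rate"] <= 100
        assert perf["trials_to_criterion"] != NOT_REACHED
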