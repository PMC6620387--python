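"""Pedal-trace parsing: holding periods, release events and onsets, trial
classification, and task-performance metrics.

The task rules: both pedals must stay inside the holding area (0-30% of the
pedal range) for at least 1 s; the trial ends when either pedal is released
past 30%.  The release onset is the last time the moving pedal first
exceeded its pre-release baseline by 5 percentage points before the release
event.  Attempts shorter than 1 s are immature; completed attempts are
correct when the chosen pedal matches the rewarded block side.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .core import (
    HOLDING_AREA_MAX,
    MIN_HOLD_S,
    BlockSpec,
    PedalTrace,
    TrialRecord,
)

NOT_REACHED = -1  # sentinel for trials_to_criterion


def _both_down_runs(trace: PedalTrace) -> list[tuple[int, int]]:
    """Maximal index runs [i0, i1] (inclusive) with both pedals <= 30%."""
    down = (trace.right_pos <= HOLDING_AREA_MAX) & (trace.left_pos <= HOLDING_AREA_MAX)
    if not down.any():
        return []
    d = np.diff(down.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if down[0]:
        starts.insert(0, 0)
    if down[-1]:
        ends.append(down.size - 1)
    return list(zip(starts, ends))


def find_holding_periods(trace: PedalTrace,
                         min_duration: float = MIN_HOLD_S) -> list[tuple[float, float]]:
    """Maximal intervals with both pedals in the holding area for >= 1 s."""
    out = []
    for i0, i1 in _both_down_runs(trace):
        t0, t1 = trace.times[i0], trace.times[i1]
        if t1 - t0 >= min_duration:
            out.append((float(t0), float(t1)))
    return out


def detect_release_event(trace: PedalTrace,
                         holding_interval: tuple[float, float]
                         ) -> Optional[tuple[str, float]]:
    """First time after the holding interval at which either pedal exceeds 30%.

    Returns (side, event_time), or None when the trace ends inside the
    holding area.  A simultaneous dual-pedal crossing is reported as
    ("bilateral", t); bilateral movements are excluded from unilateral
    analyses downstream.
    """
    i1 = int(np.searchsorted(trace.times, holding_interval[1], side="right")) - 1
    r = trace.right_pos[i1:] > HOLDING_AREA_MAX
    l = trace.left_pos[i1:] > HOLDING_AREA_MAX
    either = np.flatnonzero(r | l)
    if either.size == 0:
        return None
    k = either[0]
    t = float(trace.times[i1 + k])
    if r[k] and l[k]:
        return ("bilateral", t)
    return ("right" if r[k] else "left", t)


def locate_release_onset(
    trace: PedalTrace,
    side: str,
    event_time: float,
    baseline_window: tuple[float, float] = (-0.3, -0.1),
    holding_interval: Optional[tuple[float, float]] = None,
    threshold_pct: float = 5.0,
) -> float:
    """Onset of the release movement: the start of the final contiguous run of
    samples exceeding (pre-release baseline + 5 percentage points).

    The baseline is the mean pedal position over ``baseline_window`` relative
    to the release event (default the 200-ms window ending 100 ms before the
    event, which excludes the release ramp itself); if that window is
    unavailable the mean over the holding interval is used.
    """
    pos = trace.position(side)
    times = trace.times
    i_ev = int(np.searchsorted(times, event_time, side="left"))
    i_ev = min(i_ev, times.size - 1)
    b0 = int(np.searchsorted(times, event_time + baseline_window[0]))
    b1 = int(np.searchsorted(times, event_time + baseline_window[1]))
    if b1 > b0 and b0 >= 0:
        baseline = float(np.mean(pos[b0:b1]))
    elif holding_interval is not None:
        h0 = int(np.searchsorted(times, holding_interval[0]))
        h1 = int(np.searchsorted(times, holding_interval[1], side="right"))
        baseline = float(np.mean(pos[h0:h1])) if h1 > h0 else float(pos[i_ev])
    else:
        baseline = float(pos[max(i_ev - 1, 0)])
    level = baseline + threshold_pct
    j = i_ev
    while j > 0 and pos[j - 1] > level:
        j -= 1
    return float(times[j])


def classify_trials(
    trace: PedalTrace,
    blocks: Sequence[BlockSpec],
    min_attempt_duration: float = 0.2,
) -> list[TrialRecord]:
    """Label every attempt (both-pedals-down run followed by a release).

    The block schedule is an input; each attempt is assigned the block that
    contains its hold start.  Bilateral releases get chosen_side="none" and
    outcome "error"/"immature" depending on holding duration.
    """
    records: list[TrialRecord] = []
    runs = _both_down_runs(trace)
    prev_end = -np.inf
    for i0, i1 in runs:
        t0, t1 = float(trace.times[i0]), float(trace.times[i1])
        if t1 - t0 < min_attempt_duration:
            continue
        if t0 < prev_end:
            raise ValueError("overlapping trials in pedal trace")
        ev = detect_release_event(trace, (t0, t1))
        if ev is None:
            continue
        side, event_time = ev
        prev_end = event_time
        holding = event_time - t0
        block_side = _block_side_at(blocks, t0)
        if side == "bilateral":
            chosen, onset = "none", np.nan
            outcome = "immature" if holding < MIN_HOLD_S else "error"
        else:
            chosen = side
            onset = locate_release_onset(trace, side, event_time,
                                         holding_interval=(t0, t1))
            if holding < MIN_HOLD_S:
                outcome = "immature"
            else:
                outcome = "correct" if chosen == block_side else "error"
        pos_r = trace.right_pos[i0:i1 + 1]
        pos_l = trace.left_pos[i0:i1 + 1]
        within = 0.5 * (np.mean(np.abs(pos_r - pos_r.mean()))
                        + np.mean(np.abs(pos_l - pos_l.mean())))
        records.append(TrialRecord(
            block_side=block_side, chosen_side=chosen, outcome=outcome,
            hold_start_time=t0, holding_duration=holding,
            release_event_time=event_time, release_onset_time=onset,
            within_hold_movement=float(within),
        ))
    return records


def _block_side_at(blocks: Sequence[BlockSpec], t: float) -> str:
    for b in blocks:
        if b.t_start <= t <= b.t_end:
            return b.side
    # outside any block: use the nearest block boundary
    if not blocks:
        raise ValueError("no block schedule provided")
    nearest = min(blocks, key=lambda b: min(abs(t - b.t_start), abs(t - b.t_end)))
    return nearest.side


# ---------------------------------------------------------------------------
# performance metrics


def choice_rate_series(trials: Sequence[TrialRecord], window: int = 10) -> np.ndarray:
    """Trailing-window right-choice percentage per choice trial.

    Immature/bilateral attempts (no choice) are skipped; shorter prefix
    windows use the trials available so far.
    """
    chosen = [t.chosen_side for t in trials if t.chosen_side in ("right", "left")]
    if not chosen:
        return np.empty(0)
    is_right = np.array([c == "right" for c in chosen], dtype=float)
    out = np.empty(is_right.size)
    for k in range(is_right.size):
        w = is_right[max(0, k - window + 1): k + 1]
        out[k] = 100.0 * w.mean()
    return out


def block_complete(trials_in_block: Sequence[TrialRecord],
                   min_correct: int = 30, last_n: int = 10,
                   criterion: float = 0.8) -> bool:
    """Block-completion rule: >= 30 correct trials and >= 80% correct in the
    last 10 trials."""
    outcomes = [t.outcome for t in trials_in_block if t.outcome != "immature"]
    n_correct = sum(o == "correct" for o in outcomes)
    if n_correct < min_correct or len(outcomes) < 1:
        return False
    tail = outcomes[-last_n:]
    return sum(o == "correct" for o in tail) >= criterion * last_n


def trials_to_criterion(trials: Sequence[TrialRecord], block_change_index: int,
                        window: int = 10, criterion: float = 0.5) -> int:
    """Trials after a block change until the trailing-window correct rate
    first reaches the criterion (default 50%); NOT_REACHED if never."""
    outcomes = [t.outcome for t in trials[block_change_index:]
                if t.outcome != "immature"]
    correct = np.array([o == "correct" for o in outcomes], dtype=float)
    for k in range(correct.size):
        w = correct[max(0, k - window + 1): k + 1]
        if w.mean() >= criterion:
            return k + 1
    return NOT_REACHED


def performance_summary(trials: Sequence[TrialRecord], window: int = 10) -> dict:
    """Headline task-performance numbers for one session."""
    completed = [t for t in trials if t.outcome != "immature"]
    choices = [t for t in trials if t.chosen_side in ("right", "left")]
    n_right = sum(t.chosen_side == "right" for t in choices)
    n_left = len(choices) - n_right
    correct_rate = (100.0 * sum(t.outcome == "correct" for t in completed)
                    / len(completed)) if completed else np.nan
    right_bias = (100.0 * (n_right - n_left) / len(choices)) if choices else np.nan
    change_idx = _first_block_change(trials)
    ttc = trials_to_criterion(trials, change_idx) if change_idx is not None else NOT_REACHED
    return dict(
        total_trials=len(trials),
        completed_trials=len(completed),
        correct_rate=correct_rate,
        right_bias=right_bias,
        choice_rate_series=choice_rate_series(trials, window=window),
        trials_to_criterion=ttc,
    )


def _first_block_change(trials: Sequence[TrialRecord]) -> Optional[int]:
    for k in range(1, len(trials)):
        if trials[k].block_side != trials[k - 1].block_side:
            return k
    return None
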