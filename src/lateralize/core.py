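"""Shared data containers for one recording session.

A session of the right-left pedal task bundles pedal-position traces, the
block schedule, isolated single units (spike times plus a mean waveform),
optogenetic stimulation event sets, and optional EMG / LFP traces.  All
containers are plain dataclasses over numpy arrays; heavier derived objects
(PETHs, classification tables) live in the analysis modules.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SIDES = ("right", "left")
AREAS = ("M1", "M2")
CONDITIONS = ("H", "NL", "L")

#: Holding area upper boundary, % of full pedal range (inclusive).
HOLDING_AREA_MAX = 30.0
#: Minimum holding duration for a completed trial, seconds.
MIN_HOLD_S = 1.0


def opposite(side: str) -> str:
    return "left" if side == "right" else "right"


@dataclass
class PedalTrace:
    """Right and left pedal positions in % of full range on a uniform grid."""

    times: np.ndarray
    right_pos: np.ndarray
    left_pos: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.right_pos = np.asarray(self.right_pos, dtype=float)
        self.left_pos = np.asarray(self.left_pos, dtype=float)
        if self.times.size == 0:
            raise ValueError("empty pedal trace")
        if not (self.times.size == self.right_pos.size == self.left_pos.size):
            raise ValueError("pedal trace arrays must share length")
        dt = np.diff(self.times)
        if self.times.size > 1 and (dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time grid must be strictly increasing and uniform")
        for arr in (self.right_pos, self.left_pos):
            if arr.min() < 0.0 or arr.max() > 100.0:
                raise ValueError("pedal positions must lie in [0, 100] %")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])

    def position(self, side: str) -> np.ndarray:
        if side not in SIDES:
            raise ValueError(f"unknown side {side!r}")
        return self.right_pos if side == "right" else self.left_pos


@dataclass
class TrialRecord:
    """One attempt at the task and its outcome.

    ``holding_duration`` runs from both-pedals-down to the release event
    (time spent inside the holding area); ``within_hold_movement`` is the
    mean absolute pedal excursion (both pedals) during holding, in %.
    """

    block_side: str
    chosen_side: str  # "right" | "left" | "none"
    outcome: str  # "correct" | "error" | "immature"
    hold_start_time: float
    holding_duration: float
    release_event_time: float
    release_onset_time: float
    within_hold_movement: float = np.nan

    def __post_init__(self) -> None:
        if self.outcome == "correct" and (
            self.chosen_side != self.block_side or self.holding_duration < MIN_HOLD_S
        ):
            raise ValueError("correct trial requires block-side choice and >=1 s hold")
        if np.isfinite(self.release_onset_time) and np.isfinite(self.release_event_time):
            if self.release_onset_time > self.release_event_time + 1e-9:
                raise ValueError("release onset must not follow the release event")


@dataclass
class BlockSpec:
    """One reward block: which pedal is rewarded between t_start and t_end."""

    side: str
    t_start: float
    t_end: float


@dataclass
class UnitRecord:
    """One isolated unit: spike times, mean waveform and session labels."""

    unit_id: str
    area: str
    condition: str
    hemisphere: str  # recording hemisphere, "right" | "left"
    spike_times: np.ndarray
    waveform: Optional[np.ndarray] = None
    waveform_sampling_rate: float = 20_000.0

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError(f"unit {self.unit_id}: spike times must be strictly increasing")

    def contra_side(self) -> str:
        """Movement side contralateral to the recording hemisphere."""
        return opposite(self.hemisphere)


@dataclass
class EmgTrace:
    """Rectifiable EMG of one forelimb on a uniform grid starting at t0."""

    values: np.ndarray
    sampling_rate: float
    side: str
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sampling_rate


@dataclass
class LfpTrace:
    """LFP of one area (uniform grid starting at t0), sampled at 1000 Hz."""

    values: np.ndarray
    sampling_rate: float
    area: str
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sampling_rate


@dataclass
class StimEventSet:
    """Optogenetic stimulation events of one mode for one unit.

    ``snippets`` holds one voltage trace per event, sampled at
    ``snippet_sampling_rate`` with sample times ``snippet_times`` relative to
    stimulus onset.  ``pulse_offsets`` lists intra-snippet pulse times (ms):
    a single 0.0 for ordinary events, [0, isi] for frequency-following pairs.
    """

    unit_id: str
    site: str  # "contralateral_cortex" | "ipsilateral_pons"
    mode: str  # "control" | "test" | "ff100" | "ff200"
    stim_times: np.ndarray
    snippets: np.ndarray  # (n_events, n_samples)
    snippet_times: np.ndarray  # ms relative to stimulus onset
    snippet_sampling_rate: float
    trigger_spike_times: Optional[np.ndarray] = None
    pulse_offsets: tuple = (0.0,)

    def __post_init__(self) -> None:
        self.snippets = np.atleast_2d(np.asarray(self.snippets, dtype=float))
        self.snippet_times = np.asarray(self.snippet_times, dtype=float)
        if self.snippets.shape[1] != self.snippet_times.size:
            raise ValueError("snippets and snippet_times must share sample count")


@dataclass
class SessionData:
    """Everything recorded in one session."""

    pedal: PedalTrace
    blocks: list[BlockSpec]
    units: list[UnitRecord] = field(default_factory=list)
    stim: dict[str, list[StimEventSet]] = field(default_factory=dict)
    emg: dict[str, EmgTrace] = field(default_factory=dict)
    lfp: dict[str, LfpTrace] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.pedal.times[0]), float(self.pedal.times[-1])

    def unit(self, unit_id: str) -> UnitRecord:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)
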