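"""Synthetic right-left pedal-task sessions with per-unit ground truth.

The generator emulates the study conditions end to end: a head-fixed rat
holds both pedals inside the 0-30% holding area for at least 1 s, releases
one pedal (two reward blocks, right- and left-rewarded), and motor-cortex
units fire with Go-type (phasic, movement-locked Gaussian bump) or
Hold-type (sustained step spanning the holding period) modulation that may
differ between contralateral and ipsilateral movements.  Optogenetic
stimulation events with collision physics, biceps EMG bursts and
condition-dependent beta-band LFP can be attached.  Every random component
draws from its own stream split off the session seed, so toggling one
component does not perturb the others, and a fixed seed reproduces the
session exactly.

Spike trains are inhomogeneous Poisson (thinning) with an absolute
refractory period; ground-truth laterality is computed analytically from
the configured rate profile passed through the same peak +/-150 ms and
baseline-window definitions the analysis applies, so that estimator
recovery is unbiased up to Poisson noise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .core import (
    BlockSpec,
    EmgTrace,
    LfpTrace,
    PedalTrace,
    SessionData,
    StimEventSet,
    UnitRecord,
    opposite,
)

# Analysis windows shared with the estimation side (seconds, re release onset).
PEAK_HALF_WINDOW_S = 0.150
BASELINE_WINDOW_S = (-1.0, -0.7)


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


# ---------------------------------------------------------------------------
# configuration dataclasses


@dataclass
class UnitSpec:
    """Ground-truth description of one simulated unit.

    ``peak_rate_contra``/``peak_rate_ipsi`` are the added modulation
    amplitudes in Hz: the height of the Gaussian bump at its center for
    Go-type units, or the height of the sustained step for Hold-type units,
    above ``baseline_rate``.
    """

    functional_type: str = "Go"  # "Go" | "Hold" | "untuned"
    baseline_rate: float = 5.0
    peak_rate_contra: float = 20.0
    peak_rate_ipsi: float = 5.0
    go_peak_lag: float = -0.05  # s re release onset
    go_width: float = 0.05  # Gaussian SD, s
    waveform_class: str = "RS"  # "RS" | "FS"
    projection: str = "none"  # "IT" | "PT" | "none"
    antidromic_latency: float = 8.0  # ms
    antidromic_reliability: float = 0.9
    antidromic_jitter: float = 0.05  # ms, SD of latency jitter
    orthodromic_response: bool = False
    orthodromic_jitter: float = 1.0  # ms, SD for non-axonal responses
    ff_follow_reliability: Optional[float] = None  # second-pulse follow prob.
    refractory: float = 2.0  # ms

    def validate(self) -> None:
        for name in ("baseline_rate", "peak_rate_contra", "peak_rate_ipsi"):
            if getattr(self, name) < 0:
                raise ConfigError(f"UnitSpec.{name} must be >= 0")
        if not 0.0 <= self.antidromic_reliability <= 1.0:
            raise ConfigError("UnitSpec.antidromic_reliability must lie in [0, 1]")
        if self.refractory <= 0:
            raise ConfigError("UnitSpec.refractory must be > 0")
        if self.functional_type not in ("Go", "Hold", "untuned"):
            raise ConfigError("UnitSpec.functional_type must be Go, Hold or untuned")
        if self.waveform_class not in ("RS", "FS"):
            raise ConfigError("UnitSpec.waveform_class must be RS or FS")
        if self.projection not in ("IT", "PT", "none"):
            raise ConfigError("UnitSpec.projection must be IT, PT or none")

    @property
    def follow_reliability(self) -> float:
        if self.ff_follow_reliability is not None:
            return self.ff_follow_reliability
        # Axonal (antidromic) responses follow paired pulses faithfully;
        # synaptic (orthodromic) responses mostly fail at 100-200 Hz.
        return 1.0 if self.projection != "none" else 0.2


@dataclass
class StimSpec:
    """Optogenetic stimulation protocol for the collision test."""

    n_control_events: int = 50
    n_test_events: int = 50
    n_ff_pairs: int = 10
    snippet_duration: float = 30.0  # ms (covers latency + paired-pulse ISI)
    snippet_sampling_rate: float = 20_000.0  # Hz
    trigger_delay: float = 1.0  # ms after a spontaneous spike (test mode)
    noise_sd: float = 0.08  # volts-equivalent, vs unit template amplitude 1.0
    spike_amplitude: float = 1.0

    def validate(self, unit_specs: Sequence[UnitSpec]) -> None:
        for f in ("n_control_events", "n_test_events"):
            if getattr(self, f) < 1:
                raise ConfigError(f"StimSpec.{f} must be >= 1")
        for spec in unit_specs:
            if spec.projection != "none" and self.snippet_duration <= spec.antidromic_latency:
                raise ConfigError(
                    "StimSpec.snippet_duration must exceed the antidromic latency "
                    f"of every stimulated unit ({spec.antidromic_latency} ms)"
                )


@dataclass
class EmgParams:
    sampling_rate: float = 10_000.0
    lead: float = 0.250  # s, burst onset before release onset
    burst_amplitude: float = 10.0  # multiples of baseline noise SD
    burst_duration: float = 0.5  # s
    noise_sd: float = 1.0


@dataclass
class LfpParams:
    sampling_rate: float = 1000.0
    beta_freq: float = 20.0  # Hz
    background_sd: float = 1.0  # pink-noise SD (0 -> pure sinusoid)
    shared_weight: float = 0.4  # inter-areal shared-component weight in [0, 1]


@dataclass
class SimConfig:
    """Full description of one synthetic session."""

    seed: int = 0
    n_trials_per_block: int = 30  # completed (non-immature) trials per block
    n_blocks: int = 4  # alternating right/left-rewarded blocks
    holding_time_range: tuple = (1.0, 3.0)  # s, uniform support
    pedal_sampling_rate: float = 1000.0
    unit_specs: Optional[list[UnitSpec]] = None
    emg_enabled: bool = True
    lfp_enabled: bool = True
    lfp_beta_amplitude: dict = field(
        default_factory=lambda: {"H": 0.5, "NL": 0.5, "L": 0.7}
    )
    stim_spec: Optional[StimSpec] = None
    area: str = "M1"
    condition: str = "H"
    hemisphere: str = "left"
    first_block: str = "right"
    p_correct: float = 0.8
    p_immature: float = 0.1
    within_hold_wiggle: float = 0.5  # %, amplitude of slow hold-period movement
    simulate_bilateral: bool = False  # bilateral releases are off by default
    emg_params: EmgParams = field(default_factory=EmgParams)
    lfp_params: LfpParams = field(default_factory=LfpParams)

    def validate(self) -> None:
        lo, hi = self.holding_time_range
        if lo < 1.0:
            raise ConfigError("SimConfig.holding_time_range lower bound must be >= 1.0 s")
        if hi <= lo:
            raise ConfigError("SimConfig.holding_time_range must be increasing")
        if self.n_trials_per_block < 1:
            raise ConfigError("SimConfig.n_trials_per_block must be >= 1")
        if self.pedal_sampling_rate <= 0:
            raise ConfigError("SimConfig.pedal_sampling_rate must be > 0")
        if self.condition not in ("H", "NL", "L"):
            raise ConfigError("SimConfig.condition must be H, NL or L")
        if self.condition not in self.lfp_beta_amplitude:
            raise ConfigError("SimConfig.lfp_beta_amplitude must map the condition")
        for i, spec in enumerate(self.unit_specs or []):
            try:
                spec.validate()
            except ConfigError as e:
                raise ConfigError(f"unit_specs[{i}]: {e}") from None
        if self.stim_spec is not None:
            specs = (self.unit_specs if self.unit_specs is not None
                     else default_unit_specs())
            if not specs:
                raise ConfigError("stim_spec requires at least one unit (unit_specs)")
            self.stim_spec.validate(specs)


def default_unit_specs() -> list[UnitSpec]:
    """A small mixed population: Go/Hold/untuned, RS/FS, one IT and one PT."""
    specs = [
        UnitSpec(functional_type="Go", peak_rate_contra=20.0, peak_rate_ipsi=5.0),
        UnitSpec(functional_type="Go", peak_rate_contra=25.0, peak_rate_ipsi=2.0),
        UnitSpec(functional_type="Go", peak_rate_contra=5.0, peak_rate_ipsi=18.0),
        UnitSpec(functional_type="Go", peak_rate_contra=15.0, peak_rate_ipsi=15.0),
        UnitSpec(functional_type="Go", peak_rate_contra=22.0, peak_rate_ipsi=4.0,
                 waveform_class="FS", baseline_rate=8.0),
        UnitSpec(functional_type="Hold", peak_rate_contra=15.0, peak_rate_ipsi=15.0),
        UnitSpec(functional_type="Hold", peak_rate_contra=18.0, peak_rate_ipsi=12.0,
                 waveform_class="FS", baseline_rate=8.0),
        UnitSpec(functional_type="untuned", peak_rate_contra=0.0, peak_rate_ipsi=0.0),
        UnitSpec(functional_type="untuned", peak_rate_contra=0.0, peak_rate_ipsi=0.0,
                 waveform_class="FS", baseline_rate=8.0),
        UnitSpec(functional_type="Go", peak_rate_contra=20.0, peak_rate_ipsi=6.0,
                 projection="IT", antidromic_latency=11.7),
        UnitSpec(functional_type="Go", peak_rate_contra=24.0, peak_rate_ipsi=5.0,
                 projection="PT", antidromic_latency=6.9),
    ]
    return specs


# ---------------------------------------------------------------------------
# behavior


@dataclass
class SimTrial:
    """Ground-truth timing of one simulated attempt."""

    side: str  # side released
    block_side: str
    outcome: str  # "correct" | "error" | "immature"
    hold_start: float  # both pedals inside the holding area
    holding_duration: float  # s, hold_start -> release event
    ramp_start: float  # release ramp begins
    release_onset: float  # +5% exceedance time (analytic)
    release_event: float  # 30% crossing time (analytic)
    emg_onset: float = np.nan


_REST = 75.0
_HOLD = 10.0
_PUSH_RAMP = 0.10  # s, rest -> hold
_RELEASE_RAMP = 0.15  # s, hold -> rest
_OTHER_PEDAL_DELAY = 0.35  # s after release ramp before the held pedal rises


def make_trial_scaffold(
    n_per_side: int,
    rng: np.random.Generator,
    holding_time_range: tuple = (1.0, 3.0),
    iti: float = 1.5,
) -> list[SimTrial]:
    """Alternating right/left completed trials for unit-level simulations."""
    trials = []
    t = 1.0
    sides = (["right", "left"] * n_per_side)[: 2 * n_per_side]
    rng.shuffle(sides)
    for side in sides:
        hold = rng.uniform(*holding_time_range)
        tr = _build_trial(t, side, side, hold, immature=False)
        trials.append(tr)
        t = tr.release_event + _RELEASE_RAMP + iti
    return trials


def _build_trial(t_push: float, side: str, block_side: str, holding: float,
                 immature: bool) -> SimTrial:
    """Lay out one attempt analytically from the push-down start time."""
    slope_down = (_REST - _HOLD) / _PUSH_RAMP
    hold_start = t_push + (_REST - 30.0) / slope_down  # both cross 30% downward
    plateau_start = t_push + _PUSH_RAMP
    slope_up = (_REST - _HOLD) / _RELEASE_RAMP
    # choose the plateau length so that hold_start -> 30% crossing equals `holding`
    ramp_start = hold_start + holding - (30.0 - _HOLD) / slope_up
    if ramp_start < plateau_start:  # very short immature holds
        ramp_start = plateau_start
        holding = (plateau_start - hold_start) + (30.0 - _HOLD) / slope_up
    release_event = ramp_start + (30.0 - _HOLD) / slope_up
    release_onset = ramp_start + 5.0 / slope_up  # exceed baseline + 5% (analytic)
    outcome = "immature" if immature else ("correct" if side == block_side else "error")
    return SimTrial(
        side=side,
        block_side=block_side,
        outcome=outcome,
        hold_start=hold_start,
        holding_duration=holding,
        ramp_start=ramp_start,
        release_onset=release_onset,
        release_event=release_event,
    )


def simulate_behavior(config: SimConfig, rng: np.random.Generator
                      ) -> tuple[list[SimTrial], PedalTrace, list[BlockSpec]]:
    """Generate the attempt sequence and render the pedal-position traces."""
    trials: list[SimTrial] = []
    t = 1.0
    blocks: list[BlockSpec] = []
    order = [config.first_block if k % 2 == 0 else opposite(config.first_block)
             for k in range(max(config.n_blocks, 2))]
    for block_side in order:
        block_t0 = t - 0.5
        n_done = 0
        while n_done < config.n_trials_per_block:
            immature = rng.random() < config.p_immature
            if immature:
                holding = rng.uniform(0.3, 0.9)
                side = block_side if rng.random() < 0.5 else opposite(block_side)
            else:
                holding = rng.uniform(*config.holding_time_range)
                side = block_side if rng.random() < config.p_correct else opposite(block_side)
                n_done += 1
            tr = _build_trial(t, side, block_side, holding, immature)
            trials.append(tr)
            t = tr.release_event + _RELEASE_RAMP + rng.uniform(1.2, 1.8)
        blocks.append(BlockSpec(side=block_side, t_start=block_t0, t_end=t - 0.5))

    fs = config.pedal_sampling_rate
    n = int(math.ceil((t + 1.0) * fs)) + 1
    times = np.arange(n) / fs
    pos = {s: np.full(n, _REST) for s in ("right", "left")}

    def idx(x: float) -> int:
        return int(round(x * fs))

    for tr in trials:
        t_push = tr.hold_start - (_REST - 30.0) / ((_REST - _HOLD) / _PUSH_RAMP)
        plateau_start = t_push + _PUSH_RAMP
        wig_f = rng.uniform(0.5, 1.2)
        wig_ph = rng.uniform(0, 2 * np.pi, size=2)
        for k, s in enumerate(("right", "left")):
            # push-down ramp
            i0, i1 = idx(t_push), idx(plateau_start)
            seg = times[i0:i1]
            pos[s][i0:i1] = _REST - (_REST - _HOLD) * (seg - t_push) / _PUSH_RAMP
            # hold plateau with small within-hold movement
            if s == tr.side:
                ramp_start = tr.ramp_start
            else:
                ramp_start = tr.ramp_start + _OTHER_PEDAL_DELAY
            i1b = idx(ramp_start)
            seg = times[i1:i1b]
            wig = config.within_hold_wiggle * np.sin(
                2 * np.pi * wig_f * (seg - plateau_start) + wig_ph[k]
            )
            pos[s][i1:i1b] = _HOLD + wig
            # release ramp, starting from the wiggled value
            start_val = pos[s][i1b - 1] if i1b > i1 else _HOLD
            i2 = idx(ramp_start + _RELEASE_RAMP)
            seg = times[i1b:i2]
            slope = (_REST - _HOLD) / _RELEASE_RAMP
            pos[s][i1b:i2] = np.minimum(start_val + slope * (seg - ramp_start), _REST)

    trace = PedalTrace(times=times, right_pos=np.clip(pos["right"], 0, 100),
                       left_pos=np.clip(pos["left"], 0, 100))

    # refine ground-truth release onsets for the wiggled trace: the analytic
    # onset uses the actual pre-release baseline and ramp start value
    for tr in trials:
        p = trace.position(tr.side)
        b0, b1 = idx(tr.release_event - 0.3), idx(tr.release_event - 0.1)
        baseline = float(np.mean(p[b0:b1])) if b1 > b0 else _HOLD
        start_val = p[idx(tr.ramp_start) - 1]
        slope = (_REST - _HOLD) / _RELEASE_RAMP
        tr.release_onset = tr.ramp_start + (baseline + 5.0 - start_val) / slope
        tr.release_event = tr.ramp_start + (30.0 - start_val) / slope
    return trials, trace, blocks


# ---------------------------------------------------------------------------
# spikes


def _modulation_amplitudes(spec: UnitSpec, trial_sides: np.ndarray,
                           hemisphere: str) -> np.ndarray:
    contra = opposite(hemisphere)
    return np.where(trial_sides == contra, spec.peak_rate_contra, spec.peak_rate_ipsi)


def _rate_at(t: np.ndarray, spec: UnitSpec, trials: Sequence[SimTrial],
             hemisphere: str) -> np.ndarray:
    rate = np.full(t.shape, float(spec.baseline_rate))
    if spec.functional_type == "untuned" or not trials:
        return rate
    sides = np.array([tr.side for tr in trials])
    amp = _modulation_amplitudes(spec, sides, hemisphere)
    if spec.functional_type == "Hold":
        hs = np.array([tr.hold_start for tr in trials])
        ro = np.array([tr.release_onset for tr in trials])
        i = np.searchsorted(hs, t, side="right") - 1
        ok = i >= 0
        j = np.clip(i, 0, None)
        in_hold = ok & (t <= ro[j])
        rate += np.where(in_hold, amp[j], 0.0)
    else:  # Go: Gaussian bump at release_onset + lag on the trial's side
        centers = np.array([tr.release_onset + spec.go_peak_lag for tr in trials])
        sig = spec.go_width
        for shift in (0, 1):
            i = np.searchsorted(centers, t) - 1 + shift
            ok = (i >= 0) & (i < len(trials))
            j = np.clip(i, 0, len(trials) - 1)
            d = t - centers[j]
            near = ok & (np.abs(d) < 6 * sig)
            rate += np.where(near, amp[j] * np.exp(-0.5 * (d / sig) ** 2), 0.0)
    return rate


def _enforce_refractory(spikes: np.ndarray, refractory_s: float) -> np.ndarray:
    if spikes.size == 0:
        return spikes
    kept = [spikes[0]]
    last = spikes[0]
    for s in spikes[1:]:
        if s - last >= refractory_s:
            kept.append(s)
            last = s
    return np.array(kept)


def simulate_unit_spikes(
    spec: UnitSpec,
    trials: Sequence[SimTrial],
    rng: np.random.Generator,
    span: Optional[tuple[float, float]] = None,
    hemisphere: str = "left",
) -> np.ndarray:
    """Inhomogeneous-Poisson spike train for one unit (thinning algorithm)."""
    spec.validate()
    if span is None:
        if not trials:
            raise ConfigError("simulate_unit_spikes: provide trials or a span")
        span = (trials[0].hold_start - 2.0, trials[-1].release_event + 2.0)
    t0, t1 = span
    max_extra = 0.0
    if spec.functional_type != "untuned":
        max_extra = max(spec.peak_rate_contra, spec.peak_rate_ipsi)
    max_rate = spec.baseline_rate + max_extra
    if max_rate <= 0:
        return np.empty(0)
    n = rng.poisson(max_rate * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n))
    accept = rng.uniform(0, max_rate, size=n) < _rate_at(cand, spec, trials, hemisphere)
    spikes = cand[accept]
    spikes = _enforce_refractory(spikes, spec.refractory / 1000.0)
    return spikes


# mean of a unit Gaussian bump over the +/-150 ms peak window, as a fraction
# of its center amplitude: sqrt(2*pi)*sigma*erf(w/(sigma*sqrt(2)))/(2*w)
def _bump_window_fraction(sigma: float, w: float = PEAK_HALF_WINDOW_S) -> float:
    return math.sqrt(2 * math.pi) * sigma * erf(w / (sigma * math.sqrt(2))) / (2 * w)


def true_laterality(spec: UnitSpec) -> tuple[float, float, float]:
    """Analytic (c, i, index) for a Go-type spec under the analysis windows."""
    if spec.baseline_rate <= 0:
        return np.nan, np.nan, np.nan
    if spec.functional_type == "Hold":
        frac = 1.0  # step is flat across the peak window
    else:
        frac = _bump_window_fraction(spec.go_width)
    c = frac * spec.peak_rate_contra / spec.baseline_rate
    i = frac * spec.peak_rate_ipsi / spec.baseline_rate
    if c > 0 and i > 0:
        idx = (c - i) / (c + i)
    elif c > 0 and i <= 0:
        idx = 1.0
    elif c <= 0 and i > 0:
        idx = -1.0
    else:
        idx = np.nan
    return c, i, idx


def _true_side_category(spec: UnitSpec) -> str:
    if spec.functional_type == "untuned":
        return "none"
    has_c = spec.peak_rate_contra > 0
    has_i = spec.peak_rate_ipsi > 0
    if has_c and has_i:
        return "bilateral"
    if has_c:
        return "contralateral"
    if has_i:
        return "ipsilateral"
    return "none"


# ---------------------------------------------------------------------------
# waveforms

_WAVEFORM_SHAPES = {
    # trough time, trough SD, peak delay, peak SD, peak amplitude (ms / a.u.)
    "RS": dict(t_tr=0.40, s_tr=0.10, d_pk=0.80, s_pk=0.30, a_pk=0.45),
    "FS": dict(t_tr=0.40, s_tr=0.07, d_pk=0.20, s_pk=0.10, a_pk=0.45),
}


def make_waveform(cls: str, sampling_rate: float = 20_000.0,
                  duration_ms: float = 2.4) -> np.ndarray:
    """Biphasic mean-waveform template (negative trough, positive peak)."""
    p = _WAVEFORM_SHAPES[cls]
    t = np.arange(int(duration_ms * sampling_rate / 1000.0)) / sampling_rate * 1000.0
    w = -np.exp(-0.5 * ((t - p["t_tr"]) / p["s_tr"]) ** 2)
    w += p["a_pk"] * np.exp(-0.5 * ((t - p["t_tr"] - p["d_pk"]) / p["s_pk"]) ** 2)
    return w


# ---------------------------------------------------------------------------
# optogenetic stimulation snippets


def _spike_template(times_ms: np.ndarray, t_spike: float, amplitude: float) -> np.ndarray:
    """Negative-going extracellular spike injected into a snippet."""
    d = times_ms - t_spike
    w = -amplitude * np.exp(-0.5 * (d / 0.15) ** 2)
    w += 0.3 * amplitude * np.exp(-0.5 * ((d - 0.45) / 0.3) ** 2)
    return w


def stim_site_for(spec: UnitSpec) -> str:
    return "ipsilateral_pons" if spec.projection == "PT" else "contralateral_cortex"


def simulate_stimulation(
    stim: StimSpec,
    spec: UnitSpec,
    spikes: np.ndarray,
    rng: np.random.Generator,
    unit_id: str = "u0",
    span: Optional[tuple[float, float]] = None,
) -> list[StimEventSet]:
    """Stimulation event sets (control, collision-test, frequency-following).

    Control events are placed where no spontaneous spike occurred in the
    preceding (latency + refractory) window; the antidromic spike appears at
    its fixed latency with probability ``antidromic_reliability``.  Test
    events are triggered ``trigger_delay`` ms after a spontaneous spike; the
    antidromic spike is annihilated by collision whenever
    trigger_delay < latency + refractory.  Non-projection units may emit a
    jittered orthodromic response in both modes (no collision).
    """
    if span is None:
        if spikes.size:
            span = (float(spikes[0]), float(spikes[-1]))
        else:
            span = (0.0, 100.0)
    lat, refr = spec.antidromic_latency, spec.refractory
    dead = (lat + refr) / 1000.0
    in_span = spikes[(spikes >= span[0]) & (spikes <= span[1])] if spikes.size \
        else spikes
    n_samp = int(stim.snippet_duration * stim.snippet_sampling_rate / 1000.0)
    times_ms = np.arange(n_samp) / stim.snippet_sampling_rate * 1000.0
    site = stim_site_for(spec)
    is_proj = spec.projection != "none"
    responds = is_proj or spec.orthodromic_response

    def snippet(pulses_ms: Sequence[float], collided: Sequence[bool]) -> np.ndarray:
        snip = rng.normal(0.0, stim.noise_sd, size=n_samp)
        for p_ms, coll in zip(pulses_ms, collided):
            if not responds or coll:
                continue
            if rng.random() >= spec.antidromic_reliability:
                continue
            jit = spec.antidromic_jitter if is_proj else spec.orthodromic_jitter
            t_spike = p_ms + lat + rng.normal(0.0, jit)
            snip += _spike_template(times_ms, t_spike, stim.spike_amplitude)
        return snip

    out: list[StimEventSet] = []

    # control events: no spontaneous spike in the preceding dead window
    ctrl_times = []
    guard = 0
    while len(ctrl_times) < stim.n_control_events and guard < 100_000:
        guard += 1
        t = rng.uniform(span[0] + 1.0, span[1] - 1.0)
        k = np.searchsorted(spikes, t)
        if k > 0 and t - spikes[k - 1] < dead:
            continue
        ctrl_times.append(t)
    ctrl_times = np.sort(np.array(ctrl_times))
    ctrl_snips = np.array([snippet([0.0], [False]) for _ in ctrl_times])
    out.append(StimEventSet(unit_id, site, "control", ctrl_times, ctrl_snips,
                            times_ms, stim.snippet_sampling_rate))

    # test events: triggered by spontaneous spikes within the epoch
    if in_span.size == 0:
        trig = np.empty(0)
    elif in_span.size <= stim.n_test_events:
        trig = in_span.copy()
    else:
        trig = np.sort(rng.choice(in_span, size=stim.n_test_events, replace=False))
    collided = is_proj and (stim.trigger_delay < lat + refr)
    test_times = trig + stim.trigger_delay / 1000.0
    test_snips = np.array([snippet([0.0], [collided]) for _ in test_times]) \
        if test_times.size else np.empty((0, n_samp))
    out.append(StimEventSet(unit_id, site, "test", test_times, test_snips,
                            times_ms, stim.snippet_sampling_rate,
                            trigger_spike_times=trig))

    # frequency-following pairs at 100 and 200 Hz
    for mode, isi in (("ff100", 10.0), ("ff200", 5.0)):
        if stim.n_ff_pairs < 1:
            continue
        ts, snips = [], []
        follow = spec.follow_reliability
        for _ in range(stim.n_ff_pairs):
            t = rng.uniform(span[0] + 1.0, span[1] - 1.0)
            snip = rng.normal(0.0, stim.noise_sd, size=n_samp)
            for k, p_ms in enumerate((0.0, isi)):
                if not responds:
                    continue
                prob = spec.antidromic_reliability * (follow if k == 1 else 1.0)
                if rng.random() >= prob:
                    continue
                jit = spec.antidromic_jitter if is_proj else spec.orthodromic_jitter
                snip += _spike_template(times_ms, p_ms + lat + rng.normal(0.0, jit),
                                        stim.spike_amplitude)
            ts.append(t)
            snips.append(snip)
        out.append(StimEventSet(unit_id, site, mode, np.array(ts), np.array(snips),
                                times_ms, stim.snippet_sampling_rate,
                                pulse_offsets=(0.0, isi)))
    return out


# ---------------------------------------------------------------------------
# EMG and LFP


def simulate_emg(trials: Sequence[SimTrial], rng: np.random.Generator,
                 span: tuple[float, float], params: Optional[EmgParams] = None
                 ) -> dict[str, EmgTrace]:
    """Baseline noise plus a movement burst on the moving side's forelimb.

    The burst is modeled as an amplitude-modulated noise envelope switching
    on ``lead`` seconds before each release onset (the recorded ground-truth
    EMG onset), holding for ~60% of the burst and decaying linearly.
    """
    p = params or EmgParams()
    fs = p.sampling_rate
    n = int(math.ceil((span[1] - span[0]) * fs)) + 1
    out = {}
    for side in ("right", "left"):
        scale = np.ones(n)
        for tr in trials:
            if tr.side != side:
                continue
            onset = tr.release_onset - p.lead
            tr.emg_onset = onset
            i0 = int(round((onset - span[0]) * fs))
            i_hold = int(round((onset + 0.6 * p.burst_duration - span[0]) * fs))
            i1 = int(round((onset + p.burst_duration - span[0]) * fs))
            i0, i_hold, i1 = (max(0, min(n, i)) for i in (i0, i_hold, i1))
            scale[i0:i_hold] = p.burst_amplitude
            if i1 > i_hold:
                scale[i_hold:i1] = np.linspace(p.burst_amplitude, 1.0, i1 - i_hold)
        values = rng.normal(0.0, p.noise_sd, size=n) * scale
        out[side] = EmgTrace(values=values, sampling_rate=fs, side=side, t0=span[0])
    return out


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, unit variance."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    spec = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    with np.errstate(divide="ignore"):
        spec /= np.sqrt(np.maximum(freqs, freqs[1] if n > 1 else 1.0))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_lfp(duration: float, condition: str, rng: np.random.Generator,
                 beta_amplitude: dict, params: Optional[LfpParams] = None,
                 t0: float = 0.0) -> dict[str, LfpTrace]:
    """Two-area LFP: pink background + condition-dependent 20 Hz component.

    A shared pink-noise component (weight ``shared_weight``) controls the
    inter-areal coherence; the beta sinusoid has a common phase in both
    areas.  Sampling rate 1000 Hz.
    """
    p = params or LfpParams()
    n = int(math.ceil(duration * p.sampling_rate)) + 1
    t = np.arange(n) / p.sampling_rate
    amp = beta_amplitude[condition]
    beta = amp * np.sin(2 * np.pi * p.beta_freq * t)
    shared = _pink_noise(n, rng)
    out = {}
    w = p.shared_weight
    for area in ("M1", "M2"):
        indep = _pink_noise(n, rng)
        bg = p.background_sd * (w * shared + (1.0 - w) * indep)
        out[area] = LfpTrace(values=bg + beta, sampling_rate=p.sampling_rate,
                             area=area, t0=t0)
    return out


# ---------------------------------------------------------------------------
# whole sessions


@dataclass
class GroundTruth:
    """Per-unit and per-trial generator truth for a synthetic session."""

    units: pd.DataFrame  # indexed by unit_id
    trials: pd.DataFrame  # one row per attempt, in order


def _ground_truth_units(specs: Sequence[UnitSpec], unit_ids: Sequence[str]
                        ) -> pd.DataFrame:
    rows = []
    for uid, spec in zip(unit_ids, specs):
        c, i, idx = true_laterality(spec)
        rows.append(dict(
            unit_id=uid,
            functional_type=spec.functional_type,
            waveform_class=spec.waveform_class,
            projection=spec.projection,
            baseline_rate=spec.baseline_rate,
            peak_rate_contra=spec.peak_rate_contra,
            peak_rate_ipsi=spec.peak_rate_ipsi,
            c_true=c,
            i_true=i,
            laterality_index_true=idx,
            side_category_true=_true_side_category(spec),
            antidromic_latency=spec.antidromic_latency,
            antidromic_reliability=spec.antidromic_reliability,
        ))
    if not rows:
        return pd.DataFrame(columns=["unit_id"]).set_index("unit_id")
    return pd.DataFrame(rows).set_index("unit_id")


def _ground_truth_trials(trials: Sequence[SimTrial]) -> pd.DataFrame:
    return pd.DataFrame([dict(
        block_side=tr.block_side, chosen_side=tr.side, outcome=tr.outcome,
        hold_start=tr.hold_start, holding_duration=tr.holding_duration,
        release_onset=tr.release_onset, release_event=tr.release_event,
        emg_onset=tr.emg_onset,
    ) for tr in trials])


def simulate_session(config: SimConfig) -> tuple[SessionData, GroundTruth]:
    """Generate one complete synthetic session with matching ground truth."""
    config.validate()
    specs = config.unit_specs if config.unit_specs is not None else default_unit_specs()
    ss = np.random.SeedSequence(config.seed)
    s_beh, s_spk, s_stim, s_emg, s_lfp = ss.spawn(5)
    rng_beh = np.random.default_rng(s_beh)

    trials, trace, blocks = simulate_behavior(config, rng_beh)
    span = (float(trace.times[0]), float(trace.times[-1]))

    # stimulation happens in a dedicated post-task epoch so the 1-s
    # post-stimulus spike blanking does not eat into trial activity
    stim_epoch = None
    spike_span = span
    if config.stim_spec is not None:
        st = config.stim_spec
        n_ev = st.n_control_events + st.n_test_events + 2 * st.n_ff_pairs
        stim_epoch = (span[1] + 5.0, span[1] + 5.0 + 2.0 * n_ev + 10.0)
        spike_span = (span[0], stim_epoch[1] + 2.0)

    unit_ids = [f"u{k:03d}" for k in range(len(specs))]
    units = []
    stim_sets: dict[str, list[StimEventSet]] = {}
    spk_streams = s_spk.spawn(max(len(specs), 1))
    stim_streams = s_stim.spawn(max(len(specs), 1))
    for uid, spec, st_spk, st_stim in zip(unit_ids, specs, spk_streams, stim_streams):
        spikes = simulate_unit_spikes(spec, trials, np.random.default_rng(st_spk),
                                      span=spike_span,
                                      hemisphere=config.hemisphere)
        units.append(UnitRecord(
            unit_id=uid, area=config.area, condition=config.condition,
            hemisphere=config.hemisphere, spike_times=spikes,
            waveform=make_waveform(spec.waveform_class),
        ))
        if config.stim_spec is not None and (spec.projection != "none"
                                             or spec.orthodromic_response):
            stim_sets[uid] = simulate_stimulation(
                config.stim_spec, spec, spikes, np.random.default_rng(st_stim),
                unit_id=uid, span=stim_epoch)

    emg = {}
    if config.emg_enabled:
        emg = simulate_emg(trials, np.random.default_rng(s_emg), span,
                           config.emg_params)
    lfp = {}
    if config.lfp_enabled:
        lfp = simulate_lfp(span[1] - span[0], config.condition,
                           np.random.default_rng(s_lfp),
                           config.lfp_beta_amplitude, config.lfp_params,
                           t0=span[0])

    session = SessionData(
        pedal=trace, blocks=blocks, units=units, stim=stim_sets,
        emg=emg, lfp=lfp,
        metadata=dict(area=config.area, condition=config.condition,
                      hemisphere=config.hemisphere, seed=config.seed),
    )
    truth = GroundTruth(units=_ground_truth_units(specs, unit_ids),
                        trials=_ground_truth_trials(trials))
    return session, truth


# Mean generator laterality per condition for group-level studies: the
# lesioned hemisphere loses most of its contralateral preference while the
# non-lesioned hemisphere keeps (or slightly strengthens) it.
CONDITION_LATERALITY_MEANS = {"H": 0.38, "NL": 0.40, "L": 0.05}
CONDITION_LATERALITY_SD = 0.30


def condition_unit_specs(condition: str, n_units: int,
                         rng: np.random.Generator,
                         baseline_rate: float = 5.0,
                         max_modulation: float = 25.0) -> list[UnitSpec]:
    """Go-type unit specs whose true laterality indices are drawn around the
    condition mean (clipped to (-0.9, 0.9))."""
    mu = CONDITION_LATERALITY_MEANS[condition]
    targets = np.clip(rng.normal(mu, CONDITION_LATERALITY_SD, size=n_units),
                      -0.9, 0.9)
    return specs_for_true_index(targets, baseline_rate=baseline_rate,
                                max_modulation=max_modulation)


def specs_for_true_index(index_values: Sequence[float], baseline_rate: float = 5.0,
                         max_modulation: float = 25.0) -> list[UnitSpec]:
    """Go-type specs whose analytic laterality index equals each target value.

    With both modulations positive the true index reduces to
    (A_c - A_i)/(A_c + A_i); the larger modulation is pinned at
    ``max_modulation`` Hz.
    """
    specs = []
    for L in index_values:
        if not -1.0 < L < 1.0:
            raise ConfigError("specs_for_true_index: targets must lie in (-1, 1)")
        if L >= 0:
            a_c = max_modulation
            a_i = max_modulation * (1 - L) / (1 + L)
        else:
            a_i = max_modulation
            a_c = max_modulation * (1 + L) / (1 - L)
        specs.append(UnitSpec(functional_type="Go", baseline_rate=baseline_rate,
                              peak_rate_contra=a_c, peak_rate_ipsi=a_i))
    return specs
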