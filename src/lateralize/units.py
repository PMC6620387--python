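"""Per-unit basal spiking properties, waveform-based RS/FS typing, and
event-aligned PETH machinery.

All event-aligned analyses use 20-ms bins over [-1.0, +0.5] s relative to
release onset; display smoothing uses a Gaussian kernel (sigma 12.5 ms) on a
0.05-ms grid.  Units are typed regular-spiking (RS) when the spike duration
(onset to first positive peak) exceeds 0.6 ms, fast-spiking (FS) otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

PETH_WINDOW = (-1.0, 0.5)  # s re release onset
PETH_BIN = 0.020  # s
RS_DURATION_MS = 0.6  # RS iff duration strictly greater
PEAK_N_BINS = 15  # 300 ms peak-averaging window
SMOOTH_SIGMA_S = 0.0125
SMOOTH_GRID_S = 0.00005


@dataclass
class WaveformMetrics:
    duration: float  # ms, onset -> first positive peak
    width: float  # ms, time above half-amplitude of the positive wave
    cell_class: str  # "RS" | "FS"


@dataclass
class Peth:
    """Event-aligned binned firing-rate estimate."""

    align_event: str
    bin_edges: np.ndarray  # s re event
    rate: np.ndarray  # Hz per bin
    n_trials: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class SpikingProperties:
    ongoing_rate: float
    isi_cv: float
    peak_rate: float
    peak_time: float
    n_spikes: int


def remove_poststim_spikes(spikes: np.ndarray, stim_times: np.ndarray,
                           blank: float = 1.0) -> np.ndarray:
    """Drop spikes within (t_stim, t_stim + 1 s] of any stimulation event."""
    spikes = np.asarray(spikes, dtype=float)
    stim_times = np.asarray(stim_times, dtype=float)
    if spikes.size == 0 or stim_times.size == 0:
        return spikes
    idx = np.searchsorted(stim_times, spikes, side="left") - 1
    ok = idx >= 0
    j = np.clip(idx, 0, None)
    within = ok & (spikes - stim_times[j] <= blank) & (spikes - stim_times[j] > 0)
    return spikes[~within]


def _exclusion_union(movement_times: np.ndarray,
                     window: tuple[float, float]) -> list[tuple[float, float]]:
    """Union of [m + w0, m + w1] intervals."""
    if movement_times.size == 0:
        return []
    ivs = sorted((m + window[0], m + window[1]) for m in movement_times)
    merged = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(iv) for iv in merged]


def ongoing_rate(spikes: np.ndarray, movement_times: np.ndarray,
                 session_span: tuple[float, float],
                 window: tuple[float, float] = (-1.0, 0.5)) -> float:
    """Average firing rate excluding [-1, +0.5] s around each movement.

    Overlapping exclusion windows are merged (no double exclusion); raises
    when no non-excluded time remains.
    """
    spikes = np.asarray(spikes, dtype=float)
    t0, t1 = session_span
    merged = _exclusion_union(np.asarray(movement_times, dtype=float), window)
    excl_time = 0.0
    n_excl = 0
    for a, b in merged:
        a, b = max(a, t0), min(b, t1)
        if b > a:
            excl_time += b - a
            n_excl += int(np.searchsorted(spikes, b, side="right")
                          - np.searchsorted(spikes, a, side="left"))
    total = (t1 - t0) - excl_time
    if total <= 0:
        raise ValueError("no non-excluded time for ongoing rate")
    in_span = int(np.searchsorted(spikes, t1, side="right")
                  - np.searchsorted(spikes, t0, side="left"))
    return (in_span - n_excl) / total


def isi_cv(spikes: np.ndarray) -> float:
    """Coefficient of variation of the interspike intervals (SD/mean).

    Returns NaN for fewer than 3 spikes (fewer than 2 intervals).
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size < 3:
        return np.nan
    isi = np.diff(spikes)
    m = isi.mean()
    return float(isi.std() / m) if m > 0 else np.nan


def waveform_metrics(waveform: np.ndarray, sampling_rate: float = 20_000.0,
                     onset_fraction: float = 0.05) -> WaveformMetrics:
    """Spike duration (onset to first positive peak), width (time above half
    of the positive peak) and the RS/FS class (RS iff duration > 0.6 ms)."""
    w = np.asarray(waveform, dtype=float)
    if w.size < 3:
        raise ValueError("waveform too short")
    amax = np.abs(w).max()
    if amax <= 0:
        raise ValueError("flat waveform")
    dev = np.flatnonzero(np.abs(w) > onset_fraction * amax)
    onset_idx = int(dev[0]) if dev.size else 0
    # first positive local maximum after onset
    pos_peaks = [k for k in range(max(onset_idx, 1), w.size - 1)
                 if w[k] > 0 and w[k] >= w[k - 1] and w[k] >= w[k + 1]]
    if not pos_peaks:
        raise ValueError("waveform has no positive peak after onset")
    peak_idx = pos_peaks[0]
    # if the first local max is a shoulder, take the global positive max beyond it
    gmax = peak_idx + int(np.argmax(w[peak_idx:]))
    if w[gmax] > w[peak_idx] * 1.05:
        peak_idx = gmax
    duration_ms = (peak_idx - onset_idx) / sampling_rate * 1000.0
    half = 0.5 * w[peak_idx]
    above = w > half
    width_ms = float(above.sum()) / sampling_rate * 1000.0
    cls = "RS" if duration_ms > RS_DURATION_MS else "FS"
    return WaveformMetrics(duration=duration_ms, width=width_ms, cell_class=cls)


def align_spikes(spikes: np.ndarray, align_times: Sequence[float],
                 window: tuple[float, float] = PETH_WINDOW) -> list[np.ndarray]:
    """Per-trial spike offsets relative to each alignment event."""
    spikes = np.asarray(spikes, dtype=float)
    out = []
    for t in align_times:
        lo = np.searchsorted(spikes, t + window[0], side="left")
        hi = np.searchsorted(spikes, t + window[1], side="right")
        out.append(spikes[lo:hi] - t)
    return out


def build_peth(spikes: np.ndarray, align_times: Sequence[float],
               window: tuple[float, float] = PETH_WINDOW,
               bin_width: float = PETH_BIN,
               align_event: str = "release_onset") -> Peth:
    """Trial-averaged binned firing rate around the alignment events."""
    align_times = np.asarray(align_times, dtype=float)
    if align_times.size == 0:
        raise ValueError("build_peth requires at least one alignment event")
    n_bins = int(round((window[1] - window[0]) / bin_width))
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for rel in align_spikes(spikes, align_times, window):
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (align_times.size * bin_width)
    return Peth(align_event=align_event, bin_edges=edges, rate=rate,
                n_trials=int(align_times.size))


def smooth_peth(spikes_by_trial: Sequence[np.ndarray],
                window: tuple[float, float] = PETH_WINDOW,
                sigma: float = SMOOTH_SIGMA_S,
                grid: float = SMOOTH_GRID_S) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-filtered rate estimate (sigma 12.5 ms on a 0.05-ms grid).

    Returns (times, rate) with the total spike mass preserved (the kernel is
    normalized; edge spill-over is below 1% for in-window activity).
    """
    n_trials = len(spikes_by_trial)
    if n_trials == 0:
        raise ValueError("smooth_peth requires at least one trial")
    n = int(round((window[1] - window[0]) / grid))
    t = window[0] + grid * (np.arange(n) + 0.5)
    counts = np.zeros(n)
    for rel in spikes_by_trial:
        rel = np.asarray(rel, dtype=float)
        sel = rel[(rel >= window[0]) & (rel < window[1])]
        idx = ((sel - window[0]) / grid).astype(int)
        np.add.at(counts, np.clip(idx, 0, n - 1), 1.0)
    rate = counts / (n_trials * grid)
    smoothed = gaussian_filter1d(rate, sigma / grid, mode="constant", truncate=6.0)
    return t, smoothed


def peak_activity(peth: Peth, n_bins: int = PEAK_N_BINS) -> tuple[float, float]:
    """Peak activity: the mean rate over the 15-bin (300 ms) window centered
    at the maximum bin, truncated at the PETH edges; ties break to the
    earliest bin.  Returns (peak_rate, peak_time)."""
    if not np.any(peth.rate > 0):
        raise ValueError("peak undefined for an all-zero PETH")
    k = int(np.argmax(peth.rate))  # argmax returns the earliest maximum
    half = n_bins // 2
    lo, hi = max(0, k - half), min(peth.rate.size, k + half + 1)
    peak_rate = float(np.mean(peth.rate[lo:hi]))
    return peak_rate, float(peth.bin_centers[k])


def spiking_properties(spikes: np.ndarray, movement_times: np.ndarray,
                       session_span: tuple[float, float],
                       align_times: Optional[Sequence[float]] = None
                       ) -> SpikingProperties:
    """Ongoing rate, ISI CV and peak metrics for one unit."""
    rate = ongoing_rate(spikes, movement_times, session_span)
    cv = isi_cv(spikes)
    peak_rate = peak_time = np.nan
    if align_times is not None and len(align_times) > 0:
        peth = build_peth(spikes, align_times)
        if np.any(peth.rate > 0):
            peak_rate, peak_time = peak_activity(peth)
    return SpikingProperties(ongoing_rate=rate, isi_cv=cv, peak_rate=peak_rate,
                             peak_time=peak_time,
                             n_spikes=int(np.asarray(spikes).size))
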