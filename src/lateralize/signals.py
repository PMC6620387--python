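"""EMG rectification / onset / peak metrics and LFP spectral analysis.

EMG onset follows a 5-SD rule: rectified activity is binned at 1 ms and the
onset is the first run of >= 10 consecutive bins exceeding the baseline mean
by 5 baseline SDs, where the baseline is the [-1000, -700] ms window before
release onset.  LFP analysis takes +/-1 s segments around the release onset
of correct trials (bandpass 0.5-100 Hz, optionally rectified), averages
per-segment FFT power spectra, and sums power over the 15-35 Hz beta band.
Inter-areal coupling uses magnitude-squared wavelet coherence (analytic
Morlet) with time- and scale-smoothing, normalized to [0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pywt
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .core import EmgTrace, LfpTrace

EMG_BIN_S = 0.001
EMG_BASELINE_WINDOW = (-1.0, -0.7)  # s re release onset
EMG_SD_FACTOR = 5.0
EMG_MIN_RUN = 10  # consecutive 1-ms bins
BETA_BAND = (15.0, 35.0)  # Hz
LFP_SEGMENT_HALF_S = 1.0
LFP_BANDPASS = (0.5, 100.0)  # Hz


@dataclass
class SpectrumResult:
    freqs: np.ndarray
    power: np.ndarray  # averaged across segments
    band_power: float  # summed (or mean) power over the beta band
    band: tuple = BETA_BAND
    n_segments: int = 0


@dataclass
class CoherenceMap:
    times: np.ndarray
    freqs: np.ndarray
    coherence: np.ndarray  # (n_freqs, n_times) in [0, 1]


# ---------------------------------------------------------------------------
# EMG


def rectify(values: np.ndarray) -> np.ndarray:
    """Pointwise absolute value."""
    return np.abs(np.asarray(values, dtype=float))


def _bin_power(trace: EmgTrace, t_start: float, n_bins: int,
               bin_s: float = EMG_BIN_S) -> np.ndarray:
    """Mean rectified amplitude per 1-ms bin from t_start onward."""
    per_bin = int(round(trace.sampling_rate * bin_s))
    i0 = int(round((t_start - trace.t0) * trace.sampling_rate))
    need = n_bins * per_bin
    if i0 < 0 or i0 + need > trace.values.size:
        raise ValueError("requested EMG window exceeds trace bounds")
    seg = rectify(trace.values[i0:i0 + need])
    return seg.reshape(n_bins, per_bin).mean(axis=1)


def emg_onset(trace: EmgTrace, release_onset: float,
              search_window: tuple[float, float] = (-0.7, 0.5),
              baseline_window: tuple[float, float] = EMG_BASELINE_WINDOW,
              sd_factor: float = EMG_SD_FACTOR,
              min_run: int = EMG_MIN_RUN) -> Optional[float]:
    """Muscle-activity onset before one release, or None if no burst.

    Returns the absolute time of the first of >= ``min_run`` consecutive
    1-ms bins whose rectified power exceeds baseline mean + 5 SD.
    """
    nb_base = int(round((baseline_window[1] - baseline_window[0]) / EMG_BIN_S))
    base = _bin_power(trace, release_onset + baseline_window[0], nb_base)
    mu, sd = float(base.mean()), float(base.std())
    if sd == 0.0:
        raise ValueError("degenerate EMG baseline (SD = 0)")
    nb = int(round((search_window[1] - search_window[0]) / EMG_BIN_S))
    power = _bin_power(trace, release_onset + search_window[0], nb)
    above = power > mu + sd_factor * sd
    run = 0
    for k, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_run:
            start_bin = k - min_run + 1
            return release_onset + search_window[0] + start_bin * EMG_BIN_S
    return None


def emg_peak_change(trace: EmgTrace, release_onset: float,
                    peak_search: tuple[float, float] = (-0.5, 0.5),
                    peak_half_window: float = 0.150,
                    baseline_window: tuple[float, float] = EMG_BASELINE_WINDOW,
                    ) -> float:
    """Movement-associated EMG change in % of baseline activity.

    The peak metric is the mean rectified activity in +/-150 ms around the
    maximum 1-ms-binned activity near the movement; the change is expressed
    relative to the baseline-period activity.
    """
    nb_base = int(round((baseline_window[1] - baseline_window[0]) / EMG_BIN_S))
    base = _bin_power(trace, release_onset + baseline_window[0], nb_base)
    mu = float(base.mean())
    if mu == 0.0:
        raise ValueError("EMG baseline activity is zero")
    nb = int(round((peak_search[1] - peak_search[0]) / EMG_BIN_S))
    power = _bin_power(trace, release_onset + peak_search[0], nb)
    k = int(np.argmax(power))
    half = int(round(peak_half_window / EMG_BIN_S))
    lo, hi = max(0, k - half), min(nb, k + half + 1)
    peak = float(power[lo:hi].mean())
    return 100.0 * (peak / mu - 1.0)


# ---------------------------------------------------------------------------
# LFP


def lfp_segments(trace: LfpTrace, release_onsets: Sequence[float],
                 half_window: float = LFP_SEGMENT_HALF_S,
                 bandpass: tuple[float, float] = LFP_BANDPASS,
                 do_rectify: bool = True) -> tuple[np.ndarray, int]:
    """One +/-1 s segment per (correct) trial, bandpassed and rectified.

    Trials whose window exceeds the trace bounds are skipped; returns
    (segments, n_skipped).
    """
    fs = trace.sampling_rate
    nyq = fs / 2.0
    sos = sps.butter(4, [bandpass[0] / nyq, min(bandpass[1] / nyq, 0.999)],
                     btype="band", output="sos")
    filtered = sps.sosfiltfilt(sos, trace.values)
    if do_rectify:
        filtered = np.abs(filtered)
    n_half = int(round(half_window * fs))
    segs = []
    skipped = 0
    for t in release_onsets:
        c = int(round((t - trace.t0) * fs))
        if c - n_half < 0 or c + n_half > filtered.size:
            skipped += 1
            continue
        segs.append(filtered[c - n_half:c + n_half])
    return (np.array(segs) if segs else np.empty((0, 2 * n_half))), skipped


def power_spectrum(segments: np.ndarray, sampling_rate: float = 1000.0,
                   band: tuple[float, float] = BETA_BAND,
                   band_agg: str = "sum") -> SpectrumResult:
    """Per-segment Hann-windowed FFT power, averaged across segments.

    ``band_power`` integrates the power spectral density over the beta band
    (sum of psd * df by default; ``band_agg="mean"`` averages the band bins
    instead).
    """
    segments = np.atleast_2d(np.asarray(segments, dtype=float))
    if segments.shape[0] < 1 or segments.size == 0:
        raise ValueError("power_spectrum requires at least one segment")
    freqs, psd = sps.periodogram(segments, fs=sampling_rate, window="hann",
                                 scaling="density", axis=-1)
    mean_psd = psd.mean(axis=0)
    df = freqs[1] - freqs[0]
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if band_agg == "sum":
        band_power = float(np.sum(mean_psd[mask]) * df)
    elif band_agg == "mean":
        band_power = float(np.mean(mean_psd[mask]))
    else:
        raise ValueError(f"unknown band_agg {band_agg!r}")
    return SpectrumResult(freqs=freqs, power=mean_psd, band_power=band_power,
                          band=band, n_segments=segments.shape[0])


def _cwt(x: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    wavelet = "cmor1.5-1.0"
    fc = pywt.central_frequency(wavelet)
    scales = fc * fs / freqs
    coeffs, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs,
                         method="fft")
    return coeffs


def _smooth(z: np.ndarray, freqs: np.ndarray, fs: float,
            time_cycles: float, scale_bins: int) -> np.ndarray:
    """Smooth a (possibly complex) scalogram over time (Gaussian, width
    proportional to the scale) then over scales (boxcar)."""
    out = np.empty_like(z)
    for k, f in enumerate(freqs):
        sigma = time_cycles * fs / f  # samples per smoothing span at this scale
        if np.iscomplexobj(z):
            out[k] = (gaussian_filter1d(z[k].real, sigma, mode="nearest")
                      + 1j * gaussian_filter1d(z[k].imag, sigma, mode="nearest"))
        else:
            out[k] = gaussian_filter1d(z[k], sigma, mode="nearest")
    if scale_bins > 1:
        if np.iscomplexobj(out):
            out = (uniform_filter1d(out.real, scale_bins, axis=0, mode="nearest")
                   + 1j * uniform_filter1d(out.imag, scale_bins, axis=0,
                                           mode="nearest"))
        else:
            out = uniform_filter1d(out, scale_bins, axis=0, mode="nearest")
    return out


def wavelet_coherence(a: np.ndarray, b: np.ndarray, sampling_rate: float = 1000.0,
                      freqs: Optional[np.ndarray] = None,
                      time_cycles: float = 1.0,
                      scale_bins: int = 5) -> CoherenceMap:
    """Magnitude-squared wavelet coherence between two equal-length signals.

    Analytic Morlet CWT; the cross- and auto-spectra are smoothed over time
    (Gaussian, ``time_cycles`` cycles wide per scale) and across scales
    (boxcar over ``scale_bins`` neighbors).  Entries are clipped to [0, 1];
    identical (or proportional) signals give coherence 1 everywhere.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("wavelet_coherence requires equal-length signals")
    if freqs is None:
        freqs = np.geomspace(4.0, 100.0, 40)
    wa = _cwt(a, freqs, sampling_rate)
    wb = _cwt(b, freqs, sampling_rate)
    s_ab = _smooth(wa * np.conj(wb), freqs, sampling_rate, time_cycles, scale_bins)
    s_aa = _smooth(np.abs(wa) ** 2, freqs, sampling_rate, time_cycles, scale_bins)
    s_bb = _smooth(np.abs(wb) ** 2, freqs, sampling_rate, time_cycles, scale_bins)
    denom = s_aa * s_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(s_ab) ** 2 / np.where(denom > 0, denom, np.nan)
    coh = np.clip(np.nan_to_num(coh, nan=0.0), 0.0, 1.0)
    times = np.arange(a.size) / sampling_rate
    return CoherenceMap(times=times, freqs=freqs, coherence=coh)


def band_coherence(cmap: CoherenceMap, band: tuple[float, float] = BETA_BAND) -> float:
    """Mean coherence over a frequency band (time-averaged)."""
    mask = (cmap.freqs >= band[0]) & (cmap.freqs <= band[1])
    if not mask.any():
        raise ValueError("band outside the analyzed frequencies")
    return float(cmap.coherence[mask].mean())
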