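"""Antidromic spike-collision identification of IT and PT projection neurons.

Stimulation of the contralateral motor cortex probes intratelencephalic (IT)
axons; stimulation of the ipsilateral pontine nuclei probes pyramidal-tract
(PT) axons.  For each stimulated unit the pipeline: (1) sets a detection
window where the averaged control trace diverges from the averaged
collision-test trace, (2) picks an amplitude cutoff on the most-negative
in-window point by ROC, (3) counts spike/no-spike events per mode, (4)
requires a control spike probability >= 50% with a test probability below
half of it, (5) confirms the collisional disappearance with a 2x2 chi-square
test (p < 0.05), and (6) requires constant latency (quartile jitter
<= 0.5 ms) and, when available, frequency-following at 100 and 200 Hz.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import StimEventSet

DETECTION_SD_FACTOR = 3.0
CONTROL_P_MIN = 0.5
CHI2_ALPHA = 0.05
JITTER_MAX_MS = 0.5
FF_MIN_FRACTION = 0.5


@dataclass
class CollisionResult:
    """Evidence from one stimulation site for one unit."""

    unit_id: str = ""
    site: str = ""
    window: Optional[tuple[float, float]] = None  # ms re stimulus
    cutoff: float = np.nan
    p_control: float = np.nan
    p_test: float = np.nan
    counts: Optional[np.ndarray] = None  # 2x2 spike/no-spike x control/test
    chi2_p: float = np.nan
    latency: float = np.nan  # ms, median peak position
    jitter: float = np.nan  # ms, Q3 - Q1
    eligible: bool = False
    constant_latency: bool = False
    ff_pass: Optional[bool] = None  # None when untested
    passed: bool = False
    reason: Optional[str] = None


def detection_window(
    snippets_with: np.ndarray,
    snippets_without: np.ndarray,
    times_ms: np.ndarray,
    sd_factor: float = DETECTION_SD_FACTOR,
    pad_ms: float = 0.5,
    min_onset_ms: float = 0.5,
) -> Optional[tuple[float, float]]:
    """Window where the averaged with-spike trace diverges from the averaged
    without-spike trace beyond ``sd_factor`` x the without-spike SD.

    The earliest contiguous divergence lobe after ``min_onset_ms`` is taken
    and padded by roughly one waveform width; returns None when the traces
    never dissociate (the unit is then unidentifiable from this site).
    """
    with_mean = np.atleast_2d(snippets_with).mean(axis=0)
    wo = np.atleast_2d(snippets_without)
    wo_mean = wo.mean(axis=0)
    noise_sd = float(wo.std())
    if noise_sd == 0:
        noise_sd = 1e-12
    diverged = np.abs(with_mean - wo_mean) > sd_factor * noise_sd
    diverged &= times_ms >= min_onset_ms
    idx = np.flatnonzero(diverged)
    if idx.size == 0:
        return None
    # earliest contiguous lobe (allow single-sample gaps)
    start = idx[0]
    end = start
    for k in idx[1:]:
        if k - end <= 2:
            end = k
        else:
            break
    t0 = max(float(times_ms[start]) - pad_ms, 0.0)
    t1 = min(float(times_ms[end]) + pad_ms, float(times_ms[-1]))
    return (t0, t1)


def min_amplitudes(snippets: np.ndarray, times_ms: np.ndarray,
                   window: tuple[float, float]) -> np.ndarray:
    """Most negative in-window point per snippet."""
    mask = (times_ms >= window[0]) & (times_ms <= window[1])
    if not mask.any():
        raise ValueError("detection window outside snippet support")
    return np.atleast_2d(snippets)[:, mask].min(axis=1)


def roc_cutoff(amps_spike: np.ndarray, amps_nospike: np.ndarray) -> float:
    """Amplitude threshold maximizing Youden's J on the ROC between the two
    most-negative-point distributions (spike present iff amplitude below the
    threshold).  Identical distributions fall back to the pooled median with
    a warning."""
    amps_spike = np.asarray(amps_spike, dtype=float)
    amps_nospike = np.asarray(amps_nospike, dtype=float)
    if amps_spike.size == 0 or amps_nospike.size == 0:
        raise ValueError("both amplitude groups must be non-empty")
    cand = np.unique(np.concatenate([amps_spike, amps_nospike]))
    # midpoints between consecutive order statistics as candidate thresholds
    thr = (cand[:-1] + cand[1:]) / 2.0 if cand.size > 1 else cand
    tpr = np.array([(amps_spike < t).mean() for t in thr])
    fpr = np.array([(amps_nospike < t).mean() for t in thr])
    j = tpr - fpr
    if j.max() <= 1e-12:
        warnings.warn("spike/no-spike amplitude distributions are "
                      "indistinguishable; cutoff at pooled median")
        return float(np.median(np.concatenate([amps_spike, amps_nospike])))
    return float(thr[int(np.argmax(j))])


def spike_probabilities(
    control: StimEventSet, test: StimEventSet,
    window: tuple[float, float], cutoff: float,
) -> tuple[float, float, np.ndarray]:
    """Per-mode detected-spike fractions and the 2x2 count table
    [[control_spike, control_nospike], [test_spike, test_nospike]]."""
    out = []
    counts = np.zeros((2, 2), dtype=int)
    for row, ev in enumerate((control, test)):
        if ev.snippets.shape[0] == 0:
            raise ValueError(f"no events in {ev.mode} mode")
        amps = min_amplitudes(ev.snippets, ev.snippet_times, window)
        detected = amps < cutoff
        counts[row] = (int(detected.sum()), int((~detected).sum()))
        out.append(float(detected.mean()))
    return out[0], out[1], counts


def eligibility(p_control: float, p_test: float,
                control_min: float = CONTROL_P_MIN) -> bool:
    """Collision-test eligibility: control spike probability >= 50% and test
    probability below half of the control's."""
    return p_control >= control_min and p_test < 0.5 * p_control


def collision_chi2(counts: np.ndarray, alpha: float = CHI2_ALPHA
                   ) -> tuple[float, bool]:
    """Pearson chi-square (no continuity correction) on the 2x2 spike /
    no-spike x control/test table; pass iff p < 0.05."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("chi-square undefined for a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(p), bool(p < alpha)


def chi2_statistic(counts: np.ndarray) -> float:
    """Closed-form 2x2 Pearson statistic N(ad - bc)^2 / (row/col products)."""
    (a, b), (c, d) = np.asarray(counts, dtype=float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return float(n * (a * d - b * c) ** 2 / denom)


def latency_jitter(peak_positions_ms: Sequence[float],
                   jitter_max: float = JITTER_MAX_MS
                   ) -> tuple[float, float, bool]:
    """(latency, jitter, constant_latency_pass) from detected peak positions.

    Latency is the median (Q2) and jitter the Q3 - Q1 interquartile range of
    the peak positions (linear-interpolation quantiles); the constant-latency
    test passes iff jitter <= 0.5 ms.  Requires >= 4 detections.
    """
    peaks = np.asarray(peak_positions_ms, dtype=float)
    if peaks.size < 4:
        return np.nan, np.nan, False
    q1, q2, q3 = np.percentile(peaks, [25, 50, 75])
    jitter = float(q3 - q1)
    return float(q2), jitter, bool(jitter <= jitter_max)


def peak_positions(snippets: np.ndarray, times_ms: np.ndarray,
                   window: tuple[float, float], cutoff: float) -> np.ndarray:
    """Most-negative-point times (ms) of the detected in-window spikes."""
    mask = (times_ms >= window[0]) & (times_ms <= window[1])
    seg = np.atleast_2d(snippets)[:, mask]
    t_in = times_ms[mask]
    amps = seg.min(axis=1)
    detected = amps < cutoff
    return t_in[np.argmin(seg[detected], axis=1)] if detected.any() else np.empty(0)


def frequency_following(
    ff_sets: Sequence[StimEventSet],
    window: tuple[float, float], cutoff: float,
    min_fraction: float = FF_MIN_FRACTION,
) -> Optional[bool]:
    """Paired-pulse test: the second pulse's detection probability must be at
    least ``min_fraction`` of the first's at both 100 and 200 Hz.

    Returns None (test skipped) when no paired-pulse snippets exist.
    """
    tested = False
    for ev in ff_sets:
        if len(ev.pulse_offsets) < 2 or ev.snippets.shape[0] == 0:
            continue
        if window[1] + ev.pulse_offsets[1] > ev.snippet_times[-1]:
            continue  # second-pulse window outside snippet support
        tested = True
        probs = []
        for off in ev.pulse_offsets[:2]:
            w = (window[0] + off, window[1] + off)
            amps = min_amplitudes(ev.snippets, ev.snippet_times, w)
            probs.append(float((amps < cutoff).mean()))
        p1, p2 = probs
        if p1 == 0 or p2 < min_fraction * p1:
            return False
    return True if tested else None


def collision_test(
    control: StimEventSet,
    test: StimEventSet,
    ff_sets: Sequence[StimEventSet] = (),
    window: Optional[tuple[float, float]] = None,
) -> CollisionResult:
    """Run the full identification pipeline for one unit at one site.

    The detection window is derived from the control/test averaged-trace
    dissociation unless supplied manually.
    """
    res = CollisionResult(unit_id=control.unit_id, site=control.site)
    if window is None:
        if test.snippets.shape[0] == 0:
            res.reason = "no_test_events"
            return res
        window = detection_window(control.snippets, test.snippets,
                                  control.snippet_times)
    if window is None:
        res.reason = "no_detection_window"
        return res
    res.window = window
    amps_ctrl = min_amplitudes(control.snippets, control.snippet_times, window)
    amps_test = min_amplitudes(test.snippets, test.snippet_times, window)
    res.cutoff = roc_cutoff(amps_ctrl, amps_test)
    res.p_control, res.p_test, res.counts = spike_probabilities(
        control, test, window, res.cutoff)
    res.eligible = eligibility(res.p_control, res.p_test)
    if not res.eligible:
        res.reason = "eligibility"
        return res
    try:
        res.chi2_p, chi_ok = collision_chi2(res.counts)
    except ValueError:
        res.reason = "degenerate_counts"
        return res
    peaks = peak_positions(control.snippets, control.snippet_times, window,
                           res.cutoff)
    res.latency, res.jitter, res.constant_latency = latency_jitter(peaks)
    res.ff_pass = frequency_following(ff_sets, window, res.cutoff)
    ff_ok = res.ff_pass is not False  # skipped test does not fail the unit
    res.passed = bool(chi_ok and res.constant_latency and ff_ok)
    if not res.passed:
        res.reason = ("chi2" if not chi_ok
                      else "jitter" if not res.constant_latency else "ff")
    return res


SITE_CLASS = {"contralateral_cortex": "IT", "ipsilateral_pons": "PT"}


@dataclass
class ProjectionAssignment:
    unit_id: str
    projection_class: str  # "IT" | "PT" | "unidentified"
    conflict: bool = False
    results: list = field(default_factory=list)


def assign_projection(unit_id: str, site_results: Sequence[CollisionResult]
                      ) -> ProjectionAssignment:
    """IT iff contralateral-cortex stimulation passes; PT iff ipsilateral
    pons passes; both passing is a conflict (excluded from IT/PT groups)."""
    passed = {SITE_CLASS.get(r.site) for r in site_results if r.passed}
    passed.discard(None)
    if len(passed) == 1:
        cls = passed.pop()
        return ProjectionAssignment(unit_id, cls, results=list(site_results))
    if len(passed) > 1:
        return ProjectionAssignment(unit_id, "unidentified", conflict=True,
                                    results=list(site_results))
    return ProjectionAssignment(unit_id, "unidentified", results=list(site_results))


def identify_units(stim: dict[str, list[StimEventSet]]
                   ) -> dict[str, ProjectionAssignment]:
    """Run collision tests for every stimulated unit in a session."""
    out = {}
    for uid, sets in stim.items():
        by_site: dict[str, dict[str, list[StimEventSet]]] = {}
        for ev in sets:
            d = by_site.setdefault(ev.site, {"control": [], "test": [], "ff": []})
            if ev.mode == "control":
                d["control"].append(ev)
            elif ev.mode == "test":
                d["test"].append(ev)
            else:
                d["ff"].append(ev)
        results = []
        for site, d in by_site.items():
            if not d["control"] or not d["test"]:
                continue
            results.append(collision_test(d["control"][0], d["test"][0],
                                          ff_sets=d["ff"]))
        out[uid] = assign_projection(uid, results)
    return out
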