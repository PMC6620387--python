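"""Self-validation studies: ground-truth recovery on synthetic sessions.

Each function runs one study end to end through the package — generate the
stated synthetic data, run the analysis, measure recovery — and returns the
headline numbers.  The studies dimension the problem the way a desk-scale
replication would: unit counts, trial counts and event counts follow the
package's own validation protocol (see docs/methods.md) and every random
draw derives from the caller's seed.
"""
from __future__ import annotations

import numpy as np

from . import behavior
from .classify import hold_go_classify, crossing_time_75, task_relevance_index
from .collision import chi2_statistic, identify_units
from .laterality import laterality_index, unit_laterality
from .model import SessionAnalysis
from .signals import emg_onset, lfp_segments, power_spectrum, wavelet_coherence
from .simulate import (
    EmgParams,
    LfpParams,
    SimConfig,
    StimSpec,
    UnitSpec,
    condition_unit_specs,
    make_trial_scaffold,
    simulate_emg,
    simulate_lfp,
    simulate_stimulation,
    simulate_unit_spikes,
    specs_for_true_index,
)
from .stats import group_compare
from .units import align_spikes, build_peth, peak_activity


def laterality_branches() -> dict:
    """The saturated branches of the piecewise index."""
    return dict(
        excited_contra_only=laterality_index(0.3, -0.1),
        excited_ipsi_only=laterality_index(-0.2, 0.4),
    )


def self_coherence_peak(seed: int, n: int = 2000) -> float:
    """Wavelet coherence of a pink-ish noise trace with itself: peak value."""
    rng = np.random.default_rng(seed)
    lfp = simulate_lfp(n / 1000.0, "H", rng, {"H": 0.4})
    x = lfp["M1"].values[:n]
    return float(wavelet_coherence(x, x).coherence.max())


def laterality_recovery(seed: int, n_units: int = 200,
                        n_per_side: int = 60) -> dict:
    """Median |recovered - true| laterality index over a grid of true values
    in [-0.8, 0.8] (baseline 5 Hz, max modulation 25 Hz)."""
    rng = np.random.default_rng(seed)
    targets = np.linspace(-0.8, 0.8, n_units)
    specs = specs_for_true_index(targets)
    trials = make_trial_scaffold(n_per_side, rng)
    contra = [t.release_onset for t in trials if t.side == "right"]
    ipsi = [t.release_onset for t in trials if t.side == "left"]
    errs = []
    for spec, tgt in zip(specs, targets):
        spikes = simulate_unit_spikes(spec, trials, rng)
        res = unit_laterality(spikes, contra, ipsi)
        errs.append(abs(res.index - tgt) if res.defined else np.nan)
    errs = np.asarray(errs)
    return dict(median_abs_error=float(np.nanmedian(errs)),
                n_defined=int(np.isfinite(errs).sum()), n=n_units)


def hold_go_typing(seed: int, n_units_per_type: int = 30,
                   n_per_side: int = 40, modulation: float = 15.0) -> dict:
    """Fraction of step-profile (Hold) and bump-profile (Go) units whose
    functional type is recovered by the crossing-time slope rule."""
    rng = np.random.default_rng(seed)
    trials = make_trial_scaffold(n_per_side, rng)
    contra = [t for t in trials if t.side == "right"]
    onsets = [t.release_onset for t in contra]
    holding = [t.holding_duration for t in contra]
    correct = {"Hold": 0, "Go": 0}
    for ftype in ("Hold", "Go"):
        for _ in range(n_units_per_type):
            spec = UnitSpec(functional_type=ftype, baseline_rate=5.0,
                            peak_rate_contra=modulation,
                            peak_rate_ipsi=modulation)
            spikes = simulate_unit_spikes(spec, trials, rng)
            peth = build_peth(spikes, onsets)
            _, peak_time = peak_activity(peth)
            by_trial = align_spikes(spikes, onsets, window=(-3.5, 0.5))
            crossings = crossing_time_75(by_trial, holding)
            got = hold_go_classify(peak_time, crossings).functional_type
            correct[ftype] += int(got == ftype)
    n = n_units_per_type
    return dict(accuracy=float((correct["Hold"] + correct["Go"]) / (2 * n)),
                hold_accuracy=correct["Hold"] / n,
                go_accuracy=correct["Go"] / n, n=2 * n)


def untuned_false_positive_rate(seed: int, n_units: int = 1000,
                                n_per_side: int = 20) -> dict:
    """Fraction of untuned (homogeneous) units flagged task-related at the
    p < 1e-6 threshold."""
    rng = np.random.default_rng(seed)
    trials = make_trial_scaffold(n_per_side, rng)
    onsets = [t.release_onset for t in trials]
    spec = UnitSpec(functional_type="untuned", baseline_rate=7.0,
                    peak_rate_contra=0.0, peak_rate_ipsi=0.0)
    flagged = 0
    tested = 0
    for _ in range(n_units):
        spikes = simulate_unit_spikes(spec, trials, rng)
        by_trial = align_spikes(spikes, onsets)
        try:
            p = task_relevance_index(by_trial)
        except ValueError:
            continue
        tested += 1
        flagged += int(p < 1e-6)
    return dict(rate=float(flagged / tested) if tested else np.nan,
                n=tested)


def projection_identification(seed: int, n_projection: int = 50,
                              n_orthodromic: int = 50) -> dict:
    """Sensitivity/specificity of IT/PT assignment and the PT-vs-IT latency
    ordering on simulated antidromic and orthodromic responders."""
    rng = np.random.default_rng(seed)
    stim = StimSpec()
    sets, true = {}, {}
    for k in range(n_projection + n_orthodromic):
        if k < n_projection // 2:
            spec = UnitSpec(projection="IT",
                            antidromic_latency=float(rng.normal(11.7, 1.0)),
                            antidromic_reliability=0.9)
        elif k < n_projection:
            spec = UnitSpec(projection="PT",
                            antidromic_latency=float(rng.normal(6.9, 0.8)),
                            antidromic_reliability=0.9)
        else:
            spec = UnitSpec(projection="none", orthodromic_response=True,
                            antidromic_latency=float(rng.normal(9.0, 1.0)),
                            antidromic_reliability=0.9)
        uid = f"u{k:03d}"
        true[uid] = spec.projection
        sub = np.random.default_rng(rng.integers(2 ** 31))
        spikes = simulate_unit_spikes(spec, [], sub, span=(0.0, 300.0))
        sets[uid] = simulate_stimulation(stim, spec, spikes, sub,
                                         unit_id=uid, span=(0.0, 300.0))
    res = identify_units(sets)
    tp = sum(pa.projection_class == true[uid]
             for uid, pa in res.items() if true[uid] != "none")
    tn = sum(pa.projection_class == "unidentified"
             for uid, pa in res.items() if true[uid] == "none")
    lats = {"IT": [], "PT": []}
    for uid, pa in res.items():
        if pa.projection_class in lats and pa.results:
            lats[pa.projection_class].append(
                next(r.latency for r in pa.results if r.passed))
    return dict(
        sensitivity=float(tp / n_projection),
        specificity=float(tn / n_orthodromic),
        pt_latency_median=float(np.median(lats["PT"])) if lats["PT"] else np.nan,
        it_latency_median=float(np.median(lats["IT"])) if lats["IT"] else np.nan,
        n=n_projection + n_orthodromic,
    )


def chi2_closed_form() -> float:
    """Pearson statistic of the textbook 2x2 collision table."""
    return chi2_statistic(np.array([[45, 5], [5, 45]]))


def emg_onset_recovery(seed: int, n_trials: int = 30,
                       burst_amplitude: float = 8.0,
                       n_noise_draws: int = 1000) -> dict:
    """Onset error on synthetic bursts and the false-onset rate on noise."""
    from .core import EmgTrace

    rng = np.random.default_rng(seed)
    trials = make_trial_scaffold(n_trials, rng)
    emg = simulate_emg(trials, rng, (0.0, trials[-1].release_event + 2.0),
                       EmgParams(burst_amplitude=burst_amplitude))
    errs = []
    for tr in trials:
        onset = emg_onset(emg[tr.side], tr.release_onset)
        errs.append(np.nan if onset is None
                    else abs(onset - tr.emg_onset) * 1000.0)
    errs = np.asarray(errs)
    fp = 0
    fs = 10_000.0
    for k in range(n_noise_draws):
        sub = np.random.default_rng(rng.integers(2 ** 31))
        trace = EmgTrace(values=sub.normal(0, 1, int(2.2 * fs)),
                         sampling_rate=fs, side="right", t0=-1.2)
        if emg_onset(trace, 0.0) is not None:
            fp += 1
    return dict(median_abs_error_ms=float(np.nanmedian(errs)),
                max_abs_error_ms=float(np.nanmax(errs)),
                n_missed=int(np.isnan(errs).sum()),
                false_onset_rate=float(fp / n_noise_draws),
                n=len(errs))


def beta_power_scaling(seed: int) -> dict:
    """Band-power ratio when the 20 Hz component doubles (expected 4)."""
    rng = np.random.default_rng(seed)
    band = []
    for amp in (0.4, 0.8):
        lfp = simulate_lfp(30.0, "H", rng, {"H": amp},
                           LfpParams(background_sd=0.0))
        segs, _ = lfp_segments(lfp["M1"], np.arange(2.0, 28.0, 2.5),
                               do_rectify=False)
        band.append(power_spectrum(segs).band_power)
    return dict(ratio=float(band[1] / band[0]), n=11)


def condition_contrast(seed: int, n_units_per_group: int = 100) -> dict:
    """Three-condition study: sessions with generator laterality means
    ordered L < H <= NL; the group comparison must detect NL vs L."""
    rng = np.random.default_rng(seed)
    lat = {}
    for k, cond in enumerate(("H", "NL", "L")):
        specs = condition_unit_specs(cond, n_units_per_group, rng)
        cfg = SimConfig(seed=int(rng.integers(2 ** 31)), condition=cond,
                        unit_specs=specs, emg_enabled=False, lfp_enabled=False)
        results = SessionAnalysis.from_simulation(cfg).fit()
        u = results.units
        lat[cond] = u.loc[u.functional_type == "Go",
                          "laterality_index"].dropna().to_numpy()
    r = group_compare("mannwhitney", [lat["NL"], lat["L"]])
    kw = group_compare("kruskal", [lat["H"], lat["NL"], lat["L"]],
                       labels=["H", "NL", "L"])
    return dict(
        p_nl_vs_l=float(r.pvalue),
        kruskal_p=float(kw.pvalue),
        mean_h=float(lat["H"].mean()),
        mean_nl=float(lat["NL"].mean()),
        mean_l=float(lat["L"].mean()),
        n=sum(len(v) for v in lat.values()),
    )
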