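"""Generator-level checks: determinism, task structure, rate recovery,
collision physics, EMG/LFP ground truth."""
import numpy as np
import pytest

from lateralize.simulate import (
    ConfigError,
    EmgParams,
    LfpParams,
    SimConfig,
    StimSpec,
    UnitSpec,
    make_trial_scaffold,
    simulate_emg,
    simulate_lfp,
    simulate_session,
    simulate_stimulation,
    simulate_unit_spikes,
    specs_for_true_index,
    true_laterality,
)
from lateralize.units import build_peth


def test_seeded_determinism():
    cfg = SimConfig(seed=7, n_trials_per_block=5, n_blocks=2,
                    stim_spec=StimSpec(n_control_events=5, n_test_events=5,
                                       n_ff_pairs=2))
    s1, t1 = simulate_session(cfg)
    s2, t2 = simulate_session(cfg)
    np.testing.assert_array_equal(s1.pedal.right_pos, s2.pedal.right_pos)
    for u1, u2 in zip(s1.units, s2.units):
        np.testing.assert_array_equal(u1.spike_times, u2.spike_times)
    for uid in s1.stim:
        for e1, e2 in zip(s1.stim[uid], s2.stim[uid]):
            np.testing.assert_array_equal(e1.snippets, e2.snippets)
    np.testing.assert_array_equal(s1.emg["right"].values, s2.emg["right"].values)
    np.testing.assert_array_equal(s1.lfp["M1"].values, s2.lfp["M1"].values)
    assert t1.trials.equals(t2.trials)


def test_session_structure():
    cfg = SimConfig(seed=3, n_trials_per_block=30, n_blocks=2, emg_enabled=False,
                    lfp_enabled=False)
    session, truth = simulate_session(cfg)
    assert len(truth.trials) >= 60
    assert set(truth.trials.block_side) == {"right", "left"}
    assert session.pedal.right_pos.min() >= 0
    assert session.pedal.right_pos.max() <= 100
    for u in session.units:
        assert np.all(np.diff(u.spike_times) > 0)


def test_invalid_configs_name_the_field():
    with pytest.raises(ConfigError, match="holding_time_range"):
        SimConfig(holding_time_range=(0.5, 3.0)).validate()
    with pytest.raises(ConfigError, match="baseline_rate"):
        SimConfig(unit_specs=[UnitSpec(baseline_rate=-1)]).validate()
    with pytest.raises(ConfigError, match="snippet_duration"):
        SimConfig(unit_specs=[UnitSpec(projection="PT", antidromic_latency=50.0)],
                  stim_spec=StimSpec()).validate()


def test_zero_rate_unit_emits_no_spikes():
    spec = UnitSpec(functional_type="untuned", baseline_rate=0.0,
                    peak_rate_contra=0.0, peak_rate_ipsi=0.0)
    rng = np.random.default_rng(0)
    trials = make_trial_scaffold(5, rng)
    assert simulate_unit_spikes(spec, trials, rng).size == 0


def test_refractory_enforced():
    spec = UnitSpec(functional_type="untuned", baseline_rate=80.0, refractory=2.0)
    rng = np.random.default_rng(0)
    spikes = simulate_unit_spikes(spec, [], rng, span=(0.0, 50.0))
    assert spikes.size > 100
    assert np.diff(spikes).min() >= 0.002 - 1e-12


def test_go_rate_recovery_oracle(scaffold60):
    """Trial-averaged PETH of a Go unit converges to the analytic profile:
    contra peak ~ baseline + amplitude, ipsi ~ baseline."""
    rng = np.random.default_rng(5)
    trials = make_trial_scaffold(300, rng, iti=0.8)
    spec = UnitSpec(functional_type="Go", baseline_rate=5.0,
                    peak_rate_contra=20.0, peak_rate_ipsi=0.0)
    spikes = simulate_unit_spikes(spec, trials, rng)
    contra = [t.release_onset for t in trials if t.side == "right"]
    ipsi = [t.release_onset for t in trials if t.side == "left"]
    p_c = build_peth(spikes, contra)
    p_i = build_peth(spikes, ipsi)
    # max of the analytic profile averaged over a 20-ms bin is ~ base + 0.97*A
    assert p_c.rate.max() == pytest.approx(5.0 + 20.0, rel=0.15)
    # ipsi PETH has no bump: its maximum stays within extreme-value range
    # of the flat baseline (75 bins of Poisson noise), far below base + A
    assert p_i.rate.max() < 5.0 + 0.5 * 20.0
    # ipsi mean tracks the flat baseline
    assert p_i.rate.mean() == pytest.approx(5.0, rel=0.15)


def test_hold_rate_span_tracks_holding(scaffold60):
    rng = np.random.default_rng(8)
    trials = make_trial_scaffold(200, rng)
    spec = UnitSpec(functional_type="Hold", baseline_rate=5.0,
                    peak_rate_contra=15.0, peak_rate_ipsi=15.0)
    spikes = simulate_unit_spikes(spec, trials, rng)
    long_t = [t for t in trials if t.holding_duration >= 2.5]
    peth = build_peth(spikes, [t.release_onset for t in long_t],
                      window=(-3.0, 0.5))
    centers = peth.bin_centers
    in_hold = (centers > -2.0) & (centers < -0.2)
    post = centers > 0.2
    assert peth.rate[in_hold].mean() == pytest.approx(20.0, rel=0.15)
    assert peth.rate[post].mean() == pytest.approx(5.0, rel=0.35)


def test_true_laterality_reduces_to_amplitude_contrast():
    spec = UnitSpec(functional_type="Go", baseline_rate=5.0,
                    peak_rate_contra=20.0, peak_rate_ipsi=5.0)
    c, i, idx = true_laterality(spec)
    assert idx == pytest.approx((20 - 5) / (20 + 5))
    specs = specs_for_true_index([0.6, -0.3, 0.0])
    for spec, tgt in zip(specs, [0.6, -0.3, 0.0]):
        assert true_laterality(spec)[2] == pytest.approx(tgt)


class TestStimulation:
    def _run(self, spec, seed=0, stim=None):
        stim = stim or StimSpec(n_control_events=60, n_test_events=60,
                                n_ff_pairs=0)
        rng = np.random.default_rng(seed)
        spikes = simulate_unit_spikes(spec, [], rng, span=(0.0, 400.0))
        sets = simulate_stimulation(stim, spec, spikes, rng, span=(0.0, 400.0))
        return {ev.mode: ev for ev in sets}, stim

    def _detect(self, ev, latency):
        # amplitude at the template trough per snippet
        k = np.argmin(np.abs(ev.snippet_times - latency))
        return ev.snippets[:, k] < -0.5

    def test_collision_suppresses_test_spikes(self):
        spec = UnitSpec(projection="PT", antidromic_latency=7.0,
                        antidromic_reliability=0.9)
        sets, _ = self._run(spec)
        p_ctrl = self._detect(sets["control"], 7.0).mean()
        p_test = self._detect(sets["test"], 7.0).mean()
        assert p_ctrl == pytest.approx(0.9, abs=0.12)
        assert p_test == 0.0

    def test_zero_reliability_no_spikes(self):
        spec = UnitSpec(projection="PT", antidromic_latency=7.0,
                        antidromic_reliability=0.0)
        sets, _ = self._run(spec)
        assert not self._detect(sets["control"], 7.0).any()

    def test_orthodromic_latency_jitters(self):
        spec = UnitSpec(projection="none", orthodromic_response=True,
                        antidromic_latency=8.0, antidromic_reliability=1.0,
                        orthodromic_jitter=1.0)
        sets, _ = self._run(spec)
        mask = (sets["control"].snippet_times > 4) & (sets["control"].snippet_times < 14)
        troughs = sets["control"].snippet_times[mask][
            np.argmin(sets["control"].snippets[:, mask], axis=1)]
        assert troughs.std() > 0.5

    def test_no_spontaneous_spike_before_control_events(self):
        spec = UnitSpec(projection="PT", antidromic_latency=7.0,
                        baseline_rate=20.0)
        rng = np.random.default_rng(1)
        spikes = simulate_unit_spikes(spec, [], rng, span=(0.0, 200.0))
        sets = simulate_stimulation(StimSpec(n_ff_pairs=0), spec, spikes, rng,
                                    span=(0.0, 200.0))
        ctrl = next(ev for ev in sets if ev.mode == "control")
        dead = (7.0 + 2.0) / 1000.0
        for t in ctrl.stim_times:
            k = np.searchsorted(spikes, t)
            assert k == 0 or t - spikes[k - 1] >= dead


class TestEmgLfp:
    def test_emg_ground_truth_onsets(self):
        rng = np.random.default_rng(0)
        trials = make_trial_scaffold(10, rng)
        emg = simulate_emg(trials, rng, (0.0, trials[-1].release_event + 2))
        for tr in trials:
            assert tr.emg_onset == pytest.approx(tr.release_onset - 0.250)
            trace = emg[tr.side]
            i0 = int((tr.emg_onset - trace.t0) * trace.sampling_rate)
            burst = np.abs(trace.values[i0:i0 + 1000]).mean()
            base = np.abs(trace.values[i0 - 2000:i0 - 1000]).mean()
            assert burst > 5 * base

    def test_zero_amplitude_burst_is_pure_noise(self):
        rng = np.random.default_rng(0)
        trials = make_trial_scaffold(5, rng)
        emg = simulate_emg(trials, rng, (0.0, trials[-1].release_event + 2),
                           EmgParams(burst_amplitude=1.0))
        v = emg["right"].values
        assert np.abs(v).mean() == pytest.approx(np.sqrt(2 / np.pi), rel=0.05)

    def test_shared_weight_one_gives_identical_areas(self):
        rng = np.random.default_rng(0)
        lfp = simulate_lfp(10.0, "H", rng, {"H": 0.3},
                           LfpParams(shared_weight=1.0))
        np.testing.assert_allclose(lfp["M1"].values, lfp["M2"].values)

    def test_beta_power_scales_quadratically(self):
        """Parseval oracle on the pure sinusoid: power = A^2/2."""
        from lateralize.signals import lfp_segments, power_spectrum

        rng = np.random.default_rng(0)
        band = []
        for amp in (0.4, 0.8):
            lfp = simulate_lfp(30.0, "H", rng, {"H": amp},
                               LfpParams(background_sd=0.0))
            segs, _ = lfp_segments(lfp["M1"], np.arange(2, 28, 2.5),
                                   do_rectify=False)
            band.append(power_spectrum(segs).band_power)
        assert band[1] / band[0] == pytest.approx(4.0, rel=0.05)
        assert band[0] == pytest.approx(0.4 ** 2 / 2, rel=0.1)

    def test_zero_beta_leaves_background_level(self):
        from lateralize.signals import lfp_segments, power_spectrum

        rng = np.random.default_rng(0)
        lfp0 = simulate_lfp(30.0, "H", rng, {"H": 0.0})
        segs, _ = lfp_segments(lfp0["M1"], np.arange(2, 28, 2.5),
                               do_rectify=False)
        bp0 = power_spectrum(segs).band_power
        total = np.sum(power_spectrum(segs).power) * 0.5
        assert bp0 < 0.5 * total  # beta band holds a minority of pink power
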