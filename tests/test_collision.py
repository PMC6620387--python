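"""Antidromic collision-test pipeline: window, ROC cutoff, probabilities,
chi-square, latency/jitter, frequency-following, class assignment."""
import math

import numpy as np
import pytest

from lateralize.collision import (
    CollisionResult,
    assign_projection,
    chi2_statistic,
    collision_chi2,
    collision_test,
    detection_window,
    eligibility,
    frequency_following,
    identify_units,
    latency_jitter,
    min_amplitudes,
    roc_cutoff,
    spike_probabilities,
)
from lateralize.simulate import (
    StimSpec,
    UnitSpec,
    simulate_stimulation,
    simulate_unit_spikes,
)


def _unit_sets(spec, seed=0, stim=None):
    stim = stim or StimSpec()
    rng = np.random.default_rng(seed)
    spikes = simulate_unit_spikes(spec, [], rng, span=(0.0, 400.0))
    sets = simulate_stimulation(stim, spec, spikes, rng, span=(0.0, 400.0))
    return {ev.mode: ev for ev in sets}


class TestDetectionWindow:
    def test_window_contains_injected_latency(self):
        sets = _unit_sets(UnitSpec(projection="PT", antidromic_latency=7.0))
        w = detection_window(sets["control"].snippets, sets["test"].snippets,
                             sets["control"].snippet_times)
        assert w is not None
        assert w[0] <= 7.0 <= w[1]

    def test_pure_noise_no_window(self):
        rng = np.random.default_rng(0)
        t = np.arange(400) / 20.0
        a = rng.normal(0, 0.08, (50, 400))
        b = rng.normal(0, 0.08, (50, 400))
        assert detection_window(a, b, t) is None

    def test_earliest_lobe_chosen(self):
        """Two divergence lobes: the window tracks the earlier one
        (brute-force divergence scan oracle)."""
        t = np.arange(600) / 20.0
        a = np.zeros((20, 600))
        b = np.zeros((20, 600))
        a[:, 100:110] = -1.0  # lobe at 5.0 ms
        a[:, 400:410] = -1.0  # lobe at 20.0 ms
        b += np.random.default_rng(1).normal(0, 0.05, b.shape)
        w = detection_window(a, b, t)
        assert w[0] <= 5.0 <= w[1]
        assert w[1] < 15.0


class TestRocCutoff:
    def test_separated_distributions(self):
        spike = np.array([-1.0, -0.9, -1.1])
        nospike = np.array([-0.1, -0.2, 0.0])
        thr = roc_cutoff(spike, nospike)
        assert -0.9 < thr < -0.2
        assert (spike < thr).all() and not (nospike < thr).any()

    def test_identical_distributions_warn(self):
        x = np.array([-0.5, -0.4, -0.3])
        with pytest.warns(UserWarning):
            thr = roc_cutoff(x, x.copy())
        assert thr == pytest.approx(-0.4)

    def test_gaussian_dprime_4_misclassification(self):
        """Gaussian overlap-integral oracle: d'=4 -> error ~ Phi(-2) = 2.3%
        per class at the optimal threshold."""
        rng = np.random.default_rng(0)
        spike = rng.normal(-1.0, 0.25, 4000)
        nospike = rng.normal(0.0, 0.25, 4000)
        thr = roc_cutoff(spike, nospike)
        err = 0.5 * ((spike >= thr).mean() + (nospike < thr).mean())
        assert err <= 0.025


class TestProbabilitiesAndEligibility:
    def test_counts_and_fractions(self):
        sets = _unit_sets(UnitSpec(projection="PT", antidromic_latency=7.0,
                                   antidromic_reliability=0.9))
        w = (6.0, 8.5)
        amps_c = min_amplitudes(sets["control"].snippets,
                                sets["control"].snippet_times, w)
        amps_t = min_amplitudes(sets["test"].snippets,
                                sets["test"].snippet_times, w)
        cutoff = roc_cutoff(amps_c, amps_t)
        p_c, p_t, counts = spike_probabilities(sets["control"], sets["test"],
                                               w, cutoff)
        assert counts.sum() == 100
        assert p_c == pytest.approx(0.9, abs=0.12)
        assert p_t < 0.1

    @pytest.mark.parametrize("pc,pt,expected", [
        (0.9, 0.1, True),
        (0.4, 0.0, False),  # control probability below 50%
        (0.9, 0.5, False),  # test probability not below half of control
        (0.5, 0.24, True),
    ])
    def test_eligibility_rule(self, pc, pt, expected):
        assert eligibility(pc, pt) is expected


class TestCollisionChi2:
    def test_closed_form_64(self):
        counts = np.array([[45, 5], [5, 45]])
        assert chi2_statistic(counts) == pytest.approx(64.0)
        p, ok = collision_chi2(counts)
        assert ok and p < 1e-10

    def test_balanced_table_fails(self):
        p, ok = collision_chi2(np.array([[25, 25], [25, 25]]))
        assert not ok and p == pytest.approx(1.0)

    def test_chi2_4_passes_marginally(self):
        counts = np.array([[30, 20], [20, 30]])
        assert chi2_statistic(counts) == pytest.approx(4.0)
        p, ok = collision_chi2(counts)
        assert p == pytest.approx(0.0455, abs=0.001)
        assert ok

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            collision_chi2(np.array([[0, 0], [10, 10]]))

    def test_p_ordering_matches_exact_enumeration(self):
        """Fisher-style enumeration oracle: for 2x2 tables with fixed
        margins (N <= 40), chi-square p-values order the tables exactly as
        the exact hypergeometric tail probabilities do."""
        r1 = r2 = c1 = 20  # margins; a ranges over its support

        def fisher_exact_p(a):
            # hypergeometric enumeration over all tables with these margins
            def prob(x):
                return (math.comb(r1, x) * math.comb(r2, c1 - x)
                        / math.comb(r1 + r2, c1))
            p_obs = prob(a)
            return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
                       if prob(x) <= p_obs + 1e-12)

        tables = range(10, 21)
        chi_ps = []
        exact_ps = []
        for a in tables:
            t = np.array([[a, r1 - a], [c1 - a, r2 - (c1 - a)]])
            chi_ps.append(collision_chi2(t)[0])
            exact_ps.append(fisher_exact_p(a))
        assert np.argsort(chi_ps).tolist() == np.argsort(exact_ps).tolist()


class TestLatencyJitter:
    def test_constant_peaks(self):
        lat, jit, ok = latency_jitter([7.0] * 6)
        assert (lat, jit, ok) == (7.0, 0.0, True)

    def test_uniform_spread_fails(self):
        """Uniform quantile closed form: IQR of evenly spaced [6, 9] ms
        points is 1.5 ms > 0.5 ms."""
        peaks = np.linspace(6.0, 9.0, 13)
        lat, jit, ok = latency_jitter(peaks)
        assert lat == pytest.approx(7.5)
        assert jit == pytest.approx(1.5)
        assert not ok

    def test_tight_quartet_passes(self):
        lat, jit, ok = latency_jitter([6.9, 7.0, 7.0, 7.1])
        assert lat == pytest.approx(7.0)
        assert jit <= 0.2 and ok

    def test_too_few_peaks_undefined(self):
        lat, jit, ok = latency_jitter([7.0, 7.1])
        assert math.isnan(lat) and not ok


class TestFrequencyFollowing:
    def test_faithful_following_passes(self):
        sets = _unit_sets(UnitSpec(projection="PT", antidromic_latency=7.0,
                                   antidromic_reliability=1.0))
        ok = frequency_following([sets["ff100"], sets["ff200"]],
                                 (6.0, 8.5), -0.5)
        assert ok is True

    def test_failed_second_pulse_fails(self):
        spec = UnitSpec(projection="PT", antidromic_latency=7.0,
                        antidromic_reliability=1.0, ff_follow_reliability=0.0)
        sets = _unit_sets(spec)
        ok = frequency_following([sets["ff100"], sets["ff200"]],
                                 (6.0, 8.5), -0.5)
        assert ok is False

    def test_no_pairs_skips(self):
        assert frequency_following([], (6.0, 8.5), -0.5) is None


class TestAssignment:
    def _res(self, site, passed):
        return CollisionResult(unit_id="u", site=site, passed=passed)

    def test_pons_pass_is_pt(self):
        a = assign_projection("u", [self._res("ipsilateral_pons", True)])
        assert a.projection_class == "PT"

    def test_cortex_pass_pons_fail_is_it(self):
        a = assign_projection("u", [self._res("contralateral_cortex", True),
                                    self._res("ipsilateral_pons", False)])
        assert a.projection_class == "IT"

    def test_dual_pass_is_conflict(self):
        a = assign_projection("u", [self._res("contralateral_cortex", True),
                                    self._res("ipsilateral_pons", True)])
        assert a.projection_class == "unidentified"
        assert a.conflict


class TestEndToEnd:
    def test_small_population_identified(self):
        sets = {}
        true = {}
        for k in range(12):
            if k < 4:
                spec = UnitSpec(projection="IT", antidromic_latency=11.7)
            elif k < 8:
                spec = UnitSpec(projection="PT", antidromic_latency=6.9)
            else:
                spec = UnitSpec(projection="none", orthodromic_response=True,
                                antidromic_latency=9.0)
            uid = f"u{k}"
            true[uid] = spec.projection
            rng = np.random.default_rng(500 + k)
            spikes = simulate_unit_spikes(spec, [], rng, span=(0.0, 300.0))
            sets[uid] = simulate_stimulation(StimSpec(), spec, spikes, rng,
                                             span=(0.0, 300.0))
        res = identify_units(sets)
        for uid, pa in res.items():
            if true[uid] == "none":
                assert pa.projection_class == "unidentified"
            else:
                assert pa.projection_class == true[uid]

    def test_collision_result_fields(self):
        sets = _unit_sets(UnitSpec(projection="PT", antidromic_latency=6.9,
                                   antidromic_reliability=0.9))
        res = collision_test(sets["control"], sets["test"],
                             ff_sets=[sets["ff100"], sets["ff200"]])
        assert res.passed and res.eligible
        assert res.latency == pytest.approx(6.9, abs=0.5)
        assert res.jitter <= 0.5
        assert res.chi2_p < 0.05
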