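"""Unit/LFP metrics: smoothing, z-scoring, tuning, oddball, oscillation.

Oracles: unit-area kernel identities, hand-computed z-scores, planted
Gaussian tuning curves, constructed peak configurations, and the exact
dB value of an amplitude doubling (+6.02 dB).
"""

import numpy as np
import pandas as pd
import pytest

from v1stp.synth import (
    ORIENTATIONS_DEG,
    SpikeSessionSpec,
    expected_rate,
    generate_spike_session,
)
from v1stp.units import (
    UnitSession,
    baseline_z,
    gaussian_rate,
    layer4_lfp_select,
    morlet_cycles,
    morlet_power_db,
    oddball_metrics,
    orientation_tuning,
    oscillation_peaks_frequency,
    select_good_units,
)


class TestGaussianRate:
    def test_single_spike_integrates_to_one(self):
        t, r = gaussian_rate([0.5], n_trials=1, t_start_s=0.0, t_end_s=1.0)
        assert np.sum(r) * 1e-3 == pytest.approx(1.0, abs=1e-3)
        assert t[np.argmax(r)] == pytest.approx(0.5, abs=2e-3)

    def test_homogeneous_plateau(self):
        rng = np.random.default_rng(0)
        n_trials, rate_hz, dur = 1000, 10.0, 2.0
        n = rng.poisson(rate_hz * dur * n_trials)
        spikes = rng.uniform(0.0, dur, size=n)
        t, r = gaussian_rate(spikes, n_trials, 0.0, dur)
        interior = (t > 0.2) & (t < 1.8)
        # smoothed per-point SD ~ sqrt(rate/(n_trials*dt)/(2*sqrt(pi)*sigma_bins)) ~ 0.24 Hz
        assert abs(r[interior].mean() - rate_hz) < 0.1
        assert np.max(np.abs(r[interior] - rate_hz)) < 1.0

    def test_shift_equivariance(self):
        # spikes at bin centers so float edge rounding can't move them
        spikes = np.array([0.1005, 0.3005, 0.3505, 0.9005])
        t1, r1 = gaussian_rate(spikes, 2, 0.0, 1.0)
        t2, r2 = gaussian_rate(spikes + 0.3, 2, 0.3, 1.3)
        n = min(len(r1), len(r2))
        np.testing.assert_allclose(r1[:n], r2[:n], atol=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            gaussian_rate([0.5], 1, 0.0, 1.0, sigma_ms=0.0)
        with pytest.raises(ValueError):
            gaussian_rate([0.5], 0, 0.0, 1.0)


class TestBaselineZ:
    def test_hand_computed(self):
        time = np.array([-0.15, -0.05, 0.05])
        rate = np.array([1.0, 3.0, 4.0])   # baseline mean 2, SD 1
        z = baseline_z(rate, time)
        np.testing.assert_allclose(z, [-1.0, 1.0, 2.0])

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        time = np.arange(-0.5, 1.5, 1e-3)
        rate = rng.uniform(1, 10, len(time))
        z1 = baseline_z(rate, time)
        z2 = baseline_z(3.0 * rate + 7.0, time)
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_zero_sd_rejected(self):
        time = np.arange(-0.5, 0.5, 1e-3)
        with pytest.raises(ZeroDivisionError):
            baseline_z(np.ones(len(time)), time)

    def test_no_baseline_samples(self):
        with pytest.raises(ValueError):
            baseline_z(np.ones(5), np.linspace(0.1, 0.5, 5))


class TestGoodUnits:
    def test_strict_threshold(self):
        spikes = pd.DataFrame({"unit_id": [0, 1, 2], "trial_id": [0, 0, 0],
                               "time_s": [0.1, 0.2, 0.3]})
        trials = pd.DataFrame({"trial_id": [0], "condition": ["a"],
                               "onset_s": [0.0]})
        meta = pd.DataFrame({"unit_id": [0, 1, 2],
                             "mean_rate_hz": [0.6, 0.5, 0.4]})
        sess = select_good_units(UnitSession(spikes, trials, meta))
        assert list(sess.unit_meta["unit_id"]) == [0]
        assert set(sess.spikes["unit_id"]) == {0}


class TestTuning:
    def test_one_hot_osi_one(self):
        res = orientation_tuning([1, 0, 0, 0, 0, 0], ORIENTATIONS_DEG)
        assert res.preferred_deg == 15.0
        assert res.osi == 1.0

    def test_uniform_osi_zero(self):
        res = orientation_tuning(np.full(6, 2.5), ORIENTATIONS_DEG)
        assert res.osi == 0.0

    def test_osi_scale_invariant(self):
        r = np.array([5.0, 3.0, 1.0, 0.5, 1.0, 3.0])
        a = orientation_tuning(r, ORIENTATIONS_DEG)
        b = orientation_tuning(10.0 * r, ORIENTATIONS_DEG)
        assert a.osi == pytest.approx(b.osi, abs=1e-12)

    def test_all_zero_osi_undefined(self):
        assert orientation_tuning(np.zeros(6), ORIENTATIONS_DEG).osi is None

    def test_planted_gaussian_recovered(self):
        angles = np.asarray(ORIENTATIONS_DEG)
        pref = 75.0
        d = np.abs((angles - pref + 90.0) % 180.0 - 90.0)
        r = 1.0 + 2.0 * np.exp(-d ** 2 / (2 * 30.0 ** 2))
        res = orientation_tuning(r, ORIENTATIONS_DEG)
        assert res.preferred_deg == pref
        assert res.good_fit and res.r2 > 0.95
        assert abs(res.gauss[1]) < 0.5   # peak at normalized index 0

    def test_validation(self):
        with pytest.raises(ValueError):
            orientation_tuning([1, 2, 3], ORIENTATIONS_DEG[:3])
        with pytest.raises(ValueError):
            orientation_tuning([1, 2, 3, 4, 5, np.nan], ORIENTATIONS_DEG)


class TestOddball:
    def test_window_assignment(self):
        time = np.arange(-0.2, 1.0, 1e-3)
        flat = np.ones(len(time))
        deviant = flat.copy()
        deviant[(time >= 0.09) & (time < 0.11)] = 10.0  # early bump only
        m = oddball_metrics({"control": flat, "redundant": flat,
                             "deviant": deviant}, time)
        assert m["mismatch_deviant_peak"] == 1.0   # bump outside [0.2, 0.5)
        assert m["adaptation_control_peak"] == 1.0
        late = flat.copy()
        late[(time >= 0.54) & (time < 0.56)] = 10.0  # outside [0, 0.5)
        m2 = oddball_metrics({"control": late, "redundant": flat,
                              "deviant": flat}, time)
        assert m2["adaptation_control_peak"] == 1.0

    def test_missing_condition(self):
        time = np.arange(0, 1, 1e-3)
        with pytest.raises(ValueError):
            oddball_metrics({"control": np.ones(1000)}, time)

    def test_expected_rate_null_when_deviant_gain_one(self):
        spec = SpikeSessionSpec(mode="oddball", deviant_gain=1.0)
        t = np.arange(-0.5, 1.5, 1e-3)
        rates = {c: expected_rate(spec, t, c)
                 for c in ("control", "redundant", "deviant")}
        m = oddball_metrics(rates, t)
        assert m["mismatch_deviant_peak"] == m["mismatch_redundant_peak"]

    def test_planted_adaptation_and_mismatch_recovered(self):
        """Sampled oddball sessions reproduce the planted ordering for
        >= 95% of units (adaptation 0.6, deviant gain 1.5)."""
        spec = SpikeSessionSpec(mode="oddball", n_units=20,
                                trials_per_condition=50, seed=4)
        sess = generate_spike_session(spec)
        merged = sess.spikes.merge(sess.trials, on="trial_id")
        t = np.arange(-0.5, 1.5, 1e-3) + 5e-4
        n_adapt, n_mismatch = 0, 0
        n_by_cond = sess.trials["condition"].value_counts()
        for u in range(spec.n_units):
            rates = {}
            for c in ("control", "redundant", "deviant"):
                sel = merged[(merged["unit_id"] == u)
                             & (merged["condition"] == c)]
                _, rates[c] = gaussian_rate(sel["time_s"].to_numpy(),
                                            int(n_by_cond[c]), -0.5, 1.5)
            m = oddball_metrics(rates, t[: len(rates["control"])])
            n_adapt += (m["adaptation_control_peak"]
                        > m["adaptation_redundant_peak"])
            n_mismatch += (m["mismatch_deviant_peak"]
                           > m["mismatch_redundant_peak"])
        assert n_adapt >= 19
        assert n_mismatch >= 19


class TestOscillation:
    def test_pure_sinusoid_frequency(self):
        t = np.arange(0.0, 2.0, 1e-3)
        z = np.sin(2 * np.pi * 5.0 * t)
        res = oscillation_peaks_frequency(z, t)
        assert res.frequency_hz == pytest.approx(5.0, abs=0.01)
        assert res.n_peaks == 10
        # constraints hold on the output itself
        assert np.all(np.diff(res.peak_times_s) >= 0.1)
        assert np.all(z[np.searchsorted(t, res.peak_times_s)] >= 0.5)

    def test_small_amplitude_no_peaks(self):
        t = np.arange(0.0, 2.0, 1e-3)
        res = oscillation_peaks_frequency(0.3 * np.sin(2 * np.pi * 5 * t), t)
        assert res.n_peaks == 0 and res.frequency_hz is None

    def test_greedy_suppression(self):
        """Bumps at 0.2 s (1.0), 0.35 s (0.9) and 0.25 s (0.6): the lower
        bump 50 ms from the largest is suppressed; freq = 1/0.15."""
        t = np.arange(0.0, 0.6, 1e-3)

        def bump(c, a):
            return a * np.exp(-((t - c) ** 2) / (2 * 0.01 ** 2))

        z = bump(0.2, 1.0) + bump(0.35, 0.9) + bump(0.25, 0.6)
        res = oscillation_peaks_frequency(z, t)
        assert res.n_peaks == 2
        np.testing.assert_allclose(res.peak_times_s, [0.2, 0.35], atol=5e-3)
        assert res.frequency_hz == pytest.approx(1.0 / 0.15, rel=0.05)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            oscillation_peaks_frequency(np.ones(5), np.ones(4))

    def test_population_frequency_recovered_by_genotype(self):
        """Planted 5 Hz (WT-like) vs 4 Hz (KO-like) familiarity
        oscillations are recovered from pooled population rates."""
        for freq in (5.0, 4.0):
            spec = SpikeSessionSpec(mode="familiarity", n_units=10,
                                    trials_per_condition=300,
                                    osc_freq_hz=freq, seed=int(freq))
            sess = generate_spike_session(spec)
            t, r = gaussian_rate(sess.spikes["time_s"].to_numpy(),
                                 n_trials=spec.trials_per_condition
                                 * spec.n_units,
                                 t_start_s=-0.5, t_end_s=1.5, sigma_ms=20.0)
            z = baseline_z(r, t)
            post = t >= 0.25   # skip the stimulus transient
            res = oscillation_peaks_frequency(z[post], t[post])
            assert res.frequency_hz == pytest.approx(freq, abs=0.5)


class TestLFP:
    def test_layer4_selection(self):
        t = np.arange(0.0, 0.3, 1e-3)
        lfp = np.zeros((3, len(t)))
        depths = np.array([200.0, 400.0, 600.0])
        lfp[1, 100] = -5.0    # in range, in window
        lfp[2, 100] = -50.0   # larger but out of depth range
        assert layer4_lfp_select(lfp, depths, t) == 1

    def test_out_of_window_deflection_ignored(self):
        t = np.arange(0.0, 0.3, 1e-3)
        lfp = np.zeros((2, len(t)))
        depths = np.array([350.0, 450.0])
        lfp[0, 250] = -50.0   # 250 ms: outside [50, 150) ms
        lfp[1, 100] = -1.0
        assert layer4_lfp_select(lfp, depths, t) == 1

    def test_no_channel_in_range(self):
        t = np.arange(0.0, 0.3, 1e-3)
        with pytest.raises(ValueError):
            layer4_lfp_select(np.zeros((2, len(t))),
                              np.array([100.0, 700.0]), t)

    def test_morlet_cycles_endpoints(self):
        c = morlet_cycles(np.array([0.5, 80.0]))
        np.testing.assert_allclose(c, [2.0, 22.0])

    def test_morlet_db_of_amplitude_doubling(self):
        """Doubling a sinusoid's amplitude gives +10*log10(4) = 6.02 dB."""
        fs = 250.0
        t = np.arange(0.0, 2.5, 1 / fs)
        amp = np.where(t >= 1.25, 2.0, 1.0)
        x = amp * np.sin(2 * np.pi * 20.0 * t)
        freqs, db = morlet_power_db(x[np.newaxis, :], fs, onset_s=1.0,
                                    freqs_hz=np.array([20.0]))
        i_pre = int(round(0.8 * fs))
        i_post = int(round(1.6 * fs))
        assert db[0, i_pre] == pytest.approx(0.0, abs=0.3)
        assert db[0, i_post] == pytest.approx(10 * np.log10(4.0), abs=0.3)

    def test_morlet_requires_baseline_coverage(self):
        fs = 250.0
        x = np.random.default_rng(0).normal(size=(1, 500))
        with pytest.raises(ValueError):
            morlet_power_db(x, fs, onset_s=0.1)
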