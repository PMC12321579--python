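import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iedtools.coupling import (
    CCGResult,
    ccg_brute_force,
    ccg_convolution,
    classify_independent,
    composite_responsiveness,
    coupling_modulation,
    fit_occurrence_trajectories,
    gabor_spectrogram,
    independence_matrix,
    mann_kendall,
    multitaper_coherence,
    occurrence_rate,
    spindle_band_power,
)
from iedtools.types import EventSeries, StateIntervals

from conftest import make_noise_bundle


class TestCCG:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        ref = np.sort(rng.uniform(0, 600, 50))
        tgt = np.sort(rng.uniform(0, 600, 80))
        res = ccg_convolution(ref, tgt)
        np.testing.assert_array_equal(res.counts, ccg_brute_force(ref, tgt))

    def test_shifted_train_single_peak(self):
        rng = np.random.default_rng(1)
        ref = np.sort(rng.uniform(10, 590, 100))
        res = ccg_convolution(ref, ref + 0.15)
        peak_lag = res.lags_s[np.argmax(res.counts)]
        assert peak_lag == pytest.approx(0.15, abs=1e-9)
        assert res.counts.max() >= 100

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        ref = np.sort(rng.uniform(0, 300, 40))
        tgt = np.sort(rng.uniform(0, 300, 60))
        ab = ccg_convolution(ref, tgt)
        ba = ccg_convolution(tgt, ref)
        np.testing.assert_array_equal(ab.counts, ba.counts[::-1])

    def test_conservation(self):
        rng = np.random.default_rng(3)
        ref = np.sort(rng.uniform(0, 100, 30))
        tgt = np.sort(rng.uniform(0, 100, 30))
        res = ccg_convolution(ref, tgt)
        pairs = sum(
            1 for r in ref for t in tgt if abs(t - r) <= 1.0 + res.bin_s / 2 - 1e-12
        )
        assert res.counts.sum() == pairs

    def test_ci_brackets_baseline(self):
        rng = np.random.default_rng(4)
        ref = np.sort(rng.uniform(0, 3600, 400))
        tgt = np.sort(rng.uniform(0, 3600, 400))
        res = ccg_convolution(ref, tgt)
        assert np.all(res.ci_low <= res.baseline_b + 1e-9)
        assert np.all(res.baseline_b <= res.ci_high + 1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ccg_convolution(np.empty(0), np.array([1.0]))

    def test_few_refs_warn(self):
        with pytest.warns(UserWarning, match="reference events"):
            ccg_convolution(np.arange(5.0), np.arange(5.0) + 0.1)

    def test_translation_invariance_of_m(self):
        rng = np.random.default_rng(5)
        ref = np.sort(rng.uniform(10, 1990, 200))
        tgt = np.sort(np.r_[ref + 0.02, rng.uniform(0, 2000, 400)])
        m1 = coupling_modulation(ccg_convolution(ref, tgt))
        m2 = coupling_modulation(ccg_convolution(ref + 123.4, tgt + 123.4))
        assert m1 == pytest.approx(m2)


class TestCouplingModulation:
    @staticmethod
    def fake_ccg(counts, baseline):
        counts = np.asarray(counts, float)
        baseline = np.asarray(baseline, float)
        from scipy import stats

        k = counts.size // 2
        return CCGResult(
            bin_s=0.01,
            lags_s=np.arange(-k, k + 1) * 0.01,
            counts=counts,
            baseline_b=baseline,
            ci_low=stats.poisson.ppf(0.025, baseline),
            ci_high=stats.poisson.ppf(0.975, baseline),
            n_ref=100,
            n_tgt=100,
        )

    def test_a_equals_b_gives_zero(self):
        ccg = self.fake_ccg([4, 4, 4, 4, 4], [4.0] * 5)
        assert coupling_modulation(ccg) == 0.0

    def test_a_twice_b_gives_one(self):
        ccg = self.fake_ccg([4, 4, 20, 4, 4], [10.0] * 5)
        assert coupling_modulation(ccg) == pytest.approx(1.0)

    def test_degenerate_baseline_raises(self):
        ccg = self.fake_ccg([0, 0, 5, 0, 0], [0.0] * 5)
        with pytest.raises(ValueError, match="degenerate"):
            coupling_modulation(ccg)

    def test_m_never_negative_at_default(self):
        ccg = self.fake_ccg([1, 1, 1, 1, 1], [10.0] * 5)
        assert coupling_modulation(ccg) == 0.0


class TestIndependence:
    def test_identical_series_fraction_zero(self):
        t = np.arange(10.0)
        flags, frac = classify_independent(t, t)
        assert frac == 0.0 and not flags.any()

    def test_shifted_series_fraction_one(self):
        t = np.arange(10.0)
        flags, frac = classify_independent(t + 0.2, t)
        assert frac == 1.0 and flags.all()

    def test_constructed_mixture_exact(self):
        ref = np.arange(0.0, 100.0, 1.0)
        near = ref[:70] + 0.05
        far = ref[70:] + 0.5
        tgt = np.sort(np.r_[near, far])
        _, frac = classify_independent(tgt, ref)
        assert frac == pytest.approx(0.3)

    @given(radius=st.floats(min_value=0.01, max_value=0.5))
    @settings(max_examples=25, deadline=None)
    def test_flags_depend_only_on_nearest_distance(self, radius):
        rng = np.random.default_rng(0)
        ref = np.sort(rng.uniform(0, 50, 20))
        tgt = np.sort(rng.uniform(0, 50, 30))
        flags, _ = classify_independent(tgt, ref, radius)
        nearest = np.array([np.min(np.abs(ref - t)) for t in tgt])
        np.testing.assert_array_equal(flags, nearest > radius)

    def test_matrix_examples(self):
        soz = np.arange(0.0, 50.0, 1.0)
        same = soz.copy()
        disjoint = soz + 0.5
        half = np.r_[soz[:25] + 0.05, soz[25:] + 0.5]
        table = independence_matrix(
            {"soz": soz, "same": same, "far": disjoint, "half": np.sort(half)}, "soz"
        )
        assert table["soz"] == 0.0
        assert table["same"] == 0.0
        assert table["far"] == 1.0
        assert table["half"] == pytest.approx(0.5)

    def test_matrix_unknown_soz(self):
        with pytest.raises(KeyError):
            independence_matrix({"a": np.arange(3.0), "b": np.arange(3.0)}, "c")


class TestOccurrenceRate:
    states = StateIntervals([(0.0, 1800.0, "NREM")])

    def test_rate(self):
        times = np.linspace(1, 1799, 60)
        assert occurrence_rate(times, self.states) == pytest.approx(2.0)

    def test_empty_series(self):
        assert occurrence_rate(np.empty(0), self.states) == 0.0

    def test_events_outside_state(self):
        s = StateIntervals([(0.0, 60.0, "WAKE"), (60.0, 120.0, "NREM")])
        times = np.array([10.0, 20.0, 30.0])
        assert occurrence_rate(times, s, "NREM") == 0.0

    def test_zero_state_time_raises(self):
        with pytest.raises(ValueError):
            occurrence_rate(np.array([1.0]), StateIntervals([]), "NREM")


class TestGabor:
    def test_pure_tone_peak_frequency(self):
        fs = 1250.0
        t = np.arange(0, 10, 1 / fs)
        x = np.sin(2 * np.pi * 13.0 * t)
        freqs = np.arange(5.0, 30.0, 1.0)
        p = gabor_spectrogram(x, fs, freqs)
        interior = slice(int(2 * fs), int(8 * fs))
        argmax = freqs[np.argmax(p[:, interior], axis=0)]
        assert np.all(np.abs(argmax - 13.0) <= 1.0)

    def test_zero_signal(self):
        p = gabor_spectrogram(np.zeros(1000), 1250.0, [10.0, 20.0])
        assert np.all(p == 0.0)

    def test_power_matches_band_variance(self):
        from scipy.signal import butter, sosfiltfilt

        fs = 1250.0
        rng = np.random.default_rng(0)
        sos = butter(4, [12, 14], btype="bandpass", fs=fs, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(int(20 * fs)))
        p = gabor_spectrogram(x, fs, [13.0])
        interior = slice(int(2 * fs), int(18 * fs))
        assert p[0, interior].mean() == pytest.approx(x[interior].var(), rel=0.1)

    def test_nyquist_rejected(self):
        with pytest.raises(ValueError):
            gabor_spectrogram(np.zeros(100), 1250.0, [700.0])


class TestSpindleBandPower:
    def test_random_windows_zero_mean(self, quiet_session):
        rng = np.random.default_rng(0)
        wins = [(s, s + 1.0) for s in rng.uniform(5, 290, 100)]
        z = spindle_band_power(quiet_session, "mpfc0", wins)
        assert abs(z.mean()) < 0.25

    def test_spindle_windows_elevated(self, default_session):
        gt = default_session.ground_truth.events["spindle_mpfc"]
        wins = [(ev.start_s, ev.start_s + 1.0) for ev in gt][:50]
        z = spindle_band_power(default_session, "mpfc0", wins)
        assert z.mean() > 1.0

    def test_short_window_raises(self, quiet_session):
        with pytest.raises(ValueError, match="shorter"):
            spindle_band_power(quiet_session, "mpfc0", [(10.0, 10.1)])


class TestCoherence:
    def test_identical_channels_unit_coherence(self):
        b = make_noise_bundle(n_channels=1, duration_s=300.0)
        b.lfp = np.column_stack([b.lfp[:, 0], b.lfp[:, 0]])
        b.meta.channels = [b.meta.channels[0], type(b.meta.channels[0])("ch1", "MPFC", "LFP", 0.2)]
        res = multitaper_coherence(b, "ch0", "ch1", n_segments=20)
        assert np.all(np.abs(res.coherence - 1.0) < 1e-6)

    def test_shared_tone_peaks_at_tone(self):
        fs = 1250.0
        dur = 400.0
        rng = np.random.default_rng(1)
        t = np.arange(0, dur, 1 / fs)
        tone = 20 * np.sin(2 * np.pi * 10.0 * t)
        b = make_noise_bundle(n_channels=2, duration_s=dur, seed=2)
        b.lfp[:, 0] += tone
        b.lfp[:, 1] += tone
        res = multitaper_coherence(b, "ch0", "ch1", n_segments=30, seed=0)
        c10 = res.coherence[np.argmin(np.abs(res.freqs_hz - 10.0))]
        c40 = res.coherence[np.argmin(np.abs(res.freqs_hz - 40.0))]
        assert c10 > c40

    def test_too_few_segments_raises(self):
        b = make_noise_bundle(duration_s=30.0)
        with pytest.raises(ValueError, match="5"):
            multitaper_coherence(b, "ch0", "ch1")

    def test_seeded_selection_deterministic(self):
        b = make_noise_bundle(duration_s=1500.0)
        r1 = multitaper_coherence(b, "ch0", "ch1", n_segments=50, seed=3)
        r2 = multitaper_coherence(b, "ch0", "ch1", n_segments=50, seed=3)
        np.testing.assert_array_equal(r1.coherence, r2.coherence)

    def test_normalization_mean_one(self):
        b = make_noise_bundle(duration_s=600.0)
        res = multitaper_coherence(
            b, "ch0", "ch1", n_segments=30, normalization="MEAN_1_100"
        )
        assert res.coherence.mean() == pytest.approx(1.0)


class TestMannKendall:
    def test_increasing_series(self):
        tau, p = mann_kendall(np.arange(10.0))
        assert tau == 1.0
        assert p < 0.01

    def test_constant_series(self):
        tau, _ = mann_kendall(np.ones(8))
        assert tau == 0.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            mann_kendall([1.0, 2.0, 3.0])

    def test_exact_matches_normal_approx_roughly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=9)
        tau, p = mann_kendall(x)
        assert 0.0 <= p <= 1.0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None)
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        tau_f, p_f = mann_kendall(x)
        tau_r, p_r = mann_kendall(x[::-1])
        assert tau_f == pytest.approx(-tau_r)
        assert p_f == pytest.approx(p_r)


class TestTrajectories:
    def test_identical_series(self):
        y = [0.1, 0.5, 1.2, 2.5, 4.1, 6.0, 8.5, 11.0, 14.0, 17.5]
        res = fit_occurrence_trajectories({"a": y, "b": list(y)})
        pair = res["pairwise"][("a", "b")]
        assert pair["F"] == pytest.approx(0.0, abs=1e-9)
        assert pair["p"] == pytest.approx(1.0)

    def test_noiseless_cubic_recovered(self):
        x = np.arange(12.0)
        coef = [0.02, -0.3, 1.5, 2.0]
        y = np.polyval(coef, x)
        res = fit_occurrence_trajectories({"a": y, "b": y * 2})
        np.testing.assert_allclose(res["fits"]["a"]["coef"], coef, atol=1e-6)

    def test_distinct_cubics_detected(self):
        rng = np.random.default_rng(0)
        x = np.arange(15.0)
        hits = 0
        for s in range(30):
            r = np.random.default_rng(s)
            ya = np.polyval([0.01, -0.1, 1.0, 0.0], x) + r.normal(0, 0.3, x.size)
            yb = np.polyval([-0.01, 0.3, 0.1, 2.0], x) + r.normal(0, 0.3, x.size)
            res = fit_occurrence_trajectories({"a": ya, "b": yb})
            hits += res["pairwise"][("a", "b")]["p"] < 0.01
        assert hits >= 28

    def test_too_few_days(self):
        with pytest.raises(ValueError):
            fit_occurrence_trajectories({"a": [1, 2, 3], "b": [1, 2, 3]})


class TestComposite:
    def test_cohort_mean_session_is_zero(self):
        z = composite_responsiveness([1, 2, 3], [10, 20, 30], [0.1, 0.2, 0.3])
        assert z[1] == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_above(self):
        a = [0, 1, 2, 3, 4]
        z = composite_responsiveness(a, a, a)
        sd = np.std(a)
        expect = (3 - 2) / sd
        assert z[3] == pytest.approx(expect)

    def test_zero_variance_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            z = composite_responsiveness([1, 1, 1], [1, 2, 3], [3, 2, 1])
        assert z.shape == (3,)
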