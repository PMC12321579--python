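import numpy as np
import pytest

from iedtools import detect, synth
from iedtools.types import ChannelInfo, SessionBundle, SessionMeta, StateIntervals

from conftest import make_noise_bundle

FS = 1250.0


def lfp_bundle(signals: dict, duration_s: float, state: str = "NREM") -> SessionBundle:
    """Bundle from named channel arrays (region inferred from name)."""
    n = int(duration_s * FS)
    labels = list(signals)
    regions = {"hc0": "HC", "mpfc0": "MPFC"}
    channels = [
        ChannelInfo(lbl, regions.get(lbl, "OTHER"), "ACCEL" if "acc" in lbl else "LFP", 0.2)
        for lbl in labels
    ]
    lfp = np.column_stack([signals[lbl] for lbl in labels])
    meta = SessionMeta("t", FS, n, channels)
    return SessionBundle(
        meta=meta, lfp=lfp, states=StateIntervals([(0.0, duration_s, state)])
    )


class TestScoreSleep:
    def test_state_recovery_on_default_session(self, default_session):
        scored = detect.score_sleep(default_session)
        agree = 0
        total = 0
        for t in np.arange(0.5, default_session.duration_s, 1.0):
            truth = default_session.states.state_at(t)
            got = scored.state_at(t)
            if truth and got:
                total += 1
                agree += truth == got
        assert agree / total >= 0.9

    def test_motion_burst_scored_wake(self, default_session):
        scored = detect.score_sleep(default_session)
        for s, e in default_session.states.for_state("WAKE"):
            mid = (s + e) / 2
            assert scored.state_at(mid) == "WAKE"

    def test_zero_signal_has_no_nrem(self):
        dur = 120.0
        z = np.zeros(int(dur * FS))
        b = lfp_bundle({"hc0": z, "mpfc0": z.copy(), "acc0": z.copy()}, dur)
        scored = detect.score_sleep(b)
        assert scored.duration("NREM") == 0.0

    def test_missing_accelerometer_instructive_error(self):
        dur = 120.0
        z = np.zeros(int(dur * FS))
        b = lfp_bundle({"hc0": z, "mpfc0": z.copy()}, dur)
        with pytest.raises(ValueError, match="assume-immobile"):
            detect.score_sleep(b)


class TestDetectMua:
    def test_threshold_monotonicity(self, noise_bundle):
        counts = [
            detect.detect_mua(noise_bundle, "ch0", thr_mult=m).size for m in (3, 4, 5, 6)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_injected_transients_recovered(self):
        rng = np.random.default_rng(0)
        dur = 60.0
        x = rng.normal(0, 10, int(dur * FS))
        sigma = np.median(np.abs(x)) / 0.6745
        times = np.linspace(1.0, dur - 1.0, 100)
        for t in times:
            i = int(t * FS)
            x[i - 1 : i + 2] += 8 * sigma * np.array([0.4, 1.0, 0.4])
        b = lfp_bundle({"mpfc0": x}, dur)
        got = detect.detect_mua(b, "mpfc0")
        hits = sum(1 for t in times if np.min(np.abs(got - t)) < 0.01)
        assert hits >= 95

    def test_zero_signal_no_events(self):
        b = lfp_bundle({"mpfc0": np.zeros(int(30 * FS))}, 30.0)
        assert detect.detect_mua(b, "mpfc0").size == 0

    def test_band_clipped_with_warning(self, noise_bundle):
        with pytest.warns(UserWarning, match="Nyquist"):
            detect.detect_mua(noise_bundle, "ch0", band=(80.0, 1000.0))


class TestDetectIed:
    def test_recovery_on_synthetic_session(self, default_session):
        gt = default_session.ground_truth
        series = detect.detect_ied(default_session, "hc0")
        truth = gt.events["ied_hc"].peak_times
        got = series.peak_times
        sens = np.mean([np.min(np.abs(got - t)) <= 0.025 for t in truth])
        prec = np.mean([np.min(np.abs(truth - t)) <= 0.025 for t in got])
        assert sens >= 0.9
        assert prec >= 0.9

    def test_artifact_rejection(self, quiet_session):
        b = quiet_session
        x = b.channel("hc0").copy()
        tpl = synth.ied_template(FS)
        hp_sd = x.std()  # upper bound on the >15 Hz baseline SD
        i = int(100 * FS)
        x[i : i + tpl.size] += tpl * 150 * hp_sd
        b2 = lfp_bundle({"hc0": x, "mpfc0": b.channel("mpfc0")}, b.duration_s)
        series = detect.detect_ied(b2, "hc0")
        assert len(series) == 0

    def test_monotone_in_detection_multiplier(self, default_session):
        n5 = len(detect.detect_ied(default_session, "hc0", k_detect=5.0))
        n8 = len(detect.detect_ied(default_session, "hc0", k_detect=8.0))
        assert n8 <= n5

    def test_short_nrem_raises(self):
        b = make_noise_bundle(duration_s=40.0)
        with pytest.raises(ValueError, match="NREM"):
            detect.detect_ied(b, "ch0")

    def test_noise_only_low_false_positive_rate(self):
        p = synth.GenParams(duration_s=1200.0, hc_ied_rate_per_min=0.0, p_couple=0.0,
                            n_pyr=0, n_int=0)
        b = synth.generate_session(p, seed=11)
        series = detect.detect_ied(b, "hc0")
        assert len(series) / 20.0 <= 0.5


class TestDetectSpindles:
    @staticmethod
    def background(dur, seed=0):
        """White noise plus its 10-20 Hz filtered-baseline SD."""
        from iedtools.detect import _bandpass

        rng = np.random.default_rng(seed)
        x = rng.normal(0, 12, int(dur * FS))
        return x, float(_bandpass(x, FS, 10.0, 20.0).std())

    def test_single_burst_detected(self):
        dur = 120.0
        x, sd = self.background(dur)
        tpl = synth.spindle_template(FS, 1.0, 13.0)
        x[int(60 * FS) : int(60 * FS) + tpl.size] += tpl * 6 * sd
        b = lfp_bundle({"mpfc0": x}, dur)
        series = detect.detect_spindles(b, "mpfc0")
        assert len(series) == 1
        ev = series.events[0]
        assert 0.35 <= ev.end_s - ev.start_s <= 3.0
        assert abs(ev.peak_s - 60.5) < 0.5

    def test_short_burst_rejected(self):
        dur = 120.0
        x, sd = self.background(dur)
        tpl = synth.spindle_template(FS, 0.3, 13.0)
        x[int(60 * FS) : int(60 * FS) + tpl.size] += tpl * 6 * sd
        b = lfp_bundle({"mpfc0": x}, dur)
        assert len(detect.detect_spindles(b, "mpfc0")) == 0

    def test_close_bursts_merged(self):
        dur = 120.0
        x, sd = self.background(dur)
        tpl = synth.spindle_template(FS, 0.5, 13.0)
        for t0 in (60.0, 60.6):  # 0.1 s gap between bursts
            x[int(t0 * FS) : int(t0 * FS) + tpl.size] += tpl * 6 * sd
        b = lfp_bundle({"mpfc0": x}, dur)
        series = detect.detect_spindles(b, "mpfc0")
        assert len(series) == 1

    def test_recovery_on_synthetic_session(self, default_session):
        gt = default_session.ground_truth.events["spindle_mpfc"]
        series = detect.detect_spindles(default_session, "mpfc0")

        def overlap_frac(a, b):
            hits = 0
            for ev in a:
                if any(min(ev.end_s, d.end_s) - max(ev.start_s, d.start_s) > 0 for d in b):
                    hits += 1
            return hits / len(a)

        assert overlap_frac(gt, series) >= 0.9
        assert overlap_frac(series, gt) >= 0.9

    def test_durations_within_bounds(self, default_session):
        series = detect.detect_spindles(default_session, "mpfc0")
        for ev in series:
            assert 0.35 <= ev.end_s - ev.start_s <= 3.0


class TestDetectDownStates:
    def test_recovery_and_flags(self, default_session):
        b = default_session
        gt = b.ground_truth
        mua = np.sort(np.concatenate([u.spike_times_s for u in b.units]))
        ied = detect.detect_ied(b, "hc0")
        downs = detect.detect_down_states(b, "mpfc0", mua_times=mua, ied_hc=ied)
        assert len(downs) > 0
        for d in downs:
            assert d.t_start < d.t_peak < d.t_end
            assert 0.15 <= d.duration_s <= 0.5
            assert (d.z_peak > 1 and d.z_end < -1.5) or (d.z_peak > 2 and d.z_end < 0)
        # recovery of injected DOWNs
        truth = gt.events["down_mpfc"].peak_times
        got = np.array([d.t_peak for d in downs])
        sens = np.mean([np.min(np.abs(got - t)) <= 0.1 for t in truth])
        assert sens >= 0.7
        # most DOWNs should show the injected MUA suppression
        validated = [d.mua_validated for d in downs if d.mua_validated is not None]
        assert np.mean(validated) >= 0.4

    def test_pathological_classification(self, default_session):
        b = default_session
        gt = b.ground_truth
        ied = detect.detect_ied(b, "hc0")
        downs = detect.detect_down_states(b, "mpfc0", ied_hc=ied, mua_times=None)
        path, phys = detect.classify_transitions(downs)
        assert len(path) + len(phys) == len(downs)
        truth_path = {
            round(t, 1)
            for t, flag in zip(
                gt.events["down_mpfc"].peak_times, gt.events["down_mpfc"].params["pathological"]
            )
            if flag
        }
        hits = sum(1 for d in path if round(d.t_peak, 1) in truth_path)
        assert hits / max(len(path), 1) >= 0.7

    def test_empty_mua_warns(self, default_session):
        with pytest.warns(UserWarning, match="MUA"):
            downs = detect.detect_down_states(
                default_session, "mpfc0", mua_times=np.empty(0), ied_hc=None
            )
        assert all(d.mua_validated is None for d in downs)

    def test_classify_empty(self):
        path, phys = detect.classify_transitions([])
        assert path == [] and phys == []


def test_interpolate_blanks_removes_artifact():
    x = np.zeros(1250)
    x[600:700] = 500.0
    y = detect.interpolate_blanks(x, 1250.0, [(600 / 1250.0, 700 / 1250.0)])
    assert np.abs(y[595:705]).max() == 0.0  # artifact gone (flat endpoints)
    assert np.array_equal(y[:595], x[:595])  # untouched outside the blank

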