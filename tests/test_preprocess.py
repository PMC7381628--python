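"""Filtering, blink correction, epoching, rejection, averaging."""

import copy
import warnings

import numpy as np
import pandas as pd
import pytest

from shapenum import preprocess, simulate, stimuli
from shapenum.montage import Montage
from shapenum.simulate import RawRecording


def _toy_recording(data, events=None, montage=None, sfreq=1000.0):
    n_ch = data.shape[0]
    names = [f"ch{i}" for i in range(n_ch - 1)] + ["VEOG"]
    events = events if events is not None else pd.DataFrame(
        {"sample": [], "condition": []})
    if montage is None:
        rng = np.random.default_rng(0)
        pos = rng.standard_normal((n_ch, 3))
        pos /= np.linalg.norm(pos, axis=1, keepdims=True)
        montage = Montage(names[:-1] + ["VEOGpos"], pos)
    return RawRecording(data.astype(float), sfreq, names, events, montage,
                        veog_index=n_ch - 1)


class TestFilter:
    def test_passband_preserves_10hz(self):
        t = np.arange(20000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t)
        rec = _toy_recording(np.vstack([x, np.zeros_like(x)]))
        out = preprocess.bandpass_zero_phase(rec)
        mid = slice(5000, 15000)
        ratio = out.data[0, mid].std() / x[mid].std()
        assert ratio == pytest.approx(1.0, abs=0.01)
        # zero phase: peak positions unchanged (< 0.5 deg at 10 Hz ~ 0.14 ms)
        xcorr = np.correlate(out.data[0, mid], x[mid], "full")
        lag = xcorr.argmax() - (len(x[mid]) - 1)
        assert lag == 0

    def test_stopband_attenuates_60hz(self):
        t = np.arange(20000) / 1000.0
        x = np.sin(2 * np.pi * 60 * t)
        rec = _toy_recording(np.vstack([x, np.zeros_like(x)]))
        out = preprocess.bandpass_zero_phase(rec)
        mid = slice(5000, 15000)
        atten_db = 20 * np.log10(x[mid].std() / out.data[0, mid].std())
        assert atten_db > 20

    def test_dc_removed(self):
        x = np.full(60000, 7.0)
        rec = _toy_recording(np.vstack([x, np.zeros_like(x)]))
        out = preprocess.bandpass_zero_phase(rec)
        assert abs(out.data[0, 25000:35000].mean()) < 0.5

    def test_too_short_raises(self):
        rec = _toy_recording(np.zeros((2, 50)))
        with pytest.raises(preprocess.SignalTooShortError):
            preprocess.bandpass_zero_phase(rec)


class TestBlinkCorrection:
    def test_recovers_planted_coefficients(self, rng):
        n = 60000
        veog = np.zeros(n)
        proto = simulate._blink_prototype()
        for s in range(1000, n - 500, 3000):
            veog[s:s + len(proto)] += 240 * proto
        b = np.array([0.4, 0.2, 0.05])
        eeg = b[:, None] * veog[None, :] + rng.standard_normal((3, n))
        rec = _toy_recording(np.vstack([eeg, veog]))
        out, coeffs = preprocess.correct_blinks(rec)
        assert np.abs((coeffs - b) / b).max() < 0.01
        # frontal-channel/VEOG coupling removed over blink segments
        mask = preprocess.detect_blinks(veog)
        r = np.corrcoef(out.data[0, mask], veog[mask])[0, 1]
        assert abs(r) < 0.1

    def test_zero_veog_is_identity(self):
        data = np.vstack([np.random.default_rng(1).standard_normal((2, 5000)),
                          np.zeros(5000)])
        rec = _toy_recording(data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, coeffs = preprocess.correct_blinks(rec)
        assert np.array_equal(out.data, rec.data)
        assert np.allclose(coeffs, 0)


class TestEpoching:
    def _rec_with_events(self, n_ch=3, n=5000, events=(1500, 3000)):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((n_ch, n))
        ev = pd.DataFrame({"sample": list(events),
                           "condition": ["S3"] * len(events)})
        return _toy_recording(data, ev)

    def test_epoch_length_1101(self):
        ep = preprocess.epoch(self._rec_with_events())
        assert ep.data.shape[2] == 1101
        assert ep.times_ms[0] == -100 and ep.times_ms[-1] == 1000

    def test_event_too_early_raises(self):
        rec = self._rec_with_events(events=(50,))
        with pytest.raises(preprocess.TruncatedEpochError):
            preprocess.epoch(rec)

    def test_constant_offset_removed_by_baseline(self):
        rec = self._rec_with_events()
        rec.data[0] = 42.0
        ep = preprocess.epoch(rec)
        assert np.allclose(ep.data[:, 0, :], 0.0)


class TestRejection:
    def _epochs(self, peak_uv):
        data = np.zeros((2, 3, 1101))
        data[0, 0, 500] = peak_uv
        return preprocess.EpochSet(0, data, np.arange(-100, 1001),
                                   np.array(["S3", "S3"]),
                                   ["a", "b", "VEOG"], veog_index=2)

    def test_above_threshold_rejected(self):
        out = preprocess.reject_artifacts(self._epochs(80.0))
        assert not out.retained[0] and out.retained[1]

    def test_below_threshold_retained(self):
        out = preprocess.reject_artifacts(self._epochs(74.9))
        assert out.retained.all()

    def test_veog_excluded_from_test(self):
        data = np.zeros((1, 3, 1101))
        data[0, 2, 300] = 300.0    # huge VEOG deflection only
        ep = preprocess.EpochSet(0, data, np.arange(-100, 1001),
                                 np.array(["S3"]), ["a", "b", "VEOG"], 2)
        assert preprocess.reject_artifacts(ep).retained.all()

    def test_rejection_monotone_in_threshold(self, rng):
        data = rng.normal(0, 40, size=(30, 3, 200))
        ep = preprocess.EpochSet(0, data, np.arange(200),
                                 np.array(["S3"] * 30), ["a", "b", "VEOG"], 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strict = preprocess.reject_artifacts(ep, 50.0)
            loose = preprocess.reject_artifacts(ep, 75.0)
        assert not np.any(strict.retained & ~loose.retained)

    def test_planted_artifacts_all_flagged(self, ground_truth):
        gt = copy.copy(ground_truth)
        gt.blink_rate_hz = 0.0
        gt.artifact_rate = 0.10
        sched = stimuli.build_schedule(1, 25, 3)
        rec = simulate.simulate_recording(
            sched, gt, simulate.NoiseSpec(sigma_uv=5.0, blinks=False), 6)
        assert rec.artifact_trials
        ep = preprocess.reject_artifacts(preprocess.epoch(rec))
        rejected = set(np.flatnonzero(~ep.retained))
        assert set(rec.artifact_trials) <= rejected


class TestAveraging:
    def test_identical_trials_average_to_single_trial(self):
        one = np.random.default_rng(3).standard_normal((3, 1101))
        data = np.stack([one, one, one])
        ep = preprocess.EpochSet(0, data, np.arange(-100, 1001),
                                 np.array(["S3"] * 3), ["a", "b", "VEOG"], 2)
        erp = preprocess.average_erp(ep, "S3")
        assert np.allclose(erp.data, one)

    def test_rereference_zero_mean_and_idempotent(self, rng):
        erp = preprocess.SubjectERP(0, "S3", rng.standard_normal((4, 100)),
                                    np.arange(100), ["a", "b", "c", "VEOG"])
        re1 = preprocess.rereference_average(erp)
        assert np.abs(re1.data.mean(axis=0)).max() < 1e-10
        re2 = preprocess.rereference_average(re1)
        assert np.allclose(re1.data, re2.data)

    def test_rereference_preserves_gfp(self, rng):
        from shapenum.topography import gfp

        erp = preprocess.SubjectERP(0, "S3", rng.standard_normal((4, 50)),
                                    np.arange(50), ["a", "b", "c", "VEOG"])
        re1 = preprocess.rereference_average(erp)
        for t in range(50):
            assert gfp(erp.data[:3, t]) == pytest.approx(
                gfp(re1.data[:, t]), abs=1e-12)

    def test_empty_cell_raises(self):
        ep = preprocess.EpochSet(0, np.zeros((1, 2, 10)), np.arange(10),
                                 np.array(["S3"]), ["a", "VEOG"], 1)
        with pytest.raises(preprocess.EmptyCellError):
            preprocess.average_erp(ep, "R4")

    def test_grand_average_needs_two_subjects(self):
        erp = preprocess.SubjectERP(0, "S3", np.zeros((3, 10)),
                                    np.arange(10), ["a", "b", "VEOG"])
        with pytest.raises(preprocess.EmptyCellError):
            preprocess.grand_average([erp])

    def test_zero_noise_grand_average_equals_plant(self, ground_truth):
        erps = []
        for subj in range(2):
            sched = stimuli.build_schedule(1, 1, subj)
            rec = simulate.simulate_recording(
                sched, ground_truth,
                simulate.NoiseSpec(sigma_uv=0, blinks=False, artifacts=False),
                subj)
            ep = preprocess.epoch(rec, subj)
            erps.append(preprocess.average_erp(ep, "S5"))
        ga = preprocess.grand_average(erps)
        evoked = simulate.evoked_signal("S5", ground_truth)
        post = ga.times_ms >= 0
        assert np.abs(ga.data[:, post] - evoked).max() < 1e-9
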