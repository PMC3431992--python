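"""Preprocessing tests: QRS detection, mains removal, baseline correction,
signal-averaged template construction with the 0.98 correlation gate."""

import dataclasses

import numpy as np
import pytest

from ecgallometry.preprocess import (ECGSignal, InsufficientBeatsError, _ncc,
                                     build_template, correct_baseline,
                                     detect_qrs, remove_mains)
from ecgallometry.synth import (RecordingConfig, make_beat, make_recording,
                                mi_morphology)

FS = 500.0


def _recording(lead="I", **kw):
    cfg = RecordingConfig(**{"n_beats": 10, "noise_sd": 0.02, "seed": 1, **kw})
    x, truth = make_recording(mi_morphology(lead), cfg)
    return ECGSignal(x, FS, lead), truth


class TestDetectQRS:
    def test_clean_recording_all_beats_within_10ms(self):
        sig, truth = _recording()
        det = detect_qrs(sig)
        assert len(det) == 10
        for d in det:
            assert np.min(np.abs(truth.r_peaks - d)) <= 0.010 * FS

    def test_zero_signal_yields_empty(self):
        det = detect_qrs(ECGSignal(np.zeros(3000), FS))
        assert det.size == 0

    def test_mains_interference_removed_before_detection_changes_nothing(self):
        sig_clean, truth = _recording(seed=2)
        sig_mains, _ = _recording(seed=2, mains_amplitude=0.05)
        det_clean = detect_qrs(sig_clean)
        det_mains = detect_qrs(remove_mains(sig_mains))
        assert np.array_equal(det_clean, det_mains)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            detect_qrs(ECGSignal(np.zeros(300), 90.0))

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_qrs(ECGSignal(np.zeros(100), FS))


class TestRemoveMains:
    def test_pure_mains_tone_suppressed(self):
        t = np.arange(int(10 * FS)) / FS
        tone = 0.1 * np.sin(2 * np.pi * 50.0 * t)
        out = remove_mains(ECGSignal(tone, FS))
        assert np.sqrt(np.mean(out.samples ** 2)) < 0.01

    def test_clean_beats_pass_through(self):
        sig, _ = _recording(noise_sd=0.0)
        out = remove_mains(sig)
        rms_in = np.sqrt(np.mean(sig.samples ** 2))
        rms_diff = np.sqrt(np.mean((out.samples - sig.samples) ** 2))
        assert rms_diff < 0.05 * rms_in

    def test_zero_in_zero_out(self):
        out = remove_mains(ECGSignal(np.zeros(1000), FS))
        assert np.allclose(out.samples, 0.0)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            remove_mains(ECGSignal(np.zeros(1000), 100.0))


class TestCorrectBaseline:
    def test_sinusoidal_wander_removed_at_isoelectric_segments(self):
        cfg = RecordingConfig(n_beats=15, noise_sd=0.0,
                              baseline_wander_amplitude=0.3,
                              baseline_wander_freq=0.3, seed=3)
        x, truth = make_recording(mi_morphology("I"), cfg)
        out = correct_baseline(ECGSignal(x, FS), truth.r_peaks)
        # isoelectric = the PR-knot regions themselves
        resid = []
        for r in truth.r_peaks:
            k = r - int(0.040 * FS)
            resid.extend(out.samples[k - 2:k + 3])
        assert np.sqrt(np.mean(np.square(resid))) < 0.02

    def test_zero_wander_input_unchanged_at_knots(self):
        sig, truth = _recording(noise_sd=0.0)
        out = correct_baseline(sig, truth.r_peaks)
        for r in truth.r_peaks[1:-1]:
            k = r - int(0.040 * FS)
            assert out.samples[k] == pytest.approx(sig.samples[k], abs=1e-9)

    def test_linear_drift_removed_st_recovered(self):
        cfg = RecordingConfig(n_beats=15, noise_sd=0.0, seed=4)
        x, truth = make_recording(mi_morphology("I"), cfg)
        drift = 0.1 * np.arange(len(x)) / FS          # 0.1 mV/s
        out = correct_baseline(ECGSignal(x + drift, FS), truth.r_peaks)
        for fid in truth.fiducials[1:-1]:
            st_point = fid.qrs_onset + int(round(0.050 * FS))
            iso = np.median(out.samples[fid.p_onset - 20:fid.qrs_onset])
            st = out.samples[st_point] - iso
            assert st == pytest.approx(0.08, abs=0.01)

    def test_few_beats_falls_back_to_median_with_warning(self):
        sig, truth = _recording()
        with pytest.warns(UserWarning):
            out = correct_baseline(sig, truth.r_peaks[:2])
        assert np.median(out.samples) == pytest.approx(0.0, abs=1e-9)


class TestBuildTemplate:
    AMP = 2.5    # amplified beat keeps QRS shape correlation well above the
                 # gate at the sigma = 0.05 mV white-noise study condition

    def _noisy_train(self, sigma, n_beats=35, seed=1, ectopic_rate=0.0):
        m = mi_morphology("I").scaled(amplitude=self.AMP)
        cfg = RecordingConfig(n_beats=n_beats, rr_sd=0.0, noise_sd=sigma,
                              ectopic_rate=ectopic_rate, seed=seed)
        x, truth = make_recording(m, cfg)
        return ECGSignal(x, FS), truth, m

    def test_template_rms_error_beats_averaging_bound(self):
        sigma = 0.05
        sig, truth, m = self._noisy_train(sigma)
        clean_sig, _, _ = self._noisy_train(0.0)
        tpl = build_template(sig, truth.r_peaks)
        tpl_clean = build_template(clean_sig, truth.r_peaks)
        assert tpl.n_averaged == 30
        rmse = np.sqrt(np.mean((tpl.samples - tpl_clean.samples) ** 2))
        assert rmse <= 1.5 * sigma / np.sqrt(30)

    def test_template_is_plain_mean_of_accepted_windows(self):
        # permutation invariance follows from plain-mean semantics
        sig, truth, _ = self._noisy_train(0.02, seed=5)
        tpl = build_template(sig, truth.r_peaks)
        pre = int(0.140 * FS)
        post = int(0.300 * FS)
        windows = np.stack([sig.samples[r - pre:r + post]
                            for r in truth.r_peaks[:30]])
        assert np.allclose(tpl.samples, windows.mean(axis=0), atol=1e-12)

    def test_widened_ectopic_rejected_by_correlation_gate(self):
        m = mi_morphology("I")
        ect = m.scaled(amplitude=1.5, width=1.6)
        beat, fid = make_beat(m, FS)
        ebeat, efid = make_beat(ect, FS)
        # brute-force oracle: the ectopic's QRS-window correlation with the
        # normal beat is below the 0.98 gate
        qhw = int(0.035 * FS)
        w_n = beat[fid.r_peak - qhw:fid.r_peak + qhw + 1]
        w_e = ebeat[efid.r_peak - qhw:efid.r_peak + qhw + 1]
        assert _ncc(w_e, w_n) < 0.98

        rr = int(0.365 * FS)
        pad = int(0.4 * FS)
        n = pad * 2 + rr * 32 + len(ebeat)
        x = np.zeros(n)
        r_peaks = []
        for b in range(31):
            on = pad + b * rr
            w, f = (ebeat, efid) if b == 12 else (beat, fid)
            x[on:on + len(w)] += w
            r_peaks.append(on + f.r_peak)
        tpl = build_template(ECGSignal(x, FS), np.array(r_peaks))
        assert tpl.n_averaged == 30
        assert tpl.n_rejected == 1

    def test_more_than_two_rejections_is_an_error(self):
        m = mi_morphology("I")
        ect = m.scaled(amplitude=1.5, width=1.6)
        beat, fid = make_beat(m, FS)
        ebeat, efid = make_beat(ect, FS)
        rr = int(0.365 * FS)
        pad = int(0.4 * FS)
        x = np.zeros(pad * 2 + rr * 34 + len(ebeat))
        r_peaks = []
        for b in range(33):
            on = pad + b * rr
            w, f = (ebeat, efid) if b in (10, 15, 20) else (beat, fid)
            x[on:on + len(w)] += w
            r_peaks.append(on + f.r_peak)
        with pytest.raises(InsufficientBeatsError):
            build_template(ECGSignal(x, FS), np.array(r_peaks))

    def test_noise_decreases_with_averaging_count(self):
        sigma = 0.05
        sig, truth, _ = self._noisy_train(sigma, n_beats=35, seed=11)
        clean_sig, _, _ = self._noisy_train(0.0, n_beats=35)
        errs = []
        for n in (10, 20, 30):
            tpl = build_template(sig, truth.r_peaks, n_target=n)
            tpl_c = build_template(clean_sig, truth.r_peaks, n_target=n)
            errs.append(np.sqrt(np.mean((tpl.samples - tpl_c.samples) ** 2)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[2] == pytest.approx(np.sqrt(3), rel=0.4)

    def test_common_shift_shifts_template_exactly(self):
        sig, truth, _ = self._noisy_train(0.02, seed=6)
        k = 7
        tpl = build_template(sig, truth.r_peaks)
        tpl_shifted = build_template(sig, truth.r_peaks + k)
        # shifting every trigger by k slides the window by k
        assert np.allclose(tpl_shifted.samples[:-k], tpl.samples[k:])

    def test_too_few_candidates_is_an_error(self):
        sig, truth, _ = self._noisy_train(0.02, n_beats=12)
        with pytest.raises(InsufficientBeatsError):
            build_template(sig, truth.r_peaks)
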