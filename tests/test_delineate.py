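"""Delineation tests: slope-threshold QRS bounds, median isoelectric level,
9-point-derivative P wave, tangent-method T end, fixed-offset ST."""

import dataclasses

import numpy as np
import pytest

from conftest import template_with_noise
from ecgallometry.delineate import (DelineationError, delineate_p, delineate_t,
                                    delineate_template, estimate_isoelectric,
                                    find_qrs_bounds, measure_st)
from ecgallometry.preprocess import BeatTemplate
from ecgallometry.synth import (BeatMorphology, make_template, mi_morphology,
                                random_morphology)

NOISE = 0.0037   # template-level noise: 0.02 mV recording noise / sqrt(30)


class TestQRSBounds:
    def test_clean_template_bounds_exact(self, clean_template):
        tpl, fid = clean_template
        on, end = find_qrs_bounds(tpl)
        assert on == fid.qrs_onset
        assert end == fid.qrs_end

    def test_qrs_duration_within_4ms_under_noise(self, rng):
        for _ in range(20):
            tpl, fid = template_with_noise(mi_morphology("I"), NOISE, rng)
            on, end = find_qrs_bounds(tpl)
            measured = (end - on) * 2.0
            assert measured == pytest.approx(45.0, abs=4.0)

    def test_flat_template_raises(self):
        tpl = BeatTemplate(np.zeros(220), 500.0, 30, 0, 70)
        with pytest.raises(DelineationError, match="no QRS"):
            find_qrs_bounds(tpl)

    def test_bounds_consistent_across_sampling_rates(self):
        m = mi_morphology("I")
        out = {}
        for fs in (500.0, 1000.0):
            samples, r_idx, fid = make_template(m, fs=fs)
            tpl = BeatTemplate(samples, fs, 30, 0, r_idx)
            on, end = find_qrs_bounds(tpl)
            out[fs] = ((end - on) * 1000.0 / fs)
        assert abs(out[500.0] - out[1000.0]) <= 2.0


class TestIsoelectric:
    def test_zero_pr_segment_gives_zero(self, clean_template):
        tpl, fid = clean_template
        assert estimate_isoelectric(tpl, fid.qrs_onset) == pytest.approx(0.0)

    def test_shift_equivariance(self, clean_template):
        tpl, fid = clean_template
        shifted = dataclasses.replace(tpl, samples=tpl.samples + 0.2)
        assert estimate_isoelectric(shifted, fid.qrs_onset) == pytest.approx(0.2)

    def test_median_robust_to_p_wave(self, clean_template):
        # P occupies < 50% of the pre-QRS window: brute-force mid-order value
        tpl, fid = clean_template
        level = estimate_isoelectric(tpl, fid.qrs_onset)
        pre = sorted(tpl.samples[:fid.qrs_onset])
        n = len(pre)
        mid = pre[n // 2] if n % 2 else 0.5 * (pre[n // 2 - 1] + pre[n // 2])
        assert level == pytest.approx(mid)
        assert abs(level) < 0.01     # baseline, not the 0.06 mV P amplitude

    def test_zero_onset_raises(self, clean_template):
        tpl, _ = clean_template
        with pytest.raises(DelineationError):
            estimate_isoelectric(tpl, 0)


class TestPWave:
    def test_p_duration_within_6ms(self, rng):
        for _ in range(20):
            tpl, fid = template_with_noise(mi_morphology("I"), NOISE, rng)
            on, pk, end = delineate_p(tpl, fid.qrs_onset, noise_sd=NOISE)
            assert on is not None
            assert (end - on) * 2.0 == pytest.approx(29.0, abs=6.0)

    def test_absent_p_reported_missing_not_error(self, rng):
        m = dataclasses.replace(mi_morphology("I"), p_amplitude=0.0)
        tpl, fid = template_with_noise(m, NOISE, rng)
        assert delineate_p(tpl, fid.qrs_onset, noise_sd=NOISE) == (None, None, None)

    def test_p_at_noise_floor_never_doubles_duration(self, rng):
        # SNR = 1: the P either goes undetected or keeps a sane duration
        m = dataclasses.replace(mi_morphology("I"), p_amplitude=NOISE)
        for _ in range(100):
            tpl, fid = template_with_noise(m, NOISE, rng)
            on, pk, end = delineate_p(tpl, fid.qrs_onset, noise_sd=NOISE)
            if on is not None:
                assert (end - on) * 2.0 <= 2 * 29.0


class TestTWave:
    def test_linear_tail_gives_exact_t_end(self, clean_template):
        tpl, fid = clean_template
        pk, end = delineate_t(tpl, fid.qrs_end, iso=0.0)
        assert pk == fid.t_peak
        assert end == fid.t_end

    def test_inverted_t_delineated(self, rng):
        m = mi_morphology("III")       # T = -0.05 mV
        tpl, fid = template_with_noise(m, 0.002, rng)
        pk, end = delineate_t(tpl, fid.qrs_end, iso=0.0, noise_sd=0.002)
        assert tpl.samples[pk] < 0
        assert abs(end - fid.t_end) <= 2

    def test_t_end_median_error_under_4ms_across_seeds(self, rng):
        errs = []
        for _ in range(50):
            tpl, fid = template_with_noise(mi_morphology("I"), NOISE, rng)
            _, end = delineate_t(tpl, fid.qrs_end, iso=0.0, noise_sd=NOISE)
            errs.append(abs(end - fid.t_end) * 2.0)
        assert np.median(errs) <= 4.0

    def test_no_t_wave_raises(self, rng):
        m = dataclasses.replace(mi_morphology("I"), t_amplitude=0.0, st_offset=0.0)
        tpl, fid = template_with_noise(m, 0.001, rng)
        with pytest.raises(DelineationError, match="no T wave"):
            delineate_t(tpl, fid.qrs_end, iso=0.0, noise_sd=0.001)


class TestST:
    def test_configured_offset_recovered(self, clean_template):
        tpl, fid = clean_template
        st, _ = measure_st(tpl, fid.qrs_onset, iso=0.0)
        assert st == pytest.approx(0.08, abs=0.01)

    def test_flat_template_zero(self):
        tpl = BeatTemplate(np.zeros(220), 500.0, 30, 0, 70)
        st, i = measure_st(tpl, 60, iso=0.0)
        assert st == 0.0
        assert i == 60 + 25

    def test_point_outside_template_raises(self, clean_template):
        tpl, _ = clean_template
        with pytest.raises(DelineationError):
            measure_st(tpl, len(tpl.samples) - 5, iso=0.0)


class TestFullDelineation:
    def test_fiducials_ordered_on_random_morphologies(self, rng):
        for _ in range(20):
            m = random_morphology(rng)
            tpl, fid = template_with_noise(m, NOISE, rng)
            f = delineate_template(tpl)
            f.validate()               # ordering invariant

    def test_amplitude_scaling_leaves_times_moves_amplitudes(self, rng):
        m = mi_morphology("I")
        c = 2.5
        tpl1, _ = template_with_noise(m, 0.0, rng)
        tpl2, _ = template_with_noise(m.scaled(amplitude=c), 0.0, rng)
        f1 = delineate_template(tpl1)
        f2 = delineate_template(tpl2)
        for name in ("p_onset", "p_peak", "p_end", "qrs_onset", "qrs_end",
                     "t_peak", "t_end"):
            assert getattr(f1, name) == getattr(f2, name)
        st1, _ = measure_st(tpl1, f1.qrs_onset, f1.isoelectric_level)
        st2, _ = measure_st(tpl2, f2.qrs_onset, f2.isoelectric_level)
        assert st2 == pytest.approx(c * st1, abs=1e-9)

    def test_dc_offset_leaves_all_amplitudes_unchanged(self, rng):
        tpl, _ = template_with_noise(mi_morphology("I"), 0.0, rng)
        off = dataclasses.replace(tpl, samples=tpl.samples + 0.2)
        f1 = delineate_template(tpl)
        f2 = delineate_template(off)
        a1 = tpl.samples[f1.t_peak] - f1.isoelectric_level
        a2 = off.samples[f2.t_peak] - f2.isoelectric_level
        assert a2 == pytest.approx(a1, abs=1e-9)
        st1, _ = measure_st(tpl, f1.qrs_onset, f1.isoelectric_level)
        st2, _ = measure_st(off, f2.qrs_onset, f2.isoelectric_level)
        assert st2 == pytest.approx(st1, abs=1e-9)
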