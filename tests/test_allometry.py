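"""Allometric core: VIMn, deviation-from-normality, the log-log OLS fit
against an independent oracle, and the ranked all-parameter fit table."""

import dataclasses
import math

import numpy as np
import pytest

from _oracles import ols_oracle
from ecgallometry.allometry import (allometric_fit, compute_vimn, deviation,
                                    fit_all)
from ecgallometry.synth import (AllometricStructure, CohortConfig, make_cohort,
                                study_structures, NORMAL_REFERENCE,
                                STUDY_COEFFS, residual_sd_for_se)


class TestVIMn:
    def test_zero_infarct_zero_vimn(self):
        assert compute_vimn(0.0, 6.0, 8.0) == 0.0

    def test_worked_value(self):
        assert compute_vimn(0.20, 6.0, 8.0) == pytest.approx(0.15)

    def test_percent_unit_switch(self):
        assert compute_vimn(20.0, 6.0, 8.0, pim_unit="percent") == \
            pytest.approx(0.15)

    @pytest.mark.parametrize("pim,vm,hw", [(0.2, 6.0, 0.0), (0.2, 0.0, 8.0),
                                           (1.2, 6.0, 8.0), (0.2, 9.0, 8.0)])
    def test_invalid_records_rejected(self, pim, vm, hw):
        with pytest.raises(ValueError):
            compute_vimn(pim, vm, hw)

    def test_study_range_maps_into_interval(self, rng):
        pim = rng.uniform(0.07, 0.35, 100)
        v = np.array([compute_vimn(p, 6.0, 8.0) for p in pim])
        assert np.all((v >= 0.07 * 0.75) & (v <= 0.35 * 0.75))


class TestDeviation:
    def test_equal_values_excluded(self):
        mag, sign, excluded = deviation(0.10, 0.10)
        assert mag == 0.0 and excluded

    def test_signed_magnitude(self):
        mag, sign, excluded = deviation(-0.05, 0.10)
        assert mag == pytest.approx(0.15)
        assert sign == -1 and not excluded

    def test_nan_propagates(self):
        mag, _, excluded = deviation(float("nan"), 0.1)
        assert math.isnan(mag) and excluded


class TestAllometricFit:
    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 25))
            vimn = rng.uniform(0.02, 0.3, n)
            mags = np.exp(rng.normal(0.0, 1.0, n))
            fit = allometric_fit(vimn, mags)
            o_slope, o_int, o_r, o_p, o_se, o_ise = ols_oracle(
                np.log10(vimn), np.log10(mags))
            assert fit.beta == pytest.approx(o_slope, abs=1e-10)
            assert fit.delta == pytest.approx(o_int, abs=1e-10)
            assert fit.r == pytest.approx(o_r, abs=1e-10)
            assert fit.p == pytest.approx(o_p, abs=1e-10)
            assert fit.beta_se == pytest.approx(o_se, abs=1e-10)
            assert fit.delta_se == pytest.approx(o_ise, abs=1e-10)

    def test_noiseless_line_recovered_to_machine_precision(self):
        x = np.linspace(-1.4, -0.6, 9)
        y = 3.494 + 3.464 * x
        fit = allometric_fit(10.0 ** x, 10.0 ** y)
        assert fit.beta == pytest.approx(3.464, abs=1e-12)
        assert fit.delta == pytest.approx(3.494, abs=1e-12)
        assert fit.r == pytest.approx(1.0, abs=1e-12)

    def test_scale_equivariance(self, rng):
        vimn = rng.uniform(0.05, 0.3, 12)
        mags = np.exp(rng.normal(0, 0.5, 12))
        c = 3.7
        f1 = allometric_fit(vimn, mags)
        f2 = allometric_fit(c * vimn, mags)
        assert f2.beta == pytest.approx(f1.beta, abs=1e-10)
        assert f2.r == pytest.approx(f1.r, abs=1e-10)
        assert f2.p == pytest.approx(f1.p, abs=1e-10)
        assert f2.delta == pytest.approx(f1.delta - f1.beta * math.log10(c),
                                         abs=1e-10)

    def test_zero_magnitudes_excluded_and_counted(self):
        vimn = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
        mags = np.array([1.0, 0.0, 2.0, 3.0, 4.0])
        fit = allometric_fit(vimn, mags)
        assert fit.n == 4 and fit.n_excluded == 1

    def test_errors(self):
        with pytest.raises(ValueError):
            allometric_fit(np.array([0.1, 0.2]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            allometric_fit(np.array([0.1, -0.2, 0.3]), np.ones(3))

    def test_mixed_signs_warn_and_majority_sign_reported(self):
        vimn = np.array([0.1, 0.15, 0.2, 0.25])
        mags = np.ones(4) * 2
        signs = np.array([-1, -1, -1, 1])
        with pytest.warns(UserWarning, match="mixed"):
            fit = allometric_fit(vimn, mags, signs)
        assert fit.sign == -1
        assert fit.beta_signed == -abs(fit.beta)

    def test_null_p_values_uniform(self, rng):
        # flat-magnitude truth: p should be Uniform(0, 1)
        from scipy.stats import kstest
        ps = []
        for _ in range(200):
            vimn = rng.uniform(0.05, 0.3, 9)
            mags = np.exp(rng.normal(0.0, 0.3, 9))
            ps.append(allometric_fit(vimn, mags).p)
        assert kstest(ps, "uniform").pvalue > 0.01
        rate = np.mean(np.array(ps) < 0.05)
        assert 0.02 <= rate <= 0.08


class TestRoundTrip:
    @pytest.mark.parametrize("beta,delta,direction", [
        (3.464, 3.494, 1), (-2.474, -3.593, -1), (0.57, 1.566, 1),
        (-0.6352, -0.8878, -1)])
    def test_zero_noise_generation_then_fit_is_exact(self, beta, delta, direction):
        st = {"QT": AllometricStructure(lead="III", beta=beta, delta=delta,
                                        residual_sd=0.0, direction=direction)}
        cohort, plan = make_cohort(CohortConfig(n_animals=9, n_controls=0,
                                                structures=st, seed=11))
        grp = cohort[cohort["lead"] == "III"].merge(plan, on="animal_id")
        ref = NORMAL_REFERENCE["III"]["QT"]
        devs = [deviation(v, ref) for v in grp["QT"]]
        fit = allometric_fit(grp["VIMn"].to_numpy(),
                             np.array([d[0] for d in devs]),
                             np.array([d[1] for d in devs]))
        assert fit.beta == pytest.approx(beta, abs=1e-9)
        assert fit.delta == pytest.approx(delta, abs=1e-9)
        assert abs(fit.r) == pytest.approx(1.0, abs=1e-12)
        assert fit.sign == direction


class TestFitAll:
    def _study_cohort(self, params, seed, n=9):
        base = CohortConfig(n_animals=n, n_controls=0, vm_sd=0.0, hw_sd=0.0,
                            structures=study_structures(params), seed=seed)
        _, plan = make_cohort(base)
        x = np.log10(plan.loc[plan["VIMn"] > 0, "VIMn"])
        st = study_structures(params)
        for p in params:
            st[p].residual_sd = residual_sd_for_se(x, STUDY_COEFFS[p]["beta_se"])
        return make_cohort(dataclasses.replace(base, structures=st))

    def test_seven_structured_parameters_recovered_significant(self, rng):
        sig7 = ["QT", "T_A", "ST_A", "QT_FRA", "T_PE", "QT_FRI", "QT_MA"]
        counts = {p: 0 for p in sig7}
        in_top7 = []
        n_seeds = 100
        for _ in range(n_seeds):
            cohort, plan = self._study_cohort(sig7, int(rng.integers(2 ** 31)))
            fits = fit_all(cohort, plan, normal_ref=NORMAL_REFERENCE)
            ranked = fits[fits["fittable"]].reset_index(drop=True)
            for p in sig7:
                row = ranked[ranked["parameter"] == p]
                if len(row) and bool(row["significant"].iloc[0]):
                    counts[p] += 1
            in_top7.append(sum(p in sig7 for p in ranked["parameter"][:7]))
        # each structured parameter comes back significant in the majority
        # of cohorts, and the structured set dominates the top of the ranking
        for p in sig7:
            assert counts[p] / n_seeds > 0.5, (p, counts)
        assert np.mean(in_top7) >= 4.5

    def test_direct_mode_runs_and_ranks(self):
        cohort, plan = self._study_cohort(["QT"], seed=5)
        fits = fit_all(cohort, plan, normal_ref=NORMAL_REFERENCE, mode="direct")
        assert set(fits.loc[fits["fittable"], "mode"]) == {"direct"}
        assert len(fits) == 18

    def test_unknown_mode_rejected(self):
        cohort, plan = self._study_cohort(["QT"], seed=5)
        with pytest.raises(ValueError):
            fit_all(cohort, plan, normal_ref=NORMAL_REFERENCE, mode="magic")
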