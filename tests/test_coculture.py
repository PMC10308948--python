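"""Coculture deconvolution, the GFP calibration, empirical interaction
traces, and LV coefficient fitting."""

import numpy as np
import pytest

from lvcheck import (CocultureLV, CocultureTrace, FitError, GFPCalibration,
                     LogisticParams, LVSystem, ParameterError,
                     compare_model_experiment, deconvolve_coculture,
                     empirical_interaction_trace, fit_lv_to_coculture,
                     gfp_to_od, invert_gfp_calibration, simulate_lv)
from lvcheck.simulate import simulate_coculture_trace

CAL = GFPCalibration()


class TestCalibration:
    @pytest.mark.parametrize("F, expected", [
        (0.0, 2.97e-5 * 200),                 # 0.00594
        (2999.0, 2.97e-5 * 3199),             # 0.0950 just below threshold
    ])
    def test_linear_branch_values(self, F, expected):
        assert gfp_to_od(F, CAL) == pytest.approx(expected, rel=1e-12)

    def test_sqrt_branch_value_at_threshold(self):
        b = 5.20e-6 * (100 - 3000)
        expected = -0.0283 + np.sqrt(0.0283**2 - b)
        assert gfp_to_od(3000.0, CAL) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0977, abs=1e-4)

    def test_monotone_within_and_across_branches(self):
        F = np.linspace(0, 60000, 5000)
        od = gfp_to_od(F, CAL)
        assert np.all(np.diff(od) > 0) or np.all(np.diff(od) >= 0)
        # branch jump is upward (non-decreasing overall)
        assert gfp_to_od(3000.0, CAL) > gfp_to_od(2999.999, CAL)

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(0)
        od_lin = rng.uniform(CAL.linear_scale * CAL.linear_offset,
                             CAL.od_linear_max * 0.999, 25)
        od_hi = rng.uniform(CAL.od_sqrt_min, 0.6, 25)
        for od in (od_lin, od_hi):
            F = invert_gfp_calibration(od, CAL)
            assert np.allclose(gfp_to_od(F, CAL), od, atol=1e-10)

    def test_linear_inverse_value(self):
        assert invert_gfp_calibration(0.00594, CAL) == pytest.approx(0.0, abs=1e-9)

    def test_gap_maps_to_threshold_with_flag(self):
        od = 0.5 * (CAL.od_linear_max + CAL.od_sqrt_min)
        F, gap = invert_gfp_calibration(od, CAL, return_gap_mask=True)
        assert gap and F == CAL.branch_threshold

    def test_below_range_errors_unless_extrapolating(self):
        with pytest.raises(ParameterError):
            invert_gfp_calibration(0.001, CAL)
        F = invert_gfp_calibration(0.001, CAL, extrapolate=True)
        assert gfp_to_od(F, CAL) == pytest.approx(0.001, rel=1e-10)


class TestDeconvolution:
    def test_noise_free_roundtrip_matches_simulation(self, pair_system,
                                                     no_noise):
        tr = simulate_coculture_trace(pair_system, [0.005, 0.005],
                                      noise=no_noise, seed=0)
        S = simulate_lv(pair_system, np.array([0.005, 0.005]), tr.time)
        dec = deconvolve_coculture(tr)
        assert np.allclose(dec.od1, S[:, 0], rtol=1e-6, atol=1e-9)
        assert np.allclose(dec.od2, S[:, 1], rtol=1e-6, atol=1e-9)
        assert dec.clamped_fraction == 0.0

    def test_baseline_fluorescence_yields_all_partner(self):
        t = np.arange(0, 5, 1 / 6)
        total = np.full_like(t, 0.2)
        F = np.full_like(t, invert_gfp_calibration(1e-9, CAL, extrapolate=True))
        dec = deconvolve_coculture(CocultureTrace(time=t, total_od=total,
                                                  fluorescence=F))
        assert np.allclose(dec.od1, 0.0, atol=1e-8)
        assert np.allclose(dec.od2, 0.2)

    def test_overshoot_clamped_and_flagged(self):
        t = np.arange(0, 5, 1.0)
        total = np.full_like(t, 0.05)
        F = np.full_like(t, 2000.0)  # converts to ~0.065 > total
        dec = deconvolve_coculture(CocultureTrace(time=t, total_od=total,
                                                  fluorescence=F))
        assert np.all(dec.od2 == 0.0)
        assert dec.clamped_fraction == 1.0


class TestEmpiricalTrace:
    def test_recovers_generating_coefficients(self, pair_system, no_noise):
        tr = simulate_coculture_trace(pair_system, [0.005, 0.005],
                                      noise=no_noise, seed=0)
        dec = deconvolve_coculture(tr)
        i1 = empirical_interaction_trace(dec, pair_system.isolates[0],
                                         pair_system.isolates[1], focal=1)
        i2 = empirical_interaction_trace(dec, pair_system.isolates[1],
                                         pair_system.isolates[0], focal=2)
        assert i1.median == pytest.approx(-1.26, rel=0.05)
        assert i2.median == pytest.approx(-0.52, rel=0.05)

    def test_time_constant_on_lv_data(self, pair_system, no_noise):
        """Noise-free LV dynamics yield a flat c-hat trace (sd < 5% of |c|)."""
        tr = simulate_coculture_trace(pair_system, [0.005, 0.005],
                                      noise=no_noise, seed=0)
        dec = deconvolve_coculture(tr)
        for focal, bi, bj, c in ((1, *pair_system.isolates, -1.26),
                                 (2, pair_system.isolates[1],
                                  pair_system.isolates[0], -0.52)):
            it = empirical_interaction_trace(dec, bi, bj, focal=focal)
            assert it.sd < 0.05 * abs(c)

    def test_null_interaction_recovered(self, pair_system, no_noise):
        sys0 = LVSystem(isolates=pair_system.isolates, c=np.zeros((2, 2)))
        tr = simulate_coculture_trace(sys0, [0.005, 0.005], noise=no_noise,
                                      seed=0)
        dec = deconvolve_coculture(tr)
        it = empirical_interaction_trace(dec, sys0.isolates[0],
                                         sys0.isolates[1], focal=1)
        assert abs(it.median) < 0.05

    def test_partner_below_threshold_errors(self, pair_system, no_noise):
        tr = simulate_coculture_trace(pair_system, [0.005, 0.005],
                                      noise=no_noise, seed=0)
        dec = deconvolve_coculture(tr)
        with pytest.raises(FitError):
            empirical_interaction_trace(dec, pair_system.isolates[0],
                                        pair_system.isolates[1], focal=1,
                                        partner_floor=10.0)


class TestCoefficientFit:
    def baselines(self, system):
        return (system.isolates[0], system.isolates[1])

    def test_noise_free_recovery_within_1pct(self, pair_system, no_noise):
        traces = [deconvolve_coculture(simulate_coculture_trace(
            pair_system, init, noise=no_noise, seed=s))
            for s, init in enumerate(([0.005, 0.005], [0.0005, 0.005]))]
        res = CocultureLV(traces, self.baselines(pair_system),
                          c0=(0.0, 0.0)).fit()
        assert res.c12 == pytest.approx(-1.26, rel=0.01)
        assert res.c21 == pytest.approx(-0.52, rel=0.01)

    def test_null_system_fits_to_zero(self, pair_system, no_noise):
        sys0 = LVSystem(isolates=pair_system.isolates, c=np.zeros((2, 2)))
        traces = [deconvolve_coculture(simulate_coculture_trace(
            sys0, [0.005, 0.005], noise=no_noise, seed=0))]
        res = CocultureLV(traces, self.baselines(sys0)).fit()
        assert abs(res.c12) < 0.05 and abs(res.c21) < 0.05

    def test_recovery_improves_as_noise_vanishes(self, pair_system):
        from lvcheck import NoiseModel

        errs = []
        for sd in (0.02, 0.01, 0.0):
            noise = (NoiseModel(multiplicative_sd=sd, additive_sd=0.0)
                     if sd else NoiseModel.none())
            traces = [deconvolve_coculture(simulate_coculture_trace(
                pair_system, [0.005, 0.005], noise=noise, seed=s))
                for s in range(3)]
            res = CocultureLV(traces, self.baselines(pair_system),
                              c0=(-1.0, -0.4)).fit()
            errs.append(abs(res.c12 + 1.26) + abs(res.c21 + 0.52))
        assert errs[2] < errs[1] < errs[0]

    def test_functional_wrapper_and_summary(self, pair_system, no_noise):
        traces = [deconvolve_coculture(simulate_coculture_trace(
            pair_system, [0.005, 0.005], noise=no_noise, seed=0))]
        res = fit_lv_to_coculture(traces, self.baselines(pair_system),
                                  c0=(-1.0, -0.4))
        cmp = res.compare_cfsm(-1.26, -0.52)
        assert cmp["sign_agree_c12"] and cmp["sign_agree_c21"]
        assert "c12" in res.summary()
        assert max(res.rmse().values()) < 1e-4

    def test_guards(self, pair_system, no_noise):
        with pytest.raises(ParameterError):
            CocultureLV([], self.baselines(pair_system))
        tr = simulate_coculture_trace(pair_system, [0.005, 0.005],
                                      noise=no_noise, seed=0)
        with pytest.raises(ParameterError):
            CocultureLV([tr], self.baselines(pair_system))  # not deconvolved
        with pytest.raises(ParameterError):
            CocultureLV([deconvolve_coculture(tr)],
                        self.baselines(pair_system), free=("c13",))


class TestCompare:
    def test_self_comparison_is_near_zero_rmse(self, pair_system, no_noise):
        tr = deconvolve_coculture(simulate_coculture_trace(
            pair_system, [0.005, 0.005], noise=no_noise, seed=0))
        m = compare_model_experiment(tr, pair_system)
        assert m["rmse_od1"] < 1e-6 and m["rmse_od2"] < 1e-6
        assert m["sign_agree_1"] and m["sign_agree_2"]

    def test_perturbed_system_has_larger_rmse(self, pair_system, no_noise):
        tr = deconvolve_coculture(simulate_coculture_trace(
            pair_system, [0.005, 0.005], noise=no_noise, seed=0))
        worse = LVSystem(isolates=pair_system.isolates,
                         c=pair_system.c * 1.5)
        m0 = compare_model_experiment(tr, pair_system)
        m1 = compare_model_experiment(tr, worse)
        assert m1["rmse_od1"] > m0["rmse_od1"]
        assert m1["rmse_od2"] > m0["rmse_od2"]
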