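"""Synthetic data generators: determinism, noise-free exactness, and the
LV-consistent / LV-violating panel regimes."""

import numpy as np
import pytest

from lvcheck import (GrowthCurve, LogisticParams, LVSystem, NoiseModel,
                     ParameterError, deconvolve_coculture, gfp_to_od,
                     logistic_solution)
from lvcheck.simulate import (PanelSpec, conditioned_parameters,
                              demo_panel_isolates, generate_cfsm_panel,
                              simulate_coculture_trace,
                              simulate_monoculture_curve,
                              simulate_saturating_coculture)


class TestMonoculture:
    def test_noise_free_matches_closed_form(self, no_noise):
        p = LogisticParams(r=1.85, K=0.61, S0=0.005)
        cur = simulate_monoculture_curve(p, no_noise, duration=24, seed=0)
        ref = logistic_solution(p, cur.time)
        assert np.max(np.abs(cur.od - ref) / ref) < 1e-12
        assert cur.od[0] == p.S0
        # spot value at t = 2 h
        i = np.argmin(np.abs(cur.time - 2.0))
        assert cur.od[i] == pytest.approx(0.152823, abs=1e-6)

    def test_seed_determinism(self, std_noise):
        p = LogisticParams(r=1.56, K=0.35, S0=0.005, lag=2.25)
        a = simulate_monoculture_curve(p, std_noise, seed=42)
        b = simulate_monoculture_curve(p, std_noise, seed=42)
        assert np.array_equal(a.od, b.od)
        c = simulate_monoculture_curve(p, std_noise, seed=43)
        assert not np.array_equal(a.od, c.od)

    def test_floor_and_finiteness(self):
        noise = NoiseModel(multiplicative_sd=0.1, additive_sd=0.01,
                           detection_floor=0.001)
        p = LogisticParams(r=1.0, K=0.2, S0=0.002)
        cur = simulate_monoculture_curve(p, noise, seed=7)
        assert np.all(cur.od >= 0.001) and np.all(np.isfinite(cur.od))

    def test_bad_grid_rejected(self, no_noise):
        p = LogisticParams(r=1.0, K=0.2, S0=0.002)
        with pytest.raises(ParameterError):
            simulate_monoculture_curve(p, no_noise, sampling_interval=0.0)


class TestPanel:
    def make_spec(self, mode="none", seed=0, replicates=2):
        isolates, c = demo_panel_isolates(4, seed=seed)
        return PanelSpec(isolates=isolates, interactions=c,
                         violation_mode=mode, replicates=replicates, seed=seed)

    def test_lv_mode_preserves_ratio_exactly(self):
        spec = self.make_spec("none")
        rows = conditioned_parameters(spec)
        base = {p.name: p for p in spec.isolates}
        for row in rows:
            if not row["suppressed"]:
                b = base[row["focal"]]
                assert row["r"] / row["K"] == pytest.approx(b.r / b.K, rel=1e-12)

    def test_tradeoff_mode_anticorrelates(self):
        spec = self.make_spec("rate_yield_tradeoff")
        rows = [r for r in conditioned_parameters(spec) if not r["suppressed"]]
        for focal in {r["focal"] for r in rows}:
            sub = [r for r in rows if r["focal"] == focal]
            K = np.array([r["K"] for r in sub])
            r_ = np.array([r["r"] for r in sub])
            if np.ptp(K) > 1e-9:
                assert np.corrcoef(K, r_)[0, 1] < 0

    def test_shuffle_mode_permutes_K_within_focal(self):
        spec_lv = self.make_spec("none")
        spec_sh = self.make_spec("shuffled_K")
        lv = conditioned_parameters(spec_lv)
        sh = conditioned_parameters(spec_sh)
        for focal in {r["focal"] for r in lv}:
            k_lv = sorted(r["K"] for r in lv if r["focal"] == focal)
            k_sh = sorted(r["K"] for r in sh if r["focal"] == focal)
            assert np.allclose(k_lv, k_sh)

    def test_zero_interactions_match_fresh(self, no_noise):
        isolates, _ = demo_panel_isolates(3, seed=1)
        spec = PanelSpec(isolates=isolates, interactions=np.zeros((3, 3)),
                         replicates=1, seed=1)
        curves, _ = generate_cfsm_panel(spec, no_noise)
        by = {(c.meta["isolate"], c.meta["context"]): c for c in curves}
        for p in isolates:
            fresh = by[(p.name, "fresh")]
            for q in isolates:
                cfsm = by[(p.name, f"cfsm:{q.name}")]
                assert np.allclose(cfsm.od, fresh.od)

    def test_panel_determinism(self, std_noise):
        spec = self.make_spec(seed=3)
        a, _ = generate_cfsm_panel(spec, std_noise)
        b, _ = generate_cfsm_panel(spec, std_noise)
        assert all(np.array_equal(x.od, y.od) for x, y in zip(a, b))

    def test_od_never_nan_or_below_floor(self, std_noise):
        spec = self.make_spec(seed=5)
        curves, _ = generate_cfsm_panel(spec, std_noise)
        for c in curves:
            assert np.all(np.isfinite(c.od))
            assert np.all(c.od >= std_noise.detection_floor)

    def test_suppressed_interaction_yields_floor_curve(self, no_noise):
        iso = [LogisticParams(r=1.5, K=0.1, S0=0.005, name="a"),
               LogisticParams(r=1.0, K=0.5, S0=0.005, name="b")]
        c = np.array([[0.0, -1.0], [0.0, 0.0]])  # K_ab = 0.1 - 0.5 < 0
        spec = PanelSpec(isolates=iso, interactions=c, replicates=1, seed=0)
        curves, truth = generate_cfsm_panel(spec, no_noise)
        rec = [r for r in truth["conditioned"]
               if r["focal"] == "a" and r["context"] == "b"][0]
        assert rec["suppressed"]
        sup = [cu for cu in curves
               if cu.meta["isolate"] == "a" and cu.meta["context"] == "cfsm:b"][0]
        assert np.ptp(sup.od) == pytest.approx(0.0, abs=1e-12)


class TestCocultureTrace:
    def test_noise_free_channel_identity(self, pair_system, no_noise):
        tr = simulate_coculture_trace(pair_system, [0.005, 0.005],
                                      noise=no_noise, seed=0)
        od1 = gfp_to_od(tr.fluorescence)
        assert np.allclose(od1 + (tr.total_od - od1), tr.total_od)
        dec = deconvolve_coculture(tr)
        assert np.allclose(dec.od1 + dec.od2, tr.total_od, atol=1e-12)

    def test_absent_tagged_species_gives_flat_fluorescence(self, pair_system,
                                                           no_noise):
        from lvcheck import invert_gfp_calibration

        tr = simulate_coculture_trace(pair_system, [0.0, 0.005],
                                      noise=no_noise, seed=0)
        f0 = invert_gfp_calibration(0.0, extrapolate=True)
        assert np.allclose(tr.fluorescence, f0)

    def test_negative_inoculum_rejected(self, pair_system, no_noise):
        with pytest.raises(ParameterError):
            simulate_coculture_trace(pair_system, [-0.001, 0.005],
                                     noise=no_noise)

    def test_seed_determinism(self, pair_system, std_noise):
        a = simulate_coculture_trace(pair_system, [0.005, 0.005],
                                     noise=std_noise, seed=9)
        b = simulate_coculture_trace(pair_system, [0.005, 0.005],
                                     noise=std_noise, seed=9)
        assert np.array_equal(a.total_od, b.total_od)
        assert np.array_equal(a.fluorescence, b.fluorescence)

    def test_saturating_generator_departs_from_lv(self, pair_system, no_noise):
        lv = simulate_coculture_trace(pair_system, [0.005, 0.005],
                                      noise=no_noise, seed=0)
        sat = simulate_saturating_coculture(pair_system, [0.005, 0.005],
                                            noise=no_noise, seed=0)
        assert np.max(np.abs(lv.total_od - sat.total_od)) > 0.01
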