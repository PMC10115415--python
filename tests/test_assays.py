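import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyp33switch.assays import (ITCThermogram, ProgressCurve, TitrationSeries,
                                csp_combined, fit_itc, fit_ppiase,
                                fit_titration, itc_heats, ppiase_kobs,
                                predict_shift)
from cyp33switch.network import bound_fraction_1to1
from cyp33switch.synthetic_data import (ITCDesign, PPIaseDesign,
                                        TitrationDesign, gen_itc, gen_ppiase,
                                        gen_titration)

KD_GRID = [1.0, 10.0, 100.0, 1000.0]


class TestPredictShift:
    def test_no_ligand_gives_free_shift(self):
        assert predict_shift(100, 0, 300, 3.15, 3.12) == 3.15

    def test_saturation_approaches_bound_shift(self):
        assert predict_shift(0.01, 1e6, 30, 3.15, 3.12) == pytest.approx(
            3.12, abs=1e-6)

    def test_equimolar_bound_fraction(self):
        assert predict_shift(100, 100, 4, 0.0, 1.0) == pytest.approx(
            0.8190, abs=5e-5)

    @given(l1=st.floats(0, 1e4), l2=st.floats(0, 1e4))
    def test_monotone_and_bounded(self, l1, l2):
        lo, hi = sorted([l1, l2])
        s_lo = predict_shift(50, lo, 120, 3.15, 3.12)
        s_hi = predict_shift(50, hi, 120, 3.15, 3.12)
        assert 3.12 <= s_hi <= s_lo <= 3.15


class TestFitTitration:
    @pytest.mark.parametrize("kd", KD_GRID)
    def test_noiseless_self_inversion(self, kd):
        design = TitrationDesign()
        if kd >= 1000:
            design = design.widened(40.0)
        r = fit_titration(gen_titration(kd, design=design, sigma=0.0))
        assert r.converged
        assert r["kd"] == pytest.approx(kd, rel=1e-3)

    def test_flat_series_flagged_non_binding(self):
        s = TitrationSeries(p_total=100, l_totals=[0, 100, 200, 400, 800],
                            observed_shifts=[3.15] * 5, delta_free=3.15)
        r = fit_titration(s)
        assert "non-binding" in r.flags
        assert "kd" not in r.estimates

    def test_median_recovery_under_noise(self):
        kds = [fit_titration(gen_titration(300.0, seed=s))["kd"]
               for s in range(1, 21)]
        assert np.median(kds) == pytest.approx(300.0, rel=0.10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            TitrationSeries(p_total=100, l_totals=[0, 100, 200],
                            observed_shifts=[3.15, 3.14, 3.13], delta_free=3.15)


class TestCspCombined:
    @pytest.mark.parametrize("dh,dn,w,expect", [
        (0.0, 0.0, 0.2, 0.0),
        (0.1, 0.5, 0.2, 0.14142),   # sqrt(0.01 + 0.01)
        (-0.3, 0.0, 0.2, 0.3),
    ])
    def test_weighted_euclidean(self, dh, dn, w, expect):
        assert csp_combined(dh, dn, w) == pytest.approx(expect, abs=1e-5)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            csp_combined(0.1, 0.1, 0.0)


class TestItcHeats:
    GEOM = dict(cell_volume=200.0, cell_conc=50.0, syringe_conc=500.0,
                injection_volumes=np.full(20, 2.0))

    def test_zero_enthalpy_zero_heats(self):
        q = itc_heats(1.0, 30.0, 0.0, **self.GEOM)
        assert np.all(q == 0.0)

    def test_total_heat_at_saturation(self):
        # tight binding + large titrant excess: Σq ≈ n·ΔH·(cell moles)
        q = itc_heats(1.0, 0.001, -5.0, cell_volume=200.0, cell_conc=50.0,
                      syringe_conc=5000.0, injection_volumes=np.full(30, 2.0))
        # n·ΔH·V0·[cell] in μcal: -5 kcal/mol · 200 μL · 50 μM · 1e-3;
        # the 2 μL/200 μL displacement of the first injection costs ~1%
        assert float(np.sum(q)) == pytest.approx(-5.0 * 200.0 * 50.0 * 1e-3,
                                                 rel=0.015)

    def test_matches_per_injection_brute_force(self):
        n, kd, dh = 1.0, 30.0, -5.0
        q = itc_heats(n, kd, dh, **self.GEOM)
        # independent oracle: recompute each injection with the closed form
        v0, p, l, pl_prev = 200.0, 50.0, 0.0, 0.0
        for i, v in enumerate(np.full(20, 2.0)):
            d = 1 - v / v0
            p *= d
            l = l * d + 500.0 * v / v0
            pl = bound_fraction_1to1(n * p, l, kd) * n * p
            expect = dh * v0 * (pl - pl_prev * d) * 1e-3
            assert q[i] == pytest.approx(expect, rel=1e-12)
            pl_prev = pl


class TestFitItc:
    @pytest.mark.parametrize("kd", KD_GRID)
    def test_noiseless_self_inversion(self, kd):
        design = ITCDesign(cell_conc=max(10.0, kd), syringe_conc=10 * max(10.0, kd))
        r = fit_itc(gen_itc(1.0, kd, -5.0, design=design, sigma_frac=0.0))
        assert r.converged
        assert r["kd"] == pytest.approx(kd, rel=1e-3)
        assert r["n"] == pytest.approx(1.0, rel=1e-3)
        assert r["dH"] == pytest.approx(-5.0, rel=1e-3)

    def test_all_zero_heats_flagged(self):
        tg = ITCThermogram(cell_volume=200, cell_conc=50, syringe_conc=500,
                           injection_volumes=np.full(20, 2.0),
                           heats=np.zeros(20))
        r = fit_itc(tg)
        assert "non-binding" in r.flags

    def test_low_c_value_flagged(self):
        # kd far above cell concentration → c << 0.1 → low confidence
        r = fit_itc(gen_itc(1.0, 5e4, -5.0, sigma_frac=0.0))
        assert "low-confidence" in r.flags

    def test_median_recovery_under_noise(self):
        kds = [fit_itc(gen_itc(1.0, 30.0, -5.0, seed=s))["kd"]
               for s in range(1, 21)]
        assert np.median(kds) == pytest.approx(30.0, rel=0.15)

    def test_too_few_injections_rejected(self):
        tg = ITCThermogram(cell_volume=200, cell_conc=50, syringe_conc=500,
                           injection_volumes=np.full(5, 2.0),
                           heats=np.ones(5))
        with pytest.raises(ValueError):
            fit_itc(tg)


class TestPpiaseKobs:
    def test_no_enzyme_gives_background(self):
        assert ppiase_kobs(0.02, 150.3, 0.0, 50.0) == 0.02

    def test_hand_computed_rate(self):
        assert ppiase_kobs(0.02, 150.3, 0.04, 50.0) == pytest.approx(0.14024)

    def test_linearity_in_enzyme(self):
        k1 = ppiase_kobs(0.02, 150.3, 0.01, 50.0)
        k2 = ppiase_kobs(0.02, 150.3, 0.02, 50.0)
        assert k2 - 0.02 == pytest.approx(2 * (k1 - 0.02))


class TestFitPpiase:
    def test_noiseless_self_inversion(self):
        r = fit_ppiase(gen_ppiase(0.02, 150.3, sigma_frac=0.0))
        assert r["turnover"] == pytest.approx(150.3, rel=1e-3)
        assert r["k0"] == pytest.approx(0.02, rel=1e-3)

    def test_amplitude_rescaling_invariance(self):
        curves = gen_ppiase(0.02, 150.3, sigma_frac=0.0)
        scaled = [ProgressCurve(enzyme_conc=c.enzyme_conc,
                                substrate_cis0=c.substrate_cis0,
                                times=c.times, signal=c.signal * 37.5)
                  for c in curves]
        r1, r2 = fit_ppiase(curves), fit_ppiase(scaled)
        assert r2["turnover"] == pytest.approx(r1["turnover"], rel=1e-9)

    def test_identical_blank_curves_flag_no_catalysis(self):
        design = PPIaseDesign(enzyme_grid=(0.0, 0.01, 0.04))
        blank = gen_ppiase(0.02, 0.0, design=design, sigma_frac=0.0)
        r = fit_ppiase(blank)
        assert abs(r["turnover"]) < 1e-6
        assert "no-catalysis" in r.flags

    def test_mean_recovery_under_noise(self):
        tns = [fit_ppiase(gen_ppiase(0.02, 150.3, seed=s))["turnover"]
               for s in range(1, 21)]
        assert np.mean(tns) == pytest.approx(150.3, rel=0.10)

    def test_fewer_than_three_curves_rejected(self):
        curves = gen_ppiase(0.02, 150.3, sigma_frac=0.0)[:2]
        with pytest.raises(ValueError):
            fit_ppiase(curves)
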