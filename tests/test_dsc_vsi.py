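"""DSC conversion, bolus detection, BSW correction, CBV/VSI mapping."""

import numpy as np
import pytest

from tumoxmap import phantom
from tumoxmap.dsc_vsi import (
    BolusWindow,
    adc_from_dwi,
    bsw_leakage_correct,
    compute_cbv,
    delta_r2,
    detect_bolus,
    perfusion_pipeline,
    vessel_size_map,
)
from tumoxmap.phantom import NoiseSpec, PhantomSpec, build_phantom


def _perfusion(truth, dsc=None, dwi=None):
    dsc = dsc if dsc is not None else phantom.simulate_dsc(truth)
    dwi = dwi if dwi is not None else phantom.simulate_dwi(truth)
    ref = (
        truth.brain_mask
        & (truth.parameter_maps["CBV_true"] > 0)
        & (truth.parameter_maps["leakage_K2"] == 0)
    )
    return perfusion_pipeline(
        dsc, dwi, np.array([0.0, 10.0, 1000.0]),
        truth.region_mask("contra_WM"), brain_mask=truth.brain_mask, reference_mask=ref,
    )


class TestDeltaR2:
    def test_baseline_signal_gives_zero(self):
        s = np.full((2, 2, 2, 40), 100.0)
        out = delta_r2(s, (0, 10), te_ms=18.6)
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_one_over_te_arithmetic(self):
        s = np.full((1, 1, 1, 40), 100.0)
        s[..., 20] = 100.0 * np.exp(-1.0)
        out = delta_r2(s, (0, 10), te_ms=18.6)
        assert out[0, 0, 0, 20] == pytest.approx(1 / 0.0186, rel=1e-12)
        assert out[0, 0, 0, 20] == pytest.approx(53.76, abs=0.01)

    def test_discard_drops_leading_volumes(self):
        s = np.full((1, 1, 1, 44), 100.0)
        s[..., :4] = 1e6  # wild pre-steady-state values
        out = delta_r2(s, (0, 10), te_ms=18.6, n_discard=4)
        assert out.shape[-1] == 40
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_nonpositive_sample_interpolated(self):
        s = np.full((1, 1, 1, 40), 100.0)
        s[0, 0, 0, 15] = 0.0
        out = delta_r2(s, (0, 10), te_ms=18.6)
        assert np.isfinite(out[0, 0, 0, 15])
        assert out[0, 0, 0, 15] == pytest.approx(0.0, abs=1e-12)

    def test_phantom_curve_recovered(self, small_truth):
        dsc = phantom.simulate_dsc(small_truth)
        win_probe = delta_r2(dsc.gre, (0, 8), dsc.te_gre_ms, dsc.n_discard)
        vox = tuple(np.argwhere(small_truth.region_mask("contra_WM"))[0])
        times = np.arange(90) * 1.5
        g = phantom._gamma_variate(times, phantom.BolusShape())[4:]
        np.testing.assert_allclose(win_probe[vox], 12.0 * g, atol=1e-9)


class TestDetectBolus:
    @staticmethod
    def _curve(amplitude=20.0, n=80, tr=1.5):
        t = np.arange(n) * tr
        return amplitude * phantom._gamma_variate(t, phantom.BolusShape()), t

    def test_window_brackets_95pct_of_integral(self):
        c, t = self._curve()
        w = detect_bolus(c)
        total = np.trapezoid(c, t)
        inside = np.trapezoid(c[w.t_in : w.t_out + 1], t[w.t_in : w.t_out + 1])
        assert inside >= 0.95 * total

    def test_flat_curve_raises(self):
        with pytest.raises(ValueError, match="no bolus"):
            detect_bolus(np.zeros(60))

    def test_amplitude_invariance_of_entrance(self):
        c, _ = self._curve(amplitude=20.0)
        c2, _ = self._curve(amplitude=40.0)
        assert abs(detect_bolus(c).t_in - detect_bolus(c2).t_in) <= 1

    def test_window_ordering_validated(self):
        with pytest.raises(ValueError):
            BolusWindow(t_in=10, t_peak=5, t_out=20, baseline_range=(0, 8))


class TestBswCorrection:
    def test_zero_leakage_identity(self, small_truth):
        params = {
            k: (v if k != "enhancing" else phantom.RegionParams(
                v.R2prime, v.DBV, v.R2, v.S0, v.CBV_true, v.vessel_size_true, v.ADC, 0.0))
            for k, v in phantom.DEFAULT_REGION_PARAMS.items()
        }
        t = build_phantom(PhantomSpec(grid_shape=(20, 20, 20), region_params=params))
        dsc = phantom.simulate_dsc(t)
        d = delta_r2(dsc.gre, (0, 8), dsc.te_gre_ms, dsc.n_discard)
        w = detect_bolus(np.nanmean(d[t.brain_mask], axis=0))
        ref = t.brain_mask & (t.parameter_maps["CBV_true"] > 0)
        corrected, k1, k2 = bsw_leakage_correct(d, dsc.times_s, w, ref)
        m = t.brain_mask
        np.testing.assert_allclose(corrected[m], d[m], atol=1e-8)
        assert np.abs(k2[m]).max() < 1e-6

    def test_reference_mean_voxel_gets_k1_one_k2_zero(self):
        rng = np.random.default_rng(0)
        t = np.arange(60) * 1.5
        g = phantom._gamma_variate(t, phantom.BolusShape())
        d = np.empty((3, 1, 1, 60))
        d[0, 0, 0] = g
        d[1, 0, 0] = g
        d[2, 0, 0] = g  # every voxel identical to the reference mean
        w = detect_bolus(20 * g + rng.normal(0, 1e-9, 60))
        corrected, k1, k2 = bsw_leakage_correct(d, t, w, np.ones((3, 1, 1), bool))
        np.testing.assert_allclose(k1, 1.0, atol=1e-10)
        np.testing.assert_allclose(k2, 0.0, atol=1e-10)

    def test_leaky_voxels_recovered_within_2pct(self, small_truth):
        perf = _perfusion(small_truth)
        enh = small_truth.region_mask("enhancing")
        cbv_true = small_truth.parameter_maps["CBV_true"][enh]
        assert np.abs(perf.CBV[enh] - cbv_true).max() < 0.02 * cbv_true.max()
        assert np.all(perf.K2[enh] > 0.01)

    def test_degenerate_reference_raises(self):
        d = np.zeros((2, 1, 1, 60))
        w = BolusWindow(t_in=10, t_peak=15, t_out=25, baseline_range=(0, 8))
        with pytest.raises(ValueError, match="reference"):
            bsw_leakage_correct(d, np.arange(60) * 1.5, w, np.ones((2, 1, 1), bool))


class TestComputeCbv:
    def test_contra_wm_mean_exactly_one(self, small_truth):
        perf = _perfusion(small_truth)
        wm = small_truth.region_mask("contra_WM")
        assert perf.CBV[wm].mean() == pytest.approx(1.0, abs=1e-12)

    def test_known_relative_cbv_recovered(self):
        t = np.arange(80) * 1.5
        g = phantom._gamma_variate(t, phantom.BolusShape())
        d = np.stack([g[None, None, :], 2 * g[None, None, :]], axis=0)
        w = detect_bolus(20 * g)
        wm = np.zeros((2, 1, 1), bool)
        wm[0] = True
        cbv = compute_cbv(d, t, w, wm)
        assert cbv[1, 0, 0] == pytest.approx(2.0, abs=1e-3)

    def test_global_scaling_invariance(self, small_truth):
        dsc = phantom.simulate_dsc(small_truth)
        scaled = phantom.simulate_dsc(small_truth)
        scaled.gre = scaled.gre * 3.7
        scaled.se = scaled.se * 3.7
        a = _perfusion(small_truth, dsc=dsc)
        b = _perfusion(small_truth, dsc=scaled)
        m = small_truth.brain_mask
        np.testing.assert_allclose(a.CBV[m], b.CBV[m], rtol=1e-9)

    def test_empty_wm_mask_raises(self):
        d = np.ones((2, 2, 2, 60))
        w = BolusWindow(t_in=10, t_peak=15, t_out=25, baseline_range=(0, 8))
        with pytest.raises(ValueError, match="empty"):
            compute_cbv(d, np.arange(60) * 1.5, w, np.zeros((2, 2, 2), bool))


class TestAdc:
    def test_two_point_closed_form(self):
        s = np.array([100.0, 100.0 * np.exp(-1.0)])[None, None, None, :]
        adc = adc_from_dwi(s, np.array([0.0, 1000.0]))
        assert adc[0, 0, 0] == pytest.approx(1e-3, rel=1e-12)

    def test_noiseless_three_point_exact(self, small_truth):
        dwi = phantom.simulate_dwi(small_truth)
        adc = adc_from_dwi(dwi, np.array([0.0, 10.0, 1000.0]))
        m = small_truth.brain_mask
        np.testing.assert_allclose(adc[m], small_truth.parameter_maps["ADC"][m], rtol=1e-9)

    def test_csf_exceeds_tissue(self, small_truth):
        dwi = phantom.simulate_dwi(small_truth)
        adc = adc_from_dwi(dwi, np.array([0.0, 10.0, 1000.0]))
        csf = adc[small_truth.region_mask("CSF")].mean()
        for name in ("contra_GM", "contra_WM", "enhancing"):
            assert csf > adc[small_truth.region_mask(name)].mean()

    def test_b_values_validated(self):
        s = np.ones((1, 1, 1, 2))
        with pytest.raises(ValueError):
            adc_from_dwi(s, np.array([10.0, 1000.0]))


class TestVesselSize:
    def test_worked_arithmetic_example(self):
        vs = vessel_size_map(
            np.array([[[1.0]]]), np.array([[[1e-3]]]),
            np.array([[[30.0]]]), np.array([[[10.0]]]),
        )
        assert vs[0, 0, 0] == pytest.approx(26.0, abs=0.05)
        assert vs[0, 0, 0] == pytest.approx(0.867 * np.sqrt(1e-3) * 30 / 10**1.5 * 1000, rel=1e-12)

    def test_quadrupling_cbv_doubles_vessel_size(self):
        one = np.array([[[1.0]]])
        a = vessel_size_map(one, one * 1e-3, one * 30, one * 10)
        b = vessel_size_map(one * 4, one * 1e-3, one * 30, one * 10)
        assert b[0, 0, 0] == pytest.approx(2 * a[0, 0, 0], rel=1e-12)

    def test_nonpositive_se_peak_flagged(self):
        one = np.array([[[1.0]]])
        vs = vessel_size_map(one, one * 1e-3, one * 30, one * 0.0)
        assert np.isnan(vs[0, 0, 0])

    def test_phantom_round_trip_within_1pct(self, truth):
        perf = _perfusion(truth)
        for name in ("contra_GM", "contra_WM", "edema", "nonenhancing", "enhancing", "necrosis"):
            m = truth.region_mask(name)
            vs_t = truth.parameter_maps["vessel_size_true"][m]
            rel = np.abs(perf.vessel_size[m] - vs_t) / vs_t
            assert np.nanmax(rel) < 0.01, name


class TestBswBenefit:
    def test_corrected_rmse_beats_uncorrected_under_noise(self):
        wins = 0
        n_runs = 10
        for seed in range(n_runs):
            t = build_phantom(
                PhantomSpec(grid_shape=(16, 16, 16), noise=NoiseSpec(sigma=0.01), seed=seed)
            )
            dsc = phantom.simulate_dsc(t)
            d = delta_r2(dsc.gre, (0, 8), dsc.te_gre_ms, dsc.n_discard)
            w = detect_bolus(np.nanmean(d[t.brain_mask], axis=0))
            d = delta_r2(dsc.gre, w.baseline_range, dsc.te_gre_ms, dsc.n_discard)
            ref = t.brain_mask & (t.parameter_maps["CBV_true"] > 0) & (
                t.parameter_maps["leakage_K2"] == 0
            )
            corrected, _, _ = bsw_leakage_correct(d, dsc.times_s, w, ref)
            wm = t.region_mask("contra_WM")
            enh = t.region_mask("enhancing")
            cbv_t = t.parameter_maps["CBV_true"][enh]
            rmse_unc = np.sqrt(np.mean((compute_cbv(d, dsc.times_s, w, wm)[enh] - cbv_t) ** 2))
            rmse_cor = np.sqrt(
                np.mean((compute_cbv(corrected, dsc.times_s, w, wm)[enh] - cbv_t) ** 2)
            )
            wins += rmse_cor < rmse_unc
        assert wins == n_runs
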