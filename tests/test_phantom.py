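"""Phantom construction and forward-simulator contracts."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from tumoxmap import phantom, qbold
from tumoxmap.phantom import (
    DEFAULT_REGION_PARAMS,
    NoiseSpec,
    PhantomSpec,
    RegionParams,
    build_phantom,
    simulate_dwi,
    simulate_flair_ase,
    simulate_histology,
)
from tumoxmap.qbold import fit_loglinear

from conftest import make_noisy_truth


class TestBuildPhantom:
    def test_parameter_maps_match_region_params_exactly(self, truth):
        for name, rp in truth.provenance.region_params.items():
            m = truth.region_mask(name)
            assert m.any(), f"region {name} is empty"
            for p in phantom.PARAM_NAMES:
                assert np.all(truth.parameter_maps[p][m] == getattr(rp, p))

    def test_contra_gm_r2prime_painted(self, truth):
        gm = truth.region_mask("contra_GM")
        assert np.all(truth.parameter_maps["R2prime"][gm] == 5.13)
        assert np.all(truth.parameter_maps["DBV"][gm] == 0.043)

    def test_single_region_fills_grid(self):
        spec = PhantomSpec(region_params={"contra_WM": DEFAULT_REGION_PARAMS["contra_WM"]})
        t = build_phantom(spec)
        assert np.all(t.label_volume == t.labels["contra_WM"])

    def test_same_spec_bit_identical(self):
        spec = PhantomSpec(noise=NoiseSpec(sigma=0.02), seed=7)
        a, b = build_phantom(spec), build_phantom(spec)
        assert np.array_equal(a.label_volume, b.label_volume)
        sa = simulate_flair_ase(a)
        sb = simulate_flair_ase(b)
        assert np.array_equal(sa.data, sb.data)
        assert np.array_equal(simulate_dwi(a), simulate_dwi(b))
        da, db = phantom.simulate_dsc(a), phantom.simulate_dsc(b)
        assert np.array_equal(da.gre, db.gre) and np.array_equal(da.se, db.se)

    def test_missing_contra_wm_raises(self):
        params = {k: v for k, v in DEFAULT_REGION_PARAMS.items() if k != "contra_WM"}
        with pytest.raises(ValueError, match="contra_WM"):
            build_phantom(PhantomSpec(region_params=params))

    def test_tumor_regions_nested_and_disjoint(self, truth):
        ed = truth.region_mask("edema")
        enh = truth.region_mask("enhancing")
        nec = truth.region_mask("necrosis")
        assert not (ed & enh).any() and not (enh & nec).any() and not (ed & nec).any()
        # necrosis sits strictly inside the enhancing shell's bounding box
        for m_in, m_out in ((nec, enh), (enh, ed)):
            lo_in, hi_in = np.argwhere(m_in).min(0), np.argwhere(m_in).max(0)
            lo_out, hi_out = np.argwhere(m_out).min(0), np.argwhere(m_out).max(0)
            assert np.all(lo_out <= lo_in) and np.all(hi_in <= hi_out)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError, match="DBV"):
            RegionParams(4.0, 1.5, 12.0, 100.0, 1.0, 10.0, 1e-3).validate("x")
        with pytest.raises(ValueError, match="at least 16"):
            build_phantom(PhantomSpec(grid_shape=(8, 32, 32)))


class TestFlairAse:
    def test_tau0_is_pure_t2_decay(self, truth, ase):
        m = truth.brain_mask
        pm = truth.parameter_maps
        expected = pm["S0"][m] * np.exp(-pm["R2"][m] * ase.te_ms / 1000.0)
        np.testing.assert_allclose(ase.data[m, 0], expected, rtol=1e-12)

    def test_linear_branch_printed_values(self):
        # R2'=4 /s, DBV=0.05, tau=40 ms: ln S = ln S0 - R2*TE + 0.05 - 0.16
        rp = RegionParams(4.0, 0.05, 10.0, 100.0, 1.0, 10.0, 1e-3)
        t = build_phantom(PhantomSpec(region_params={"contra_WM": rp}))
        s = simulate_flair_ase(t, taus_ms=(0.0, 16.0, 40.0), te_ms=74.0)
        lnS = np.log(s.data[0, 0, 0])
        base = np.log(100.0) - 10.0 * 0.074
        assert lnS[0] == pytest.approx(base, abs=1e-12)
        assert lnS[2] == pytest.approx(base + 0.05 - 0.16, abs=1e-12)

    def test_linear_regime_strictly_decreasing(self, truth, ase):
        m = truth.brain_mask & (truth.parameter_maps["R2prime"] > 0)
        lin = ase.taus_ms >= 16.0
        diffs = np.diff(np.log(ase.data[m][:, lin]), axis=1)
        assert np.all(diffs < 0)

    def test_invalid_taus_rejected(self, truth):
        with pytest.raises(ValueError):
            simulate_flair_ase(truth, taus_ms=(0.0, -16.0, 20.0))

    def test_shifted_peak_mode_moves_argmax(self, truth):
        mask = truth.region_mask("edema")
        s = simulate_flair_ase(truth, shifted_peak_mask=mask, peak_shift_ms=28.0)
        peaks = s.taus_ms[np.argmax(s.data[mask], axis=-1)]
        assert np.all(peaks == 28.0)

    def test_rician_noise_keeps_magnitudes_nonnegative(self):
        t = make_noisy_truth(0.05, model="rician")
        s = simulate_flair_ase(t)
        assert np.all(s.data >= 0)


class TestDwi:
    def test_closed_forms(self, truth):
        dwi = simulate_dwi(truth, b_values=(0.0, 1000.0))
        m = truth.region_mask("contra_WM")
        ratio = dwi[m, 1] / dwi[m, 0]
        np.testing.assert_allclose(ratio, np.exp(-1000.0 * 0.7e-3), rtol=1e-12)
        dwi0 = simulate_dwi(truth, b_values=(0.0, 10.0, 1000.0))
        np.testing.assert_array_equal(dwi0[..., 0], np.where(truth.brain_mask,
                                                             truth.parameter_maps["S0"], 0.0))

    def test_negative_b_rejected(self, truth):
        with pytest.raises(ValueError):
            simulate_dwi(truth, b_values=(0.0, -10.0))


class TestDscSimulator:
    def test_zero_leakage_measured_equals_true(self):
        params = {
            k: (v if k != "enhancing" else RegionParams(
                v.R2prime, v.DBV, v.R2, v.S0, v.CBV_true, v.vessel_size_true, v.ADC, 0.0))
            for k, v in DEFAULT_REGION_PARAMS.items()
        }
        t0 = build_phantom(PhantomSpec(grid_shape=(20, 20, 20), region_params=params))
        dsc = phantom.simulate_dsc(t0)
        # with no leakage anywhere the GRE signal is exactly the gamma-variate
        # response: reconstruct it analytically for one enhancing voxel
        enh = np.argwhere(t0.region_mask("enhancing"))[0]
        times = np.arange(90) * 1.5
        g = phantom._gamma_variate(times, phantom.BolusShape())
        expected = 100.0 * np.exp(-1.78 * 12.0 * g * 0.0186)
        expected[:4] *= 1.1
        np.testing.assert_allclose(dsc.gre[tuple(enh)], expected, rtol=1e-10)

    def test_bolus_outside_window_rejected(self, small_truth):
        with pytest.raises(ValueError, match="bolus peak"):
            phantom.simulate_dsc(small_truth, n_volumes=30, bolus=phantom.BolusShape(t0_s=80.0))


class TestHistologySimulator:
    @staticmethod
    def _targets(truth, n=15, seed=0):
        from tumoxmap.targeting import BiopsyTarget

        rng = np.random.default_rng(seed)
        vox = np.argwhere(truth.region_mask("enhancing") | truth.region_mask("necrosis")
                          | truth.region_mask("nonenhancing"))
        pick = vox[rng.choice(len(vox), size=n, replace=False)]
        return [BiopsyTarget(center_voxel=tuple(map(int, v)), cluster_id=i,
                             defining_criteria=(("OEF", "high"),), priority_rank=i + 1)
                for i, v in enumerate(pick)]

    def test_zero_noise_gives_perfect_spearman(self, truth):
        tab = simulate_histology(truth, self._targets(truth), seed=3)
        pm = truth.parameter_maps
        oef = truth.oef_map
        vs = [pm["vessel_size_true"][t.center_voxel] for t in self._targets(truth)]
        cbv = [pm["CBV_true"][t.center_voxel] for t in self._targets(truth)]
        o = [oef[t.center_voxel] for t in self._targets(truth)]
        assert spearmanr(vs, tab.vessel_diameter_um).statistic == pytest.approx(1.0)
        assert spearmanr(cbv, tab.vessel_density).statistic == pytest.approx(1.0)
        assert spearmanr(o, tab.hif_score).statistic == pytest.approx(1.0)

    def test_null_coupling_mean_spearman_near_zero(self, truth):
        coupling = phantom.HistologyCoupling(strength=0.0, noise=1.0)
        targets = self._targets(truth, n=12)
        pm = truth.parameter_maps
        vs = [pm["vessel_size_true"][t.center_voxel] for t in targets]
        rs = []
        for seed in range(200):
            tab = simulate_histology(truth, targets, coupling=coupling, seed=seed)
            rs.append(spearmanr(vs, tab.vessel_diameter_um).statistic)
        assert abs(np.mean(rs)) < 0.05

    def test_single_target_row_complete(self, truth):
        tab = simulate_histology(truth, self._targets(truth, n=1))
        assert len(tab) == 1
        row = tab.iloc[0]
        assert row.vessel_diameter_um > 0 and 0 <= row.vessel_density <= 1
        assert 0 <= row.hif_score <= 300

    def test_empty_targets_rejected(self, truth):
        with pytest.raises(ValueError):
            simulate_histology(truth, [])


class TestNoiseScaling:
    def test_r2prime_rmse_nondecreasing_in_sigma(self):
        sigmas = [0.0, 0.005, 0.02, 0.05]
        rmses = []
        for sigma in sigmas:
            t = make_noisy_truth(sigma, seed=11)
            s = simulate_flair_ase(t)
            maps = fit_loglinear(s)
            gm = t.region_mask("contra_GM")
            assert gm.sum() >= 100
            err = maps.R2prime[gm] - 5.13
            rmses.append(np.sqrt(np.mean(err**2)))
        assert all(a <= b + 1e-12 for a, b in zip(rmses, rmses[1:]))
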