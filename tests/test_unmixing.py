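"""Spectral unmixing regression, parameter maps, ROI statistics, t-test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from burnhsi.spectra import AbsorbanceCube, ROI, unmixing_grid
from burnhsi.unmixing import (fit_absorbance_spectrum, estimate_concentration_maps,
                              hemoglobin_indices, roi_statistics, unpaired_t_test)


class TestFitAbsorbanceSpectrum:
    def test_exact_linear_combination_recovered(self, library):
        a = 0.7 * library.eps_hbo + 0.2 * library.eps_methb + 0.05
        res = fit_absorbance_spectrum(a, library)
        assert res.a_hbo == pytest.approx(0.7, abs=1e-9)
        assert res.a_met == pytest.approx(0.2, abs=1e-9)
        assert res.a_hbr == pytest.approx(0.0, abs=1e-9)
        assert res.a_mel == pytest.approx(0.0, abs=1e-9)
        assert res.a_0 == pytest.approx(0.05, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_zero_spectrum_gives_zero_everything(self, library):
        res = fit_absorbance_spectrum(np.zeros(14), library)
        assert np.allclose(res.as_array(), 0.0, atol=1e-12)
        assert np.allclose(res.residuals, 0.0)

    def test_matches_normal_equations_oracle(self, library):
        """OLS coefficients equal an independently coded normal-equations
        solve (X'X)^-1 X'y to 1e-10."""
        rng = np.random.default_rng(12)
        x = library.design_matrix()
        for _ in range(5):
            y = rng.normal(0.5, 0.2, 14)
            beta_oracle = np.linalg.solve(x.T @ x, x.T @ y)
            res = fit_absorbance_spectrum(y, library)
            assert np.allclose(res.as_array(), beta_oracle, atol=1e-10)
            assert np.allclose(res.residuals, y - x @ beta_oracle, atol=1e-10)

    def test_residuals_orthogonal_to_predictors(self, library):
        y = np.random.default_rng(1).normal(0.5, 0.3, 14)
        res = fit_absorbance_spectrum(y, library)
        assert np.allclose(library.design_matrix().T @ res.residuals, 0.0, atol=1e-8)

    def test_r2_degrades_monotonically_with_noise(self, library):
        """Average R-squared over 50 seeds decreases along a noise-SD ladder."""
        base = 0.5 * library.eps_hbo / library.eps_hbo.max() + 0.3
        sigmas = [0.0, 0.01, 0.03, 0.1]
        means = []
        for s in sigmas:
            r2s = []
            for seed in range(50):
                noisy = base + np.random.default_rng(seed).normal(0, s, 14)
                r2s.append(fit_absorbance_spectrum(noisy, library).r_squared)
            means.append(np.mean(r2s))
        assert all(means[i + 1] < means[i] + 1e-12 for i in range(len(means) - 1))

    def test_too_few_bands_rejected(self, library):
        with pytest.raises(ValueError, match="6 bands"):
            fit_absorbance_spectrum(np.zeros(14), library, window=(550, 590))


class TestHemoglobinIndices:
    def test_fifty_fifty_oxygenation(self):
        chbt, sto2, stmet, und = hemoglobin_indices(1.0, 1.0, 0.0)
        assert (chbt, sto2, stmet, und) == (2.0, 50.0, 0.0, False)

    def test_equal_thirds(self):
        chbt, sto2, stmet, _ = hemoglobin_indices(1.0, 1.0, 1.0)
        assert sto2 == pytest.approx(100 / 3)
        assert stmet == pytest.approx(100 / 3)

    def test_zero_total_flagged_undefined(self):
        chbt, sto2, stmet, und = hemoglobin_indices(0.0, 0.0, 0.0)
        assert chbt == 0.0 and sto2 == 0.0 and stmet == 0.0 and und

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hemoglobin_indices(-0.1, 0.0, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(chbo=st.floats(0, 100), chbr=st.floats(0, 100), cmethb=st.floats(0, 100))
    def test_identities_hold_for_any_nonnegative_inputs(self, chbo, chbr, cmethb):
        chbt, sto2, stmet, und = hemoglobin_indices(chbo, chbr, cmethb)
        assert chbt == chbo + chbr + cmethb
        if und:
            assert sto2 == 0.0 and stmet == 0.0
        else:
            assert 0.0 <= sto2 <= 100.0 and 0.0 <= stmet <= 100.0
            assert sto2 + stmet <= 100.0 + 1e-9
            assert sto2 * chbt == pytest.approx(100 * chbo, rel=1e-12, abs=1e-9)


class TestConcentrationMaps:
    def _uniform_cube(self, library, a_row, shape=(6, 5)):
        data = np.broadcast_to(a_row, shape + (14,)).copy()
        return AbsorbanceCube(data, library.grid)

    def test_uniform_cube_matches_single_spectrum(self, library, linear_surrogate_formulas):
        from burnhsi.synthetic import surrogate_absorbance
        a_row = surrogate_absorbance(np.array([0.0, 8.0, 4.0, 2.0]), library)
        cube = self._uniform_cube(library, a_row)
        maps = estimate_concentration_maps(cube, library, linear_surrogate_formulas)
        res = fit_absorbance_spectrum(a_row, library)
        vals, _, _ = linear_surrogate_formulas.evaluate(res.as_array())
        assert np.allclose(maps["chbo"], vals[1])
        assert np.allclose(maps["chbt"], vals[1:].sum())
        assert np.allclose(maps["r2"], 1.0)

    def test_noiseless_synthetic_cube_recovers_truth(self, library, linear_surrogate_formulas, scenario):
        from burnhsi.synthetic import generate_concentration_fields, generate_hyperspectral_cube
        from burnhsi.spectra import compute_reflectance, absorbance_from_reflectance
        bundle = generate_concentration_fields(scenario, 2, 1, seed=3, shape=(24, 24))
        raw, white = generate_hyperspectral_cube(bundle, mode="surrogate",
                                                 noise_sd=0.0, seed=4,
                                                 grid=library.grid, library=library)
        absorb = absorbance_from_reflectance(compute_reflectance(raw, white))
        maps = estimate_concentration_maps(absorb, library, linear_surrogate_formulas)
        err = np.abs(maps["chbt"] - bundle.fields["chbt"])
        assert np.quantile(err, 0.95) < 0.2

    def test_masked_pixel_propagates_to_all_maps(self, library, linear_surrogate_formulas):
        a_row = 0.3 * np.ones(14)
        cube = self._uniform_cube(library, a_row)
        cube.mask[2, 2] = False
        maps = estimate_concentration_maps(cube, library, linear_surrogate_formulas)
        for name in ("cm", "chbo", "chbr", "cmethb", "chbt", "sto2", "stmet", "r2"):
            assert np.isnan(maps[name][2, 2])
        assert not maps.mask[2, 2]

    def test_pixel_order_independence(self, library, linear_surrogate_formulas):
        rng = np.random.default_rng(8)
        data = rng.uniform(0.2, 1.0, (5, 4, 14))
        maps1 = estimate_concentration_maps(AbsorbanceCube(data, library.grid),
                                            library, linear_surrogate_formulas)
        perm = rng.permutation(20)
        shuffled = data.reshape(20, 14)[perm].reshape(5, 4, 14)
        maps2 = estimate_concentration_maps(AbsorbanceCube(shuffled, library.grid),
                                            library, linear_surrogate_formulas)
        unshuffled = np.empty_like(maps2["chbt"].ravel())
        unshuffled[perm] = maps2["chbt"].ravel()
        assert np.array_equal(unshuffled.reshape(5, 4), maps1["chbt"])

    def test_chbt_additivity_exact(self, library, linear_surrogate_formulas):
        rng = np.random.default_rng(9)
        data = rng.uniform(0.2, 1.0, (4, 4, 14))
        maps = estimate_concentration_maps(AbsorbanceCube(data, library.grid),
                                           library, linear_surrogate_formulas)
        total = maps["chbo"] + maps["chbr"] + maps["cmethb"]
        assert np.array_equal(total, maps["chbt"])


class TestROIStatistics:
    def test_constant_map(self):
        stats_ = roi_statistics(np.full((400, 400), 3.5), ROI(10, 10, 50, 50))
        assert stats_ == {"mean": 3.5, "sd": 0.0, "n": 2500}

    def test_full_330_roi_pixel_count(self):
        m = np.zeros((480, 640))
        out = roi_statistics(m, ROI.centered(m.shape))
        assert out["n"] == 108_900  # 330 x 330

    def test_checkerboard_mean(self):
        m = np.indices((40, 40)).sum(axis=0) % 2 * 2.0
        assert roi_statistics(m, ROI(0, 0, 40, 40))["mean"] == pytest.approx(1.0)

    def test_nan_pixels_excluded(self):
        m = np.ones((20, 20))
        m[0, 0] = np.nan
        out = roi_statistics(m, ROI(0, 0, 20, 20))
        assert out["n"] == 399

    def test_empty_roi_errors(self):
        m = np.full((10, 10), np.nan)
        with pytest.raises(ValueError, match="no valid"):
            roi_statistics(m, ROI(0, 0, 10, 10))


class TestUnpairedTTest:
    def test_identical_samples(self):
        out = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == 0.0 and out["p"] == pytest.approx(1.0)
        assert not out["significant"]

    def test_clear_shift_is_significant(self):
        out = unpaired_t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert out["p"] < 0.05 and out["significant"]

    def test_matches_textbook_formula(self):
        """Pooled-variance t and p match an independently coded closed form."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            a = rng.normal(0, 1, rng.integers(3, 9))
            b = rng.normal(0.5, 1.5, rng.integers(3, 9))
            na, nb = len(a), len(b)
            sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p_oracle = 2 * stats.t.sf(abs(t_oracle), na + nb - 2)
            out = unpaired_t_test(a, b)
            assert out["t"] == pytest.approx(t_oracle, abs=1e-10)
            assert out["p"] == pytest.approx(p_oracle, abs=1e-10)

    def test_welch_flag(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 4.0, 9.0]
        out = unpaired_t_test(a, b, welch=True)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert out["t"] == pytest.approx(ref.statistic)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t_test([1.0], [1.0, 2.0])
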