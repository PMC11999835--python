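"""PDS, SST and ATLD calibration-transfer estimators."""

import numpy as np
import pytest

import spectransfer as st
from spectransfer.transfer import (ATLDTransfer, PDSTransfer, SSTTransfer,
                                   cv_select_components, fit_atld, fit_pds,
                                   fit_sst, optimize_pds, resample_to_grid)


@pytest.fixture(scope="module")
def shifted_pair():
    """Default synthetic instrument shift, aligned to the common grid."""
    master, slave = st.generate_paired_sets(n_per_class=16, seed=21)
    grid = st.common_grid(master, slave)
    mm = st.resample_to_grid(master, grid)
    ss = st.resample_to_grid(slave, grid)
    split = st.spxy_split(mm.spectra, mm.labels, 32)
    std = split.train_indices[:15]
    held = split.prediction_indices
    return mm, ss, std, held


class TestResample:
    def test_identity_on_same_grid(self, paired_sets):
        master, _, grid = paired_sets
        again = resample_to_grid(master, grid)
        assert np.array_equal(again.spectra, master.spectra)

    def test_exact_for_linear_spectra(self):
        wl = np.arange(400.0, 500.0, 2.0)
        sset = st.SpectrumSet(wl, (0.001 * wl + 0.1)[None, :])
        target = np.linspace(405.0, 490.0, 37)
        out = resample_to_grid(sset, target)
        assert np.allclose(out.spectra[0], 0.001 * target + 0.1, atol=1e-12)

    def test_smooth_band_down_up_sampling_error_small(self):
        dense = np.arange(400.0, 600.0, 1.0)
        band = 0.5 - 0.1 * np.exp(-0.5 * ((dense - 500.0) / 20.0) ** 2)
        coarse_grid = np.arange(400.0, 596.0, 5.0)
        coarse = resample_to_grid(st.SpectrumSet(dense, band[None]), coarse_grid)
        back = resample_to_grid(coarse, np.arange(400.0, 591.0, 1.0))
        truth = 0.5 - 0.1 * np.exp(
            -0.5 * ((back.wavelengths_nm - 500.0) / 20.0) ** 2)
        # linear-interpolation curvature bound: h^2 max|f''| / 8 ~ 8e-4
        assert np.max(np.abs(back.spectra[0] - truth)) < 1e-3

    def test_extrapolation_rejected(self):
        sset = st.SpectrumSet(np.arange(400.0, 500.0, 5.0),
                              np.full((1, 20), 0.5))
        with pytest.raises(ValueError, match="extends beyond"):
            resample_to_grid(sset, np.arange(390.0, 480.0, 5.0))


class TestPDS:
    def test_identity_standards_give_identity_transfer(self, rng):
        X = rng.uniform(0.2, 0.8, size=(12, 20))
        res = fit_pds(X, X, w=0, n_components=1)
        assert np.allclose(res.transform(X), X, atol=1e-8)

    def test_gain_offset_closed_form(self, rng):
        Xm = rng.uniform(0.2, 0.8, size=(15, 10))
        Xs = 2.0 * Xm + 0.1
        res = fit_pds(Xm, Xs, w=0, n_components=1)
        for b, b0 in zip(res.coeffs, res.intercepts):
            assert b[0] == pytest.approx(0.5, abs=1e-9)
            assert b0 == pytest.approx(-0.05, abs=1e-9)

    def test_w0_single_component_equals_per_wavelength_ols(self, rng):
        Xm = rng.uniform(0.2, 0.8, size=(20, 12))
        Xs = Xm * rng.uniform(0.5, 1.5, 12) + 0.05 * rng.normal(size=Xm.shape)
        res = fit_pds(Xm, Xs, w=0, n_components=1)
        for i in range(12):
            slope, intercept = np.polyfit(Xs[:, i], Xm[:, i], 1)
            assert res.coeffs[i][0] == pytest.approx(slope, abs=1e-8)
            assert res.intercepts[i] == pytest.approx(intercept, abs=1e-8)

    def test_zero_input_returns_intercepts(self, rng):
        Xm = rng.uniform(0.2, 0.8, size=(10, 8))
        Xs = rng.uniform(0.2, 0.8, size=(10, 8))
        res = fit_pds(Xm, Xs, w=1, n_components=1)
        out = res.transform(np.zeros((1, 8)))
        assert np.allclose(out[0], res.intercepts)

    def test_training_rmse_not_worse_than_identity(self, shifted_pair):
        mm, ss, std, _ = shifted_pair
        res = fit_pds(mm.spectra[std], ss.spectra[std], w=2, n_components=3)
        rmse_t = np.sqrt(np.mean(
            (res.transform(ss.spectra[std]) - mm.spectra[std]) ** 2))
        rmse_raw = np.sqrt(np.mean((ss.spectra[std] - mm.spectra[std]) ** 2))
        assert rmse_t <= rmse_raw

    def test_wide_window_handles_wavelength_shift_better(self, shifted_pair):
        mm, ss, std, held = shifted_pair
        wide = fit_pds(mm.spectra[std], ss.spectra[std], w=12, n_components=6)
        narrow = fit_pds(mm.spectra[std], ss.spectra[std], w=0, n_components=1)
        err = lambda r: np.sqrt(np.mean(
            (r.transform(ss.spectra[held]) - mm.spectra[held]) ** 2))
        assert err(wide) <= err(narrow)

    def test_infeasible_component_count_rejected(self, rng):
        X = rng.uniform(size=(10, 8))
        with pytest.raises(ValueError, match="window"):
            PDSTransfer(X, X, window_halfwidth=0, n_components=2)
        with pytest.raises(ValueError, match="standards"):
            PDSTransfer(X[:3], X[:3], window_halfwidth=5, n_components=5)

    def test_optimizer_prefers_no_window_for_identical_instruments(self, rng):
        X = rng.uniform(0.2, 0.8, size=(10, 12))
        report = optimize_pds(X, X, w_grid=(0, 1, 2), component_grid=(1, 2))
        assert report.chosen == {"w": 0, "n_components": 1}
        best = report.cv_table.dropna()["rmse"].min()
        row = report.cv_table[
            (report.cv_table["w"] == 0) & (report.cv_table["n_components"] == 1)]
        assert float(row["rmse"].iloc[0]) <= best + 1e-9

    def test_optimizer_uses_window_for_shifted_spectra(self, shifted_pair):
        mm, ss, std, _ = shifted_pair
        report = optimize_pds(mm.spectra[std[:10]], ss.spectra[std[:10]],
                              w_grid=(0, 2, 5), component_grid=(1, 3))
        assert report.chosen["w"] > 0


class TestSST:
    def test_identical_standards_give_identity_matrix(self, rng):
        X = rng.uniform(0.2, 0.8, size=(12, 15))
        res = fit_sst(X, X, n_components=5)
        assert np.abs(res.F - np.eye(15)).max() < 1e-8

    def test_per_band_gain_recovered_exactly(self, rng):
        Xm = rng.uniform(0.2, 0.8, size=(20, 10))
        Xs = Xm * np.linspace(0.5, 2.0, 10)
        res = fit_sst(Xm, Xs, n_components=10)
        assert np.allclose(res.transform(Xs), Xm, atol=1e-6)

    def test_rank_one_standards_reconstructed(self):
        t = np.linspace(1.0, 2.0, 8)[:, None]
        profile_m = np.linspace(0.2, 0.6, 12)[None, :]
        profile_s = np.linspace(0.3, 0.5, 12)[None, :]
        Xm, Xs = t @ profile_m, t @ profile_s
        res = fit_sst(Xm, Xs, n_components=1)
        assert np.allclose(res.transform(Xs), Xm, atol=1e-8)

    def test_transform_is_affine(self, rng):
        Xm = rng.uniform(0.2, 0.8, size=(15, 10))
        Xs = rng.uniform(0.2, 0.8, size=(15, 10))
        res = fit_sst(Xm, Xs, n_components=4)
        x1, x2 = rng.uniform(size=(2, 10))
        a = 0.3
        mix = res.transform((a * x1 + (1 - a) * x2)[None])
        parts = a * res.transform(x1[None]) + (1 - a) * res.transform(x2[None])
        assert np.allclose(mix, parts, atol=1e-10)

    def test_idempotent_when_instruments_match(self, rng):
        X = rng.uniform(0.2, 0.8, size=(12, 15))
        res = fit_sst(X, X, n_components=5)
        once = res.transform(X)
        twice = res.transform(once)
        assert np.abs(twice - once).max() < 1e-6

    def test_reduces_angle_on_synthetic_shift(self, shifted_pair):
        mm, ss, std, held = shifted_pair
        res = fit_sst(mm.spectra[std[:10]], ss.spectra[std[:10]], 6)
        before = st.spectral_angle(mm.spectra[held],
                                   ss.spectra[held]).mean_angle_deg
        after = st.spectral_angle(mm.spectra[held],
                                  res.transform(ss.spectra[held])).mean_angle_deg
        assert after < before

    def test_excessive_components_rejected(self, rng):
        X = rng.uniform(size=(6, 10))
        with pytest.raises(ValueError, match="n_components"):
            SSTTransfer(X, X, n_components=6)


class TestATLD:
    def _trilinear(self, seed=3, I=10, J=30):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(I, 2))
        B = rng.normal(size=(J, 2))
        C = np.abs(rng.normal(size=(2, 2))) + 0.5
        X = np.einsum("in,jn,kn->ijk", A, B, C)
        return A, B, C, X

    def test_exact_recovery_of_noiseless_rank2_tensor(self):
        _, B, _, X = self._trilinear()
        res = fit_atld(X[:, :, 0], X[:, :, 1], n_factors=2)
        assert res.relative_error < 1e-8
        # factor congruence up to permutation/scaling
        for n in range(2):
            congruence = max(
                abs(np.dot(res.B[:, j], B[:, n]))
                / (np.linalg.norm(res.B[:, j]) * np.linalg.norm(B[:, n]))
                for j in range(2)
            )
            assert congruence > 0.999

    def test_objective_monotonically_nonincreasing(self):
        _, _, _, X = self._trilinear(seed=9)
        noisy0 = X[:, :, 0] + 0.01 * np.random.default_rng(0).normal(size=X[:, :, 0].shape)
        res = fit_atld(noisy0, X[:, :, 1], n_factors=2)
        assert np.all(np.diff(res.error_history) <= 1e-9)

    def test_identical_instruments_give_identity_transfer(self, rng):
        X = rng.uniform(0.2, 0.8, size=(10, 20))
        res = fit_atld(X, X, n_factors=2)
        assert np.allclose(res.C[0], res.C[1])
        assert np.allclose(res.transform(X), X, atol=1e-8)

    def test_transform_preserves_shape_and_reduces_angle(self, shifted_pair):
        mm, ss, std, held = shifted_pair
        res = fit_atld(mm.spectra[std], ss.spectra[std], n_factors=2)
        out = res.transform(ss.spectra[held])
        assert out.shape == ss.spectra[held].shape
        before = st.spectral_angle(mm.spectra[held],
                                   ss.spectra[held]).mean_angle_deg
        after = st.spectral_angle(mm.spectra[held], out).mean_angle_deg
        assert after < before

    def test_round_trip_angle_change_below_one_degree(self, shifted_pair):
        mm, ss, std, _ = shifted_pair
        res = fit_atld(mm.spectra[std], ss.spectra[std], n_factors=2)
        forward = res.transform(ss.spectra[std], 2, 1)
        back = res.transform(forward, 1, 2)
        assert st.spectral_angle(ss.spectra[std], back).mean_angle_deg < 1.0

    def test_invalid_instrument_index_rejected(self, rng):
        X = rng.uniform(size=(8, 10))
        res = fit_atld(X, X, n_factors=1)
        with pytest.raises(ValueError, match="1 or 2"):
            res.transform(X, from_instrument=3)

    def test_unidentifiable_factor_count_rejected(self, rng):
        X = rng.uniform(size=(4, 10))
        with pytest.raises(ValueError, match="n_factors"):
            ATLDTransfer(X, X, n_factors=5)


class TestComponentSelection:
    def test_identical_instruments_tie_break_to_smallest(self, rng):
        X = rng.uniform(0.2, 0.8, size=(15, 10))
        report = cv_select_components("sst", X, X, range(1, 5), seed=0)
        assert report.chosen == {"n_components": 1}
        assert np.all(report.cv_table["rmse"].dropna() < 1e-6)

    def test_chosen_value_is_table_argmin(self, shifted_pair):
        mm, ss, std, _ = shifted_pair
        report = cv_select_components("sst", mm.spectra[std], ss.spectra[std],
                                      range(1, 8), seed=1)
        table = report.cv_table.dropna()
        best = table.loc[table["rmse"].idxmin(), "n_components"]
        assert report.chosen["n_components"] == int(best)

    def test_rank_two_instrument_difference_selects_two_factors(self, rng):
        A = rng.uniform(0.5, 1.5, size=(20, 2))
        B = np.column_stack([
            0.5 + 0.2 * np.sin(np.linspace(0, 3, 25)),
            0.4 + 0.2 * np.cos(np.linspace(0, 3, 25)),
        ])
        Xm = A @ np.diag([1.0, 1.0]) @ B.T
        Xs = A @ np.diag([1.5, 0.6]) @ B.T
        report = cv_select_components("atld", Xm, Xs, (1, 2, 3), seed=0)
        assert report.chosen["n_factors"] == 2

    def test_common_contract_all_methods_improve_on_shift(self, shifted_pair):
        mm, ss, std, held = shifted_pair
        before = st.spectral_angle(mm.spectra[held],
                                   ss.spectra[held]).mean_angle_deg
        fits = [
            fit_pds(mm.spectra[std], ss.spectra[std], 12, 6),
            fit_sst(mm.spectra[std[:10]], ss.spectra[std[:10]], 6),
            fit_atld(mm.spectra[std], ss.spectra[std], 2),
        ]
        for res in fits:
            after = st.spectral_angle(
                mm.spectra[held], res.transform(ss.spectra[held])).mean_angle_deg
            assert after < before
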