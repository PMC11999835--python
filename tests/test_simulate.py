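"""Synthetic meat spectra and instrument-observation model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import spectransfer as st
from spectransfer.simulate import (InstrumentModel, MeatClassModel,
                                   default_class_models, default_master,
                                   default_slave)

GRID_400_800 = np.arange(400.0, 800.0 + 1e-9, 0.5)


def _noise_free(model: MeatClassModel) -> MeatClassModel:
    from dataclasses import replace

    return replace(model, within_class_sd=0.0)


class TestLatentSpectra:
    def test_oxymyoglobin_band_is_a_local_minimum(self):
        chicken = _noise_free(default_class_models()["chicken"])
        sset = st.generate_latent_spectra(chicken, 1, GRID_400_800, seed=0)
        wl, r = sset.wavelengths_nm, sset.spectra[0]
        window = (wl >= 520) & (wl <= 560)
        min_wl = wl[window][np.argmin(r[window])]
        assert abs(min_wl - 540.0) <= 5.0

    def test_beef_metmyoglobin_dip_absent_from_chicken(self):
        models = default_class_models()
        beef = st.generate_latent_spectra(_noise_free(models["beef"]), 1,
                                          GRID_400_800, seed=0).spectra[0]
        chicken = st.generate_latent_spectra(_noise_free(models["chicken"]), 1,
                                             GRID_400_800, seed=0).spectra[0]

        def depth_at_630(r):
            wl = GRID_400_800
            # dip depth relative to the local baseline 610/655 nm endpoints
            i0, i1, ic = (np.argmin(np.abs(wl - v)) for v in (610, 655, 630))
            return (r[i0] + r[i1]) / 2 - r[ic]

        assert depth_at_630(beef) > 0.02
        assert depth_at_630(chicken) < 0.005

    def test_reflectance_bounds_and_determinism(self):
        beef = default_class_models()["beef"]
        a = st.generate_latent_spectra(beef, 10, seed=42)
        b = st.generate_latent_spectra(beef, 10, seed=42)
        assert np.array_equal(a.spectra, b.spectra)
        assert a.spectra.min() >= 0.0 and a.spectra.max() <= 1.0

    def test_band_center_outside_grid_rejected(self):
        model = MeatClassModel("x", 0.5, bands=((790.0, 0.1, 5.0),))
        with pytest.raises(ValueError, match="outside latent grid"):
            st.generate_latent_spectra(model, 1, np.arange(400, 700, 0.5))

    @given(
        baseline=hst.floats(0.2, 0.9),
        depth=hst.floats(0.0, 0.2),
        sd=hst.floats(0.0, 0.2),
        seed=hst.integers(0, 2**16),
    )
    @settings(max_examples=25, deadline=None)
    def test_any_valid_model_stays_in_unit_interval(self, baseline, depth, sd, seed):
        model = MeatClassModel("x", baseline, 1e-4, ((540.0, depth, 10.0),), sd)
        sset = st.generate_latent_spectra(model, 5, seed=seed)
        assert np.all(sset.spectra >= 0.0) and np.all(sset.spectra <= 1.0)


class TestApplyInstrument:
    def _latent(self, n=3, seed=0):
        return st.generate_latent_spectra(
            default_class_models()["duck"], n, GRID_400_800, seed=seed)

    def test_identity_instrument_reproduces_input(self):
        latent = self._latent()
        ident = InstrumentModel("id", GRID_400_800, fwhm_nm=1e-6)
        out = st.apply_instrument(latent, ident)
        assert np.allclose(out.spectra, latent.spectra, atol=1e-6)

    def test_gain_scales_convolved_signal(self):
        latent = self._latent()
        grid = np.arange(420.0, 780.0 + 1e-9, 5.0)
        base = InstrumentModel("s", grid, fwhm_nm=5.0)
        doubled = InstrumentModel("s", grid, fwhm_nm=5.0, gain=2.0)
        assert np.allclose(st.apply_instrument(latent, doubled).spectra,
                           2.0 * st.apply_instrument(latent, base).spectra)

    def test_constant_spectrum_passes_through_convolution(self):
        flat = st.SpectrumSet(GRID_400_800,
                              np.full((1, GRID_400_800.size), 0.5))
        instr = InstrumentModel("s", np.arange(420.0, 780.0, 5.0),
                                fwhm_nm=8.0, offset=0.1)
        out = st.apply_instrument(flat, instr)
        assert np.allclose(out.spectra, 0.6)

    def test_uncovered_grid_raises_with_range(self):
        latent = self._latent()
        instr = InstrumentModel("s", np.arange(350.0, 700.0, 5.0), fwhm_nm=5.0)
        with pytest.raises(ValueError, match="latent grid only covers"):
            st.apply_instrument(latent, instr)


class TestPairedSets:
    def test_sample_count_and_alignment(self):
        master, slave = st.generate_paired_sets(n_per_class=48, seed=0)
        assert master.n_samples == slave.n_samples == 144
        assert np.array_equal(master.labels, slave.labels)
        assert np.array_equal(master.sample_ids, slave.sample_ids)

    def test_equal_instruments_give_equal_views(self):
        instr = default_slave(noise_sd=0.0)
        m, s = st.generate_paired_sets(n_per_class=4, master=instr,
                                       slave=instr, seed=3)
        assert np.array_equal(m.spectra, s.spectra)

    def test_between_class_angle_exceeds_within_class(self):
        master, _ = st.generate_paired_sets(n_per_class=50, seed=9)
        X, lab = master.spectra, master.labels
        ch, bf = X[lab == "chicken"], X[lab == "beef"]
        within = st.spectral_angle(ch[:25], ch[25:]).mean_angle_deg
        between = st.spectral_angle(ch[:25], bf[:25]).mean_angle_deg
        assert between > within

    def test_default_instrument_shift_magnitude(self):
        master, slave = st.generate_paired_sets(n_per_class=34, seed=5)
        grid = st.common_grid(master, slave)
        mm = st.resample_to_grid(master, grid)
        ss = st.resample_to_grid(slave, grid)
        assert st.spectral_angle(mm.spectra, ss.spectra).mean_angle_deg > 5.0

        same = default_slave(noise_sd=0.0)
        m2, s2 = st.generate_paired_sets(n_per_class=10, master=same,
                                         slave=same, seed=5)
        assert st.spectral_angle(m2.spectra, s2.spectra).mean_angle_deg < 0.1


class TestSplicedCube:
    def test_equal_ratio_proportions(self):
        cube = st.generate_spliced_cube(proportions=(1, 1, 1), shape=(60, 60),
                                        seed=0)
        assert np.all(np.abs(cube.truth_proportions - 1 / 3) <= 1 / 3600 + 1e-12)

    def test_beef_heavy_ratio(self):
        cube = st.generate_spliced_cube(proportions=(2, 1, 1), shape=(60, 60),
                                        seed=0)
        beef_idx = cube.class_order.index("beef")
        assert cube.truth_proportions[beef_idx] == pytest.approx(0.5)

    def test_truth_map_counts_match_reported_proportions(self):
        cube = st.generate_spliced_cube(proportions=(0.5, 1, 2), shape=(24, 30),
                                        seed=1)
        counts = np.bincount(cube.truth_map.ravel(), minlength=3)
        assert np.array_equal(counts / counts.sum(), cube.truth_proportions)

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError, match="16x16"):
            st.generate_spliced_cube(shape=(8, 8))

    def test_vanishing_class_region_rejected(self):
        with pytest.raises(ValueError, match="no pixels"):
            st.generate_spliced_cube(proportions=(1e-6, 1, 1), shape=(16, 16))

    def test_checkerboard_layout_covers_all_classes(self):
        cube = st.generate_spliced_cube(proportions=(1, 1, 1), shape=(32, 32),
                                        seed=2, layout="checkerboard")
        assert set(np.unique(cube.truth_map)) == {0, 1, 2}


class TestInterchange:
    def test_spectrum_set_csv_round_trip(self, tmp_path):
        master, _ = st.generate_paired_sets(n_per_class=3, seed=8)
        path = tmp_path / "spectra.csv"
        master.to_csv(path)
        back = st.SpectrumSet.from_csv(path)
        assert np.allclose(back.wavelengths_nm, master.wavelengths_nm, atol=1e-9)
        assert np.allclose(back.spectra, master.spectra, atol=1e-9)
        assert np.array_equal(back.labels, master.labels)

    def test_hypercube_envi_round_trip(self, tmp_path):
        cube = st.generate_spliced_cube(proportions=(1, 1, 1), shape=(16, 20),
                                        seed=4)
        cube.to_envi(tmp_path / "cube")
        back = st.HyperCube.from_envi(tmp_path / "cube.hdr")
        assert np.allclose(back.data, cube.data, atol=1e-6)
        assert np.allclose(back.wavelengths_nm, cube.wavelengths_nm, atol=1e-5)
        assert np.array_equal(back.truth_map, cube.truth_map)
        assert back.class_order == cube.class_order
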