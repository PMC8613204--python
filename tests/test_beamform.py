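"""DICS localization, map post-processing and LCMV reconstruction against
simulated ground truth on the spherical head model."""

import numpy as np
import pytest

from cmc.beamform import (csd_matrix, dics_scan, smooth_map, threshold_map,
                          postprocess_maps, band_covariance, lcmv_virtual_electrode,
                          map_to_nifti, map_table, DICSMap)
from cmc.spectra import estimate_spectra, coherence, confidence_limit, band_mask
from cmc.synthetic import SimulationConfig, simulate_dataset, SourceGrid
from cmc.preprocess import Recording, epoch_and_normalize, segment_record


def simulate_and_segment(leadfield, **kwargs):
    cfg = SimulationConfig(**kwargs)
    ds = simulate_dataset(leadfield, cfg)
    eeg_seg = segment_record(Recording(ds.eeg, cfg.fs, ds.channel_labels))
    emg_seg = epoch_and_normalize(Recording(ds.emg[None], cfg.fs, ("EMG",)))
    return ds, eeg_seg.segments, emg_seg.segments[0]


@pytest.fixture(scope="module")
def coherent_scene(sphere_leadfield):
    src = 431
    ds, eeg, emg = simulate_and_segment(sphere_leadfield, duration=120.0,
                                        delay=25.0, coupling_gain=0.8,
                                        source_index=src, seed=7, sensor_snr=5.0)
    csd = csd_matrix(eeg, emg, 256.0, (15.0, 30.0))
    return ds, eeg, emg, csd, src


class TestCSDMatrix:
    def test_hermitian(self, coherent_scene):
        _, _, _, csd, _ = coherent_scene
        assert np.max(np.abs(csd.C - csd.C.conj().T)) < 1e-9 * np.max(np.abs(csd.C))

    def test_diagonal_matches_band_mean_auto_spectrum(self, coherent_scene):
        _, eeg, _, csd, _ = coherent_scene
        for ch in (0, 13, 40):
            sp = estimate_spectra(eeg[ch], eeg[ch], 256.0)
            sel = band_mask(sp.freqs, (15.0, 30.0))
            assert csd.C[ch, ch].real == pytest.approx(sp.f_xx[sel].mean(), rel=1e-9)

    def test_duplicated_channel_block_rank_one(self, coherent_scene):
        _, eeg, emg, _, _ = coherent_scene
        dup = np.concatenate([eeg[:2], eeg[1:2]], axis=0)
        csd = csd_matrix(dup, emg, 256.0)
        block = csd.C[1:3, 1:3]
        s = np.linalg.svd(block, compute_uv=False)
        assert s[1] < 1e-9 * s[0]

    def test_segment_mismatch_rejected(self, coherent_scene):
        _, eeg, emg, _, _ = coherent_scene
        with pytest.raises(ValueError, match="mismatch"):
            csd_matrix(eeg[:, :-1, :], emg, 256.0)


class TestDICSScan:
    def test_localizes_single_coherent_source(self, coherent_scene, sphere_leadfield):
        _, _, _, csd, src = coherent_scene
        m = dics_scan(csd, sphere_leadfield, 0.05)
        k = int(np.argmax(m.values))
        err = np.linalg.norm(sphere_leadfield.grid.positions[k]
                             - sphere_leadfield.grid.positions[src])
        assert err <= sphere_leadfield.grid.spacing

    def test_values_within_unit_interval(self, coherent_scene, sphere_leadfield):
        _, _, _, csd, _ = coherent_scene
        m = dics_scan(csd, sphere_leadfield, 0.05)
        assert np.all(m.values >= 0) and np.all(m.values <= 1)

    def test_null_map_below_corrected_confidence_limit(self, sphere_leadfield):
        _, eeg, emg, = simulate_and_segment(sphere_leadfield, duration=120.0,
                                            coupling_gain=0.0, source_index=431,
                                            seed=19)[0:3]
        csd = csd_matrix(eeg, emg, 256.0)
        m = dics_scan(csd, sphere_leadfield, 0.05)
        assert m.values.max() < confidence_limit(0.0033, csd.n_segments)

    def test_singular_csd_without_regularization_rejected(self, sphere_leadfield):
        # rank-deficient CSD (fewer segments than channels) needs reg > 0
        _, eeg, emg = simulate_and_segment(sphere_leadfield, duration=10.0,
                                           coupling_gain=0.8, source_index=431, seed=3)
        csd = csd_matrix(eeg[:, :2, :], emg[:2], 256.0)
        with pytest.raises(np.linalg.LinAlgError, match="reg"):
            dics_scan(csd, sphere_leadfield, 0.0)

    def test_channel_count_mismatch_rejected(self, coherent_scene, random_leadfield):
        _, _, _, csd, _ = coherent_scene
        with pytest.raises(ValueError, match="channel"):
            dics_scan(csd, random_leadfield)


class TestMapPostprocessing:
    def _map(self, grid, values):
        return DICSMap(grid=grid, values=values, band=(15.0, 30.0), reg_fraction=0.05)

    def test_constant_map_thresholds_to_zero(self):
        grid = SourceGrid.regular((4, 4, 4), 5.0)
        m = threshold_map(self._map(grid, np.full(64, 0.3)))
        assert np.all(m.values == 0)

    def test_impulse_smoothing_preserves_mass(self):
        grid = SourceGrid.regular((15, 15, 15), 5.0)
        vals = np.zeros(grid.n_sources)
        vals[grid.nearest((35, 35, 35))[0]] = 1.0
        sm = smooth_map(self._map(grid, vals), fwhm_mm=10.0)
        assert sm.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_grand_average_of_identical_maps_is_idempotent(self):
        grid = SourceGrid.regular((6, 6, 6), 5.0)
        rng = np.random.default_rng(0)
        m = self._map(grid, rng.uniform(0, 0.5, grid.n_sources))
        processed, ga = postprocess_maps([m, m, m])
        np.testing.assert_allclose(ga.values, processed[0].values, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        m1 = self._map(SourceGrid.regular((3, 3, 3), 5.0), np.zeros(27))
        m2 = self._map(SourceGrid.regular((4, 3, 3), 5.0), np.zeros(36))
        with pytest.raises(ValueError, match="grid"):
            postprocess_maps([m1, m2])

    def test_nifti_export_preserves_geometry(self):
        grid = SourceGrid.regular((4, 5, 6), 5.0, origin=(-10, 0, 30))
        rng = np.random.default_rng(1)
        img = map_to_nifti(self._map(grid, rng.uniform(0, 1, grid.n_sources)))
        assert img.shape == (4, 5, 6)
        np.testing.assert_allclose(img.affine[:3, 3], (-10, 0, 30))
        np.testing.assert_allclose(np.diag(img.affine)[:3], 5.0)

    def test_map_table_columns(self):
        grid = SourceGrid.regular((3, 3, 3), 5.0)
        tab = map_table(self._map(grid, np.zeros(27)))
        assert list(tab.columns) == ["x", "y", "z", "value"]


class TestLCMV:
    def test_noise_free_source_recovered_exactly(self, sphere_leadfield):
        grid = sphere_leadfield.grid
        cfg = SimulationConfig(duration=30.0, delay=0.0, coupling_gain=1.0,
                               source_index=431, sensor_snr=None,
                               emg_noise_snr=None, seed=5)
        ds = simulate_dataset(sphere_leadfield, cfg)
        cov = band_covariance(ds.eeg, 256.0, None)
        ve = lcmv_virtual_electrode(ds.eeg, cov, sphere_leadfield,
                                    grid.positions[431], 0.05)
        r = np.corrcoef(ve.timeseries, ds.source)[0, 1]
        assert abs(r) >= 0.999

    def test_unit_gain_constraint(self, sphere_leadfield):
        grid = sphere_leadfield.grid
        cfg = SimulationConfig(duration=20.0, coupling_gain=0.8, source_index=431, seed=6)
        ds = simulate_dataset(sphere_leadfield, cfg)
        cov = band_covariance(ds.eeg, 256.0)
        ve = lcmv_virtual_electrode(ds.eeg, cov, sphere_leadfield, grid.positions[100])
        assert ve.weights @ sphere_leadfield.column(100) == pytest.approx(1.0, abs=1e-9)

    def test_position_outside_grid_rejected(self, sphere_leadfield):
        cfg = SimulationConfig(duration=10.0, source_index=431, seed=6)
        ds = simulate_dataset(sphere_leadfield, cfg)
        cov = band_covariance(ds.eeg, 256.0)
        with pytest.raises(ValueError, match="grid"):
            lcmv_virtual_electrode(ds.eeg, cov, sphere_leadfield, (500.0, 500, 500))

    def test_virtual_electrode_beats_best_scalp_channel(self, coherent_scene,
                                                        sphere_leadfield):
        from cmc.spectra import band_summary
        ds, eeg_seg, emg_seg, csd, src = coherent_scene
        cov = band_covariance(ds.eeg, 256.0, (15.0, 30.0))
        ve = lcmv_virtual_electrode(ds.eeg, cov, sphere_leadfield,
                                    sphere_leadfield.grid.positions[src], 0.05)
        ve_seg = epoch_and_normalize(Recording(ve.timeseries[None], 256.0, ("VE",)))
        coh_ve = coherence(estimate_spectra(ve_seg.segments[0], emg_seg, 256.0))
        best_scalp = 0.0
        for ch in range(eeg_seg.shape[0]):
            coh_ch = coherence(estimate_spectra(eeg_seg[ch], emg_seg, 256.0))
            best_scalp = max(best_scalp, band_summary(coh_ch).area)
        assert band_summary(coh_ve).area >= best_scalp

    def test_dics_value_matches_explicit_source_coherence(self, coherent_scene,
                                                          sphere_leadfield):
        # cross-validate the scan algebra: band coherence computed from the
        # reconstructed series agrees with the map value within 0.05
        ds, _, emg_seg, csd, src = coherent_scene
        m = dics_scan(csd, sphere_leadfield, 0.05)
        cov = band_covariance(ds.eeg, 256.0, (15.0, 30.0))
        ve = lcmv_virtual_electrode(ds.eeg, cov, sphere_leadfield,
                                    sphere_leadfield.grid.positions[src], 0.05)
        ve_seg = segment_record(Recording(ve.timeseries[None], 256.0, ("VE",)))
        sp = estimate_spectra(ve_seg.segments[0], emg_seg, 256.0)
        sel = band_mask(sp.freqs, (15.0, 30.0))
        explicit = (np.abs(sp.f_xy[sel].mean()) ** 2
                    / (sp.f_xx[sel].mean() * sp.f_yy[sel].mean()))
        assert abs(m.values[src] - explicit) < 0.05


class TestLocalizationRecovery:
    def test_median_error_within_one_grid_spacing(self, sphere_leadfield):
        # 20 seeded single-source runs, 64 channels, 5-mm grid, gain 0.8
        grid = sphere_leadfield.grid
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            src = int(rng.integers(grid.n_sources))
            _, eeg, emg = simulate_and_segment(sphere_leadfield, duration=60.0,
                                               delay=25.0, coupling_gain=0.8,
                                               source_index=src, seed=seed,
                                               sensor_snr=5.0)
            m = dics_scan(csd_matrix(eeg, emg, 256.0), sphere_leadfield, 0.05)
            k = int(np.argmax(m.values))
            errs.append(np.linalg.norm(grid.positions[k] - grid.positions[src]))
        assert np.median(errs) <= grid.spacing


class TestEndToEndDirectionality:
    def test_virtual_electrode_chain_preserves_descending_dominance(self, sphere_leadfield):
        # scalp simulation -> LCMV virtual electrode -> spectra ->
        # directionality still finds cortex-leads in >= 90% of 20 runs
        from cmc.directionality import prewhiten_and_correlate, decompose_directions
        grid = sphere_leadfield.grid
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(2000 + seed)
            src = int(rng.integers(grid.n_sources))
            cfg = SimulationConfig(duration=60.0, delay=25.0, coupling_gain=0.5,
                                   source_index=src, seed=seed, sensor_snr=5.0)
            ds = simulate_dataset(sphere_leadfield, cfg)
            cov = band_covariance(ds.eeg, 256.0, (15.0, 30.0))
            ve = lcmv_virtual_electrode(ds.eeg, cov, sphere_leadfield,
                                        grid.positions[src], 0.05)
            ve_seg = epoch_and_normalize(Recording(ve.timeseries[None], 256.0, ("VE",)))
            emg_seg = epoch_and_normalize(Recording(ds.emg[None], 256.0, ("EMG",)))
            sp = estimate_spectra(ve_seg.segments[0], emg_seg.segments[0], 256.0)
            d = decompose_directions(*prewhiten_and_correlate(sp))
            hits += d.descending_magnitude > d.ascending_magnitude
        assert hits / n_runs >= 0.90
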