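#!/usr/bin/env python
"""Volumetric localization of the EMG-coherent source: simulate 64-channel
scalp data on the spherical head model, scan the 5-mm grid with DICS,
post-process the maps (10-mm smoothing, mean+2SD threshold, grand average),
export a NIfTI volume, and reconstruct an LCMV virtual electrode at the
grand-average peak for source-level coherence."""

from pathlib import Path

import numpy as np

from cmc.synthetic import SourceGrid, SimulationConfig, make_lead_field, simulate_dataset
from cmc.preprocess import Recording, epoch_and_normalize, segment_record
from cmc.spectra import estimate_spectra, coherence, band_summary
from cmc.directionality import prewhiten_and_correlate, decompose_directions
from cmc.beamform import (csd_matrix, dics_scan, postprocess_maps, map_to_nifti,
                          map_table, band_covariance, lcmv_virtual_electrode)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1
N_SUBJECTS = 6


def main() -> None:
    OUT.mkdir(exist_ok=True)
    grid = SourceGrid.hemisphere_shell(sphere_radius=85.0, spacing=5.0,
                                       r_min_frac=0.55, r_max_frac=0.8, z_min=45.0)
    lf = make_lead_field(64, grid, "single_sphere_analytic", sphere_radius=85.0)
    true_src = 431
    print(f"grid: {grid.n_sources} points at {grid.spacing:.0f} mm; "
          f"true source at {grid.positions[true_src]} mm")

    maps, errors = [], []
    last_ds = None
    for s in range(N_SUBJECTS):
        cfg = SimulationConfig(duration=120.0, delay=25.0, coupling_gain=0.8,
                               source_index=true_src, seed=SEED * 100_003 + s,
                               sensor_snr=5.0)
        ds = simulate_dataset(lf, cfg)
        eeg = segment_record(Recording(ds.eeg, 256.0, ds.channel_labels))
        emg = epoch_and_normalize(Recording(ds.emg[None], 256.0, ("EMG",)))
        m = dics_scan(csd_matrix(eeg.segments, emg.segments[0], 256.0), lf, 0.05)
        k = int(np.argmax(m.values))
        errors.append(np.linalg.norm(grid.positions[k] - grid.positions[true_src]))
        maps.append(m)
        last_ds, last_emg = ds, emg
    print(f"individual localization error: median {np.median(errors):.1f} mm "
          f"over {N_SUBJECTS} subjects (peak coherence "
          f"{np.mean([m.values.max() for m in maps]):.2f})")

    processed, grand = postprocess_maps(maps, fwhm_mm=10.0)
    map_table(grand).to_csv(OUT / "dics_grand_average.tsv", sep="\t", index=False,
                            float_format="%.6g")
    map_to_nifti(grand).to_filename(str(OUT / "dics_grand_average.nii.gz"))
    peak = grid.positions[int(np.argmax(grand.values))]
    print(f"grand-average peak (smoothed, mean+2SD threshold): {peak} mm")

    cov = band_covariance(last_ds.eeg, 256.0, (15.0, 30.0))
    ve = lcmv_virtual_electrode(last_ds.eeg, cov, lf, peak, 0.05)
    ve_seg = epoch_and_normalize(Recording(ve.timeseries[None], 256.0, ("VE",)))
    sp = estimate_spectra(ve_seg.segments[0], last_emg.segments[0], 256.0)
    summ = band_summary(coherence(sp))
    d = decompose_directions(*prewhiten_and_correlate(sp))
    print(f"virtual electrode at the peak: beta coherence peak "
          f"{summ.peak_value:.2f} at {summ.peak_freq:.0f} Hz "
          f"(limit {summ.confidence_limit:.3f}, significant={summ.significant}); "
          f"descending {d.descending_magnitude:.2f} vs ascending "
          f"{d.ascending_magnitude:.2f}")


if __name__ == "__main__":
    main()
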