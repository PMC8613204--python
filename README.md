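# cmc — corticomuscular coherence analysis

During a steady voluntary contraction, oscillatory activity in sensorimotor
cortex and in the muscle it drives is coherent in the beta band (15–30 Hz).
This package implements the full analysis chain used to quantify that
coupling from 64-channel EEG and bipolar EMG recorded during a 10%-MVC
precision-grip force-tracing task:

- **Preprocessing** — zero-phase band-pass (EEG 0.5–48 Hz, EMG 5–120 Hz),
  resampling to 256 Hz, full-wave EMG rectification, global detrend +
  unit-variance normalization, non-overlapping 1-s segmentation, and
  left/right montage flipping for left-handed participants.
- **Coherence** — segment-averaged spectra and magnitude-squared coherence
  `|C_xy(ω)|² = |f_xy|² / (f_xx f_yy)` at 1-Hz resolution, with the exact
  null confidence limit `1 − α^(1/(N−1))` and the Bonferroni-corrected
  α = 0.05/15 = 0.0033 for scanning the 15 beta bins; beta-band area, peak
  and per-subject significance.
- **Directionality** — non-parametric decomposition of coherence into
  descending (cortex→muscle), ascending (muscle→cortex) and zero-lag parts
  by pre-whitening the cross-spectrum and partitioning its lag-domain
  correlation by lag sign; the zero-lag term is discarded from the totals.
- **Beamforming** — DICS scanning of a 5-mm volumetric grid for sources
  coherent with the EMG, map post-processing (10-mm FWHM smoothing,
  mean+2SD thresholding, grand averaging, NIfTI export), and LCMV
  "virtual electrode" reconstruction of the source time series.
- **Performance metrics** — MVC, motor precision (reverse-coded RMSE from
  the target line) and motor variability (CV of the produced force).
- **Simulator** — seeded ground-truth generator (band-limited cortical
  source, lead-field projection, EMG coupled with a signed pure delay,
  force traces) so every stage is validated against known truth.

Real recordings of this kind are rarely shareable, so the package is built
to be verifiable end to end on synthetic data; readers for BDF/EDF files
and plain arrays accept real data with the same interfaces.

## Worked example

```python
import numpy as np
from cmc import (SourceGrid, make_lead_field, SimulationConfig, simulate_dataset,
                 Recording, epoch_and_normalize, estimate_spectra, coherence,
                 band_summary, prewhiten_and_correlate, decompose_directions)

grid = SourceGrid.regular((3, 3, 3), spacing=5.0)
lf = make_lead_field(8, grid, "random_wellconditioned", seed=1)
cfg = SimulationConfig(duration=120.0, delay=25.0, coupling_gain=0.5,
                       source_index=13, seed=3)           # cortex leads by 25 ms
ds = simulate_dataset(lf, cfg)

eeg = epoch_and_normalize(Recording(ds.eeg, 256.0, ds.channel_labels))
emg = epoch_and_normalize(Recording(ds.emg[None, :], 256.0, ("EMG",)))
ch = int(np.argmax(np.abs(lf.column(13))))                # strongest projection
sp = estimate_spectra(eeg.segments[ch], emg.segments[0], fs=256.0)

s = band_summary(coherence(sp))                           # beta band, alpha 0.0033
d = decompose_directions(*prewhiten_and_correlate(sp))
print(f"peak {s.peak_value:.2f} at {s.peak_freq:.0f} Hz, "
      f"limit {s.confidence_limit:.3f}, significant={s.significant}")
print(f"descending {d.descending_magnitude:.2f} vs ascending "
      f"{d.ascending_magnitude:.2f} coherence*Hz")
```

Output:

```
peak 0.86 at 19 Hz, limit 0.047, significant=True
descending 8.09 vs ascending 0.20 coherence*Hz
```

The coherence peak (0.86 at 19 Hz, inside the simulated 15–30 Hz coupling
band) clears the corrected confidence limit by a wide margin, and the
decomposition attributes ~98% of the directed coupling to the descending
path — recovering the injected cortex-leads delay.

## Analysis scripts

`analysis/01_simulate_cohort.py` … `05_force_metrics.py` run the full study
pipeline on a synthetic cohort (four groups with increasing coupling gain,
two hands each): sensor-level coherence and group-average spectra, the
directional decomposition, DICS localization with grand-averaged maps and a
virtual electrode at the group peak, and the force-task metrics. Each
script prints what it found and writes its tables under `results/`.

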