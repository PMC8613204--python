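# Methods

This package implements a corticomuscular coherence (CMC) analysis chain —
from multichannel EEG and bipolar EMG time series to beta-band coherence,
its statistical significance, its directional decomposition, and volumetric
localization of the EMG-coherent cortical source — together with a
ground-truth simulator that makes every stage testable without human
recordings. This note records the models, the defaults and their rationale,
the numerical choices, and what the synthetic validation does and does not
establish.

## Spectral estimation and coherence

Signals are conditioned (EEG band-passed 0.5–48 Hz, EMG 5–120 Hz, both
zero-phase, both resampled to 256 Hz), linearly detrended, normalized to
unit variance over the whole record, and cut into non-overlapping 1-s
segments (256 samples, so the frequency resolution is exactly 1 Hz). Auto
and cross spectra are disjoint-section FFT averages with a rectangular
window and the normalization `f_ab(ω) = mean_seg conj(X_a)·X_b / (2πL)`
(the Neurospec-style convention; the constant cancels in every coherence).
Magnitude-squared coherence is

    |C_xy(ω)|² = |f_xy(ω)|² / (f_xx(ω) · f_yy(ω)) ∈ [0, 1].

Under the null of two uncorrelated Gaussian signals the coherence estimate
from N segments is Beta(1, N−1)-distributed, so its (1−α) quantile is
exactly `1 − α^(1/(N−1))`; this closed form is the per-frequency confidence
limit. Scanning the beta band for any significant bin uses the
Bonferroni-corrected α = 0.05/15 = 0.0033. The tests verify the quantile
identity by Monte Carlo, not just the formula.

**Band conventions.** The beta band is 15–30 Hz. At 1-Hz resolution the
default in-band selector is the half-open interval [15, 30) — 15 bins,
matching the 15-fold α correction; an inclusive [15, 30] option (16 bins)
exists, since the inclusive reading is also defensible and the two differ by
one edge bin. Band "area" is the rectangle-rule sum `Σ coh·Δf`
(coherence·Hz), matching discrete-bin reporting; band scalars of the
directional components are sums as well (group contrasts are invariant to
sum-versus-mean). Peak ties break to the lowest frequency for determinism.

**Detrend/normalize scope.** Detrending and unit-variance scaling act on
the whole record, not per segment: per-segment variance normalization
biases segment-averaged spectra. A per-segment flag exists for sensitivity
checks only.

## Filters

All filtering is forward–backward (zero phase): any phase distortion would
translate directly into spurious lag, i.e. spurious directionality. The
band-pass is Butterworth of order 8 (SciPy's N; 16 poles effective after
the two passes), chosen so that mains-frequency activity one quarter-octave
above the 48-Hz EEG edge is suppressed below 5% RMS while the pass-band
stays flat. The EMG band's 120-Hz upper edge sits above the 128-Hz Nyquist
of the 256-Hz output rate, so the EMG filter runs at the native rate and
resampling always applies an explicit anti-alias guard (zero-phase low-pass
at 0.45·fs_out) before polyphase decimation. EMG rectification (|x|) is
applied after resampling and before normalization.

## Directional decomposition

Whitening the cross-spectrum, `g(ω) = f_xy / sqrt(f_xx f_yy)`, flattens both
auto spectra while preserving the cross-structure, so `|g(ω)|²` equals the
coherence bin for bin. The inverse FFT of the Hermitian-extended `g` is a
real lag-domain correlation ρ(τ). Partitioning ρ by lag sign — positive
lags (x leads y), the central zero-lag bin, negative lags — and transforming
each part back gives per-frequency components whose two-sided sum
reconstructs the total coherence *exactly* (Parseval; asserted to 1e-9).
Per-frequency additivity holds only approximately (cross-terms), which is a
property of the method, not an implementation defect; only the global
identity is asserted. With the convention `f_xy = mean conj(X)·Y`, positive
lag means x leads y, so with x = cortex the positive-lag part is the
descending (cortex→muscle) component. The zero-lag component — which in
real recordings can carry common non-physiological signal — is computed but
excluded from the reported descending/ascending totals.

Implementation choices: the construction is frequency-domain whitening with
an inverse-transform lag partition rather than time-domain MMSE whitening
filters — same fixed points, no filter-design free parameters, and the
Parseval identity becomes exactly testable. "Zero lag" is the single
central bin by default; a configurable guard band exists because volume
conduction spreads near-zero lags in real data. For even segment length L
the lone τ = −L/2 bin is its own time-reversal image; it is grouped with
the (discarded) zero-lag term so that exchanging x and y exchanges the
descending and ascending scalars exactly. Bins with auto power below
1e-12 of the mean are masked from the extension; exactly-zero bins raise.

## Beamforming

**DICS.** The band-averaged cross-spectral density C (EEG channels plus the
EMG reference in the last slot) is built with the same segmented-FFT
machinery as the spectra. For each grid point with lead-field column l the
unit-gain adaptive filter is

    W = (lᵀ C_r⁻¹ l)⁻¹ lᵀ C_r⁻¹ ,   C_r = Re(C_eeg) + λ·mean(diag)·I ,

and the map value is `|W·c_ref|² / ((W C_eeg Wᴴ) · C_ref,ref)` — the
magnitude-squared coherence between the beamformed source estimate and the
EMG, bounded in [0, 1] by Cauchy–Schwarz on the joint CSD. The real part of
the CSD builds the filter (standard practice); the complex cross-spectrum
feeds the numerator. Free-orientation lead fields are reduced per point by
the power-maximizing orientation (minimal eigenvector of lᵀC_r⁻¹l). The
regularization fraction λ defaults to 5% of the mean sensor-power diagonal
(the value is not dictated by the method; it is exposed as a parameter and
a singular unregularized matrix raises with advice).

Maps are smoothed with a Gaussian kernel of 10 mm FWHM per axis
(σ = FWHM/2.355 — FWHM being the convention of the volumetric tools this
emulates), then thresholded per individual map at mean + 2·SD over all
voxels, then grand-averaged voxel-wise; thresholding precedes averaging.
Maps export as NIfTI with an affine encoding the 5-mm spacing and grid
origin (right-handed, mm; x left→right, y posterior→anterior, z
inferior→superior).

**LCMV.** The same unit-gain filter applied to a time-domain sensor
covariance reconstructs a "virtual electrode" series at a chosen
coordinate (snapped to the nearest grid point; farther than one spacing is
an error). The covariance is band-limited to 15–30 Hz by default — the
analysis is a beta-band one — with broadband switchable. The critical
subtlety: the multichannel path must *not* per-channel variance-normalize,
because that flattens the lead-field amplitude pattern the spatial filter
inverts; `segment_record` (detrend only) exists for exactly this reason,
while the channel-pair coherence path uses the normalized segments.

## The simulator

The generator emulates the statistical structure the analysis assumes:

- **Cortical source:** unit-variance Gaussian noise band-passed (zero
  phase) to the coupling band, default 15–30 Hz — the band in which CMC is
  prominent during steady contraction.
- **EEG:** lead field × source + independent Gaussian sensor noise,
  per-channel SNR in dB (10·log10 of variance ratio), default 5 dB.
- **EMG (additive model, default):** `gain · source(t − delay) + noise`,
  with the noise floor fixed relative to the unit-variance source so that
  raising the gain genuinely raises the coupled fraction. Default gain 0.5,
  default delay +25 ms (cortex leads; roughly a corticospinal conduction
  delay for a hand muscle). A pure delay keeps the directional ground truth
  unambiguous — all cross-correlation mass at one signed lag — making the
  lag-partition tests exact. An amplitude-modulated carrier variant exists
  (`emg_model="modulated"`) because the generative process of surface EMG
  is not settled; the additive model is the simplest in which
  rectified-EMG coherence provably works and is the tested default.
- **Head model:** a homogeneous single conducting sphere with radial
  dipoles (Legendre-series solution, 120 terms) and electrodes on the upper
  surface — sufficient for localization-recovery tests, explicitly
  non-physiological (no skull/scalp conductivity profile, no realistic
  montage). A geometry-free random well-conditioned gain matrix (condition
  number ≤ 10³, redrawn otherwise) serves where only the algebra is under
  test. A radial dipole orientation is undefined at the sphere centre, so
  a grid containing the centre is rejected as degenerate.
- **Force trace:** target (10% of MVC) plus Gaussian drift low-passed at
  10 Hz and scaled to a stated SD fraction of MVC (default 2%), sampled at
  1000 Hz — mimicking a hardware-filtered load-cell channel.

One seeded generator drives all randomness; identical config + seed is
bit-identical. What the simulator does **not** emulate: 1/f background EEG,
volume-conducted common signal (the zero-lag term is structurally absent),
motor-unit pool physiology, nonstationarity, artifacts. Passing tests
therefore establish that the estimators recover the truth *under the
model's assumptions*; they do not certify performance on real recordings,
where the zero-lag guard, artifact rejection and re-referencing options
become relevant.

## Performance metrics

Motor precision is the reverse-coded RMSE from the target line (0 =
perfect; more negative = worse); motor variability is the coefficient of
variation SD/mean, reported as a fraction (units are not dictated by the
definition; group contrasts are unaffected). SD uses the n−1 denominator.
Natural-log transforms of RMSE and CV are provided for downstream group
models. An optional trim flag drops task on/offset seconds; the default
analyzes the full record.

## Problem sizes and reproducibility

Simulated records default to 120 s at 256 Hz (120 one-second segments,
matching the ~120-s task blocks the pipeline is designed for). The test
suite and `scripts/acceptance.py` use 120-s records for calibration checks
and 60-s records for the multi-run localization and cohort sweeps — sizes
chosen to keep the full validation in the minutes range on one core while
leaving every rate comfortably away from its threshold. The localization
grid is an upper-hemisphere shell of 932 points at 5-mm spacing; the
sensor-level chain uses 8–16 channels, the beamforming chain 64. All
Monte-Carlo assertions run derandomized (fixed or CLI-derived seeds).

## Known limitations

- The spherical head model and equal per-channel SNR make localization
  easier than scalp EEG with a real head; localization rates here are upper
  bounds.
- Group aggregation is descriptive (means, SDs, proportions significant);
  inferential modelling (mixed models, FDR contrasts) is deliberately out
  of scope and would be an off-the-shelf fit on the exported tables.
- ICA-based artifact removal and visual bad-segment rejection are replaced
  by an optional amplitude-threshold segment drop (k·SD, default off).
- BDF/EDF reading requires the optional `mne` dependency; all internal I/O
  is plain text or HDF5.
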