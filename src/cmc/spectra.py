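"""Segment-averaged spectra, magnitude-squared coherence and its
significance.

Auto and cross spectra are estimated by FFTs of non-overlapping rectangular
1-s segments (256 samples at 256 Hz gives 1-Hz resolution), averaged over
segments with the Neurospec normalization 1/(2*pi*L).  Coherence is

    |C_xy(w)|^2 = |f_xy(w)|^2 / (f_xx(w) * f_yy(w))

bounded in [0, 1].  Under the null of two uncorrelated Gaussian signals the
estimator's (1 - alpha) quantile has the closed form 1 - alpha**(1/(N-1)),
which serves as the per-frequency confidence limit; scanning the 15 1-Hz
bins of the beta band (15-30 Hz, half-open) uses the Bonferroni-corrected
alpha of 0.05/15 = 0.0033.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

BETA_BAND = (15.0, 30.0)
N_BETA_COMPARISONS = 15


@dataclass(frozen=True)
class SpectraSet:
    """One-sided segment-averaged auto and cross spectra.

    Convention: f_xy(w) = mean over segments of conj(X(w)) * Y(w) / (2*pi*L),
    so positive lag in the derived correlation function means x leads y.
    """

    freqs: np.ndarray
    f_xx: np.ndarray
    f_yy: np.ndarray
    f_xy: np.ndarray
    n_segments: int
    fs: float
    segment_length: int

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise ValueError("need at least 2 segments")
        if np.any(self.f_xx < 0) or np.any(self.f_yy < 0):
            raise ValueError("auto spectra must be non-negative")
        cs = np.abs(self.f_xy) ** 2 - self.f_xx * self.f_yy
        if np.any(cs > 1e-9 * np.maximum(self.f_xx * self.f_yy, 1e-300)):
            raise ValueError("cross-spectrum violates the Cauchy-Schwarz bound")

    @property
    def df(self) -> float:
        return self.fs / self.segment_length


@dataclass(frozen=True)
class CoherenceSpectrum:
    freqs: np.ndarray
    coh: np.ndarray
    n_segments: int

    def __post_init__(self) -> None:
        if np.any(self.coh < 0) or np.any(self.coh > 1 + 1e-12):
            raise ValueError("coherence outside [0, 1]")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class BandSummary:
    band: tuple[float, float]
    area: float                 # coherence * Hz
    peak_value: float
    peak_freq: float
    confidence_limit: float
    significant: bool
    n_segments: int


def _segment_ffts(segments: np.ndarray, window: str | None) -> np.ndarray:
    segments = np.asarray(segments, dtype=float)
    if segments.ndim != 2:
        raise ValueError("segments must be (n_segments, segment_length)")
    if window == "hann":
        w = np.hanning(segments.shape[1])
        segments = segments * (w / np.sqrt(np.mean(w ** 2)))
    elif window not in (None, "rectangular"):
        raise ValueError(f"unknown window {window!r}")
    return np.fft.rfft(segments, axis=1)


def estimate_spectra(seg_x: np.ndarray, seg_y: np.ndarray, fs: float,
                     window: str | None = None) -> SpectraSet:
    """Disjoint-section FFT estimate of f_xx, f_yy and f_xy.

    Rectangular window by default (1-s disjoint sections); a Hann option
    exists but changes the effective bandwidth and is off by default.
    """
    seg_x = np.asarray(seg_x, float)
    seg_y = np.asarray(seg_y, float)
    if seg_x.shape != seg_y.shape:
        raise ValueError("x and y must share the same segmentation (counts and lengths)")
    n_seg, seg_len = seg_x.shape
    X = _segment_ffts(seg_x, window)
    Y = _segment_ffts(seg_y, window)
    norm = 1.0 / (2.0 * np.pi * seg_len)
    f_xx = norm * np.mean(np.abs(X) ** 2, axis=0)
    f_yy = norm * np.mean(np.abs(Y) ** 2, axis=0)
    f_xy = norm * np.mean(np.conj(X) * Y, axis=0)
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / fs)
    return SpectraSet(freqs=freqs, f_xx=f_xx, f_yy=f_yy, f_xy=f_xy,
                      n_segments=n_seg, fs=fs, segment_length=seg_len)


def coherence(spectra: SpectraSet) -> CoherenceSpectrum:
    """Magnitude-squared coherence per frequency bin (0/0 bins set to 0)."""
    denom = spectra.f_xx * spectra.f_yy
    zero = denom == 0
    if np.any(zero):
        warnings.warn("zero auto-spectrum bins: coherence set to 0 there", RuntimeWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(zero, 0.0, np.abs(spectra.f_xy) ** 2 / np.where(zero, 1.0, denom))
    coh = np.clip(coh, 0.0, 1.0)
    return CoherenceSpectrum(freqs=spectra.freqs, coh=coh, n_segments=spectra.n_segments)


def confidence_limit(alpha: float, n_segments: int) -> float:
    """Upper (1 - alpha) confidence limit of null coherence: 1 - alpha**(1/(N-1)).

    This is exactly the 1 - alpha quantile of the coherence estimator for N
    independent segments of two uncorrelated Gaussian signals.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_segments < 2:
        raise ValueError("need at least 2 segments")
    return 1.0 - alpha ** (1.0 / (n_segments - 1))


def correct_alpha(alpha: float, n_comparisons: int) -> float:
    """Bonferroni correction: alpha / n_comparisons."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons


def band_mask(freqs: np.ndarray, band: tuple[float, float],
              inclusive: bool = False) -> np.ndarray:
    """In-band bin selector.  Default is the half-open band [lo, hi), which
    at 1-Hz resolution over 15-30 Hz selects 15 bins -- the bin count behind
    the 15-fold alpha correction; ``inclusive`` selects [lo, hi] (16 bins)."""
    lo, hi = band
    if inclusive:
        return (freqs >= lo) & (freqs <= hi)
    return (freqs >= lo) & (freqs < hi)


def peak_in_range(coh: CoherenceSpectrum, fmin: float, fmax: float) -> tuple[float, float]:
    """Frequency and value of maximal coherence in [fmin, fmax]; ties broken
    toward the lowest frequency."""
    sel = (coh.freqs >= fmin) & (coh.freqs <= fmax)
    if not np.any(sel):
        raise ValueError(f"range [{fmin}, {fmax}] Hz does not intersect the frequency axis")
    sub = coh.coh[sel]
    i = int(np.argmax(sub))  # argmax returns the first maximum: lowest frequency
    return float(coh.freqs[sel][i]), float(sub[i])


def band_summary(coh: CoherenceSpectrum, band: tuple[float, float] = BETA_BAND,
                 alpha_corrected: float = 0.05 / N_BETA_COMPARISONS,
                 inclusive: bool = False) -> BandSummary:
    """Beta-band area (rectangle rule, coherence*Hz), peak, and significance
    against the corrected confidence limit."""
    sel = band_mask(coh.freqs, band, inclusive)
    if not np.any(sel):
        raise ValueError("band outside the frequency axis")
    area = float(np.sum(coh.coh[sel]) * coh.df)
    fsel = coh.freqs[sel]
    peak_freq, peak_value = peak_in_range(coh, float(fsel[0]), float(fsel[-1]))
    limit = confidence_limit(alpha_corrected, coh.n_segments)
    return BandSummary(band=band, area=area, peak_value=peak_value,
                       peak_freq=peak_freq, confidence_limit=limit,
                       significant=bool(peak_value > limit), n_segments=coh.n_segments)


def average_coherence(spectra: list[CoherenceSpectrum]) -> CoherenceSpectrum:
    """Plain average of coherence spectra across subjects (group summary)."""
    if not spectra:
        raise ValueError("no spectra to average")
    f0 = spectra[0].freqs
    for s in spectra[1:]:
        if not np.array_equal(s.freqs, f0):
            raise ValueError("frequency axes differ across subjects")
    coh = np.mean([s.coh for s in spectra], axis=0)
    n = min(s.n_segments for s in spectra)
    return CoherenceSpectrum(freqs=f0, coh=coh, n_segments=n)


def spectra_table(spectra: SpectraSet):
    """Spectra + coherence as a tidy DataFrame for text export."""
    import pandas as pd

    coh = coherence(spectra)
    return pd.DataFrame({
        "freq": spectra.freqs,
        "f_xx": spectra.f_xx,
        "f_yy": spectra.f_yy,
        "re_f_xy": spectra.f_xy.real,
        "im_f_xy": spectra.f_xy.imag,
        "coh": coh.coh,
    })
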