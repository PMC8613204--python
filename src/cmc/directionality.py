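"""Non-parametric decomposition of coherence into descending, ascending and
zero-lag components.

Whitening the cross-spectrum, g(w) = f_xy(w) / sqrt(f_xx(w) f_yy(w)), makes
both auto spectra flat, so |g(w)|^2 equals the coherence bin for bin.  The
inverse Fourier transform of the Hermitian-extended g is a real lag-domain
correlation rho(tau) whose squared mass, by Parseval, equals the mean
coherence over the two-sided axis.  Partitioning rho by lag sign -- positive
lags where x (the cortical signal) leads y (the EMG), negative where the EMG
leads, the central bin for instantaneous correlation -- and transforming each
part back yields frequency-resolved coherence components whose two-sided sum
reproduces the total coherence exactly.  The zero-lag part (which in real
recordings can reflect common non-physiological signal) is computed but
excluded from the reported descending/ascending totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectraSet, band_mask


@dataclass(frozen=True)
class WhitenedCross:
    """Pre-whitened cross-spectrum on the full two-sided frequency axis."""

    freqs: np.ndarray            # two-sided, np.fft.fftfreq order
    g: np.ndarray                # complex, Hermitian
    n_segments: int
    fs: float

    @property
    def n_bins(self) -> int:
        return len(self.g)


@dataclass(frozen=True)
class LagCorrelation:
    lags: np.ndarray             # seconds, symmetric about 0, step 1/fs
    rho: np.ndarray              # real


@dataclass(frozen=True)
class DirectionalDecomposition:
    freqs: np.ndarray            # one-sided axis
    coh_forward: np.ndarray
    coh_backward: np.ndarray
    coh_zero: np.ndarray
    descending_magnitude: float  # band-summed, coherence * Hz
    ascending_magnitude: float
    zero_magnitude: float
    band: tuple[float, float]


def prewhiten_and_correlate(spectra: SpectraSet,
                            tiny_fraction: float = 1e-12) -> tuple[WhitenedCross, LagCorrelation]:
    """Whitened cross-spectrum and its lag-domain correlation function.

    Bins where an auto spectrum is exactly zero raise (restrict the axis or
    regularize); bins below ``tiny_fraction`` times the mean auto power are
    masked out of the two-sided extension (g set to 0 there).
    """
    L = spectra.segment_length
    f_xx, f_yy, f_xy = spectra.f_xx, spectra.f_yy, spectra.f_xy
    if np.any(f_xx == 0) or np.any(f_yy == 0):
        raise ValueError(
            "zero auto-spectrum bin: whitening undefined; restrict the frequency "
            "axis or regularize the spectra before decomposition"
        )
    tiny = (f_xx < tiny_fraction * f_xx.mean()) | (f_yy < tiny_fraction * f_yy.mean())
    g_one = np.where(tiny, 0.0, f_xy / np.sqrt(f_xx * f_yy))

    # Hermitian extension to the full circular axis; DC and (even L) Nyquist
    # bins of a real-signal cross-spectrum are real -- enforce against rounding
    g = np.zeros(L, dtype=complex)
    g[: len(g_one)] = g_one
    g[0] = g_one[0].real
    if L % 2 == 0:
        g[L // 2] = g_one[-1].real
        g[L // 2 + 1:] = np.conj(g_one[1:-1][::-1])
    else:
        g[len(g_one):] = np.conj(g_one[1:][::-1])

    rho_c = np.fft.ifft(g)
    if np.max(np.abs(rho_c.imag)) > 1e-9:
        raise AssertionError("lag correlation is not real: Hermitian extension broken")
    rho = np.fft.fftshift(rho_c.real)
    lags = (np.arange(L) - L // 2) / spectra.fs
    freqs2 = np.fft.fftfreq(L, d=1.0 / spectra.fs)
    return (WhitenedCross(freqs=freqs2, g=g, n_segments=spectra.n_segments, fs=spectra.fs),
            LagCorrelation(lags=lags, rho=rho))


def _component_coherence(rho_part: np.ndarray, n_onesided: int) -> np.ndarray:
    """One-sided |FFT|^2 of a lag-domain part (its coherence contribution)."""
    G = np.fft.fft(np.fft.ifftshift(rho_part))
    return np.abs(G[:n_onesided]) ** 2


def decompose_directions(whitened: WhitenedCross, lagcorr: LagCorrelation,
                         band: tuple[float, float] = (15.0, 30.0),
                         x_is_cortex: bool = True,
                         zero_lag_guard: int = 0) -> DirectionalDecomposition:
    """Partition the lag correlation by lag sign and return per-frequency and
    band-summed directional coherence components.

    ``zero_lag_guard`` widens the instantaneous term to +/- that many lag
    samples (default 0: the single central bin), useful on real data where
    volume conduction spreads near-zero lags.  For even segment lengths the
    lone maximal-lag bin (tau = -L/2 / fs) has no sign and is grouped with
    the instantaneous term, which keeps the decomposition exactly
    antisymmetric under exchange of x and y.  With ``x_is_cortex`` (default)
    the positive-lag part is the descending, cortex-to-muscle component.
    """
    L = whitened.n_bins
    n_one = L // 2 + 1
    df = whitened.fs / L
    if band[1] > whitened.fs / 2:
        raise ValueError("band outside the frequency axis")

    center = L // 2
    idx = np.arange(L)
    zero_idx = np.abs(idx - center) <= zero_lag_guard
    if L % 2 == 0:
        zero_idx[0] = True      # the sign-ambiguous tau = -L/2 bin
    pos_idx = idx > center + zero_lag_guard
    neg_idx = ~zero_idx & ~pos_idx

    rho = lagcorr.rho
    parts = {name: _component_coherence(np.where(sel, rho, 0.0), n_one)
             for name, sel in (("forward", pos_idx), ("backward", neg_idx), ("zero", zero_idx))}
    if not x_is_cortex:
        parts["forward"], parts["backward"] = parts["backward"], parts["forward"]

    freqs_one = np.fft.rfftfreq(L, d=1.0 / whitened.fs)
    sel = band_mask(freqs_one, band)
    return DirectionalDecomposition(
        freqs=freqs_one,
        coh_forward=parts["forward"], coh_backward=parts["backward"],
        coh_zero=parts["zero"],
        descending_magnitude=float(np.sum(parts["forward"][sel]) * df),
        ascending_magnitude=float(np.sum(parts["backward"][sel]) * df),
        zero_magnitude=float(np.sum(parts["zero"][sel]) * df),
        band=band,
    )


def directionality_table(decomp: DirectionalDecomposition, coh=None):
    """Per-frequency components (+ total coherence if given) as a DataFrame."""
    import pandas as pd

    cols = {"freq": decomp.freqs,
            "coh_descending": decomp.coh_forward,
            "coh_ascending": decomp.coh_backward,
            "coh_zero": decomp.coh_zero}
    if coh is not None:
        cols["coh"] = coh.coh
    return pd.DataFrame(cols)
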