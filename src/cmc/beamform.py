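"""DICS source localization of EMG-coherent cortical activity and LCMV
virtual-electrode reconstruction.

DICS scans a volumetric grid with adaptive spatial filters built from the
band-averaged sensor cross-spectral density (CSD) and the lead field,

    W(r) = (l^T Cr^-1 l)^-1 l^T Cr^-1,    Cr = Re(C_eeg) + reg * mean(diag) * I

and maps the coherence between the beamformed source estimate at r and the
EMG reference.  After smoothing (10-mm FWHM Gaussian) and per-individual
mean+2SD thresholding, maps are grand-averaged across subjects.  LCMV uses
the same unit-gain filter on a time-domain covariance to reconstruct a
source series ("virtual electrode") at a chosen coordinate, which then feeds
the coherence and directionality analyses in place of a scalp channel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

from .synthetic import LeadField, SourceGrid
from .spectra import band_mask

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))   # approx 2.355


@dataclass(frozen=True)
class CSDMatrix:
    """Band-averaged cross-spectral density; EMG reference in the last slot."""

    C: np.ndarray                # (n_ch+1, n_ch+1) complex Hermitian
    band: tuple[float, float]
    n_segments: int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=complex)
        if np.max(np.abs(C - C.conj().T)) > 1e-9 * max(np.max(np.abs(C)), 1e-300):
            raise ValueError("CSD matrix is not Hermitian")
        if np.any(C.diagonal().real < -1e-12):
            raise ValueError("CSD diagonal must be non-negative")
        object.__setattr__(self, "C", C)

    @property
    def n_eeg(self) -> int:
        return self.C.shape[0] - 1

    @property
    def eeg_block(self) -> np.ndarray:
        return self.C[:-1, :-1]

    @property
    def cross_ref(self) -> np.ndarray:
        """C[a, emg]: cross-spectra between each EEG channel and the EMG."""
        return self.C[:-1, -1]

    @property
    def ref_power(self) -> float:
        return float(self.C[-1, -1].real)


@dataclass(frozen=True)
class DICSMap:
    grid: SourceGrid
    values: np.ndarray           # (n_sources,) real >= 0
    band: tuple[float, float]
    reg_fraction: float
    smoothed: bool = False
    thresholded: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_sources,):
            raise ValueError("map length does not match the grid")
        if not self.smoothed and (np.any(v < -1e-12) or np.any(v > 1 + 1e-9)):
            raise ValueError("raw DICS values must be coherences in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class VirtualElectrode:
    weights: np.ndarray          # (n_channels,)
    position: np.ndarray         # mm
    timeseries: np.ndarray


def csd_matrix(eeg_segments: np.ndarray, emg_segments: np.ndarray, fs: float,
               band: tuple[float, float] = (15.0, 30.0),
               labels: tuple[str, ...] | None = None) -> CSDMatrix:
    """Band-averaged CSD from the same segmented-FFT machinery as the spectra
    (convention C[a, b] = mean of conj(X_a) X_b / (2 pi L) over segments and
    in-band bins), with the EMG appended as the reference channel."""
    eeg_segments = np.asarray(eeg_segments, float)
    emg_segments = np.asarray(emg_segments, float)
    if eeg_segments.shape[-2:] != emg_segments.shape:
        raise ValueError("EEG and EMG segmentation mismatch (counts or lengths differ)")
    all_seg = np.concatenate([eeg_segments, emg_segments[None]], axis=0)
    n_ch, n_seg, L = all_seg.shape
    X = np.fft.rfft(all_seg, axis=2)                       # (n_ch, n_seg, n_bins)
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    sel = band_mask(freqs, band)
    if not np.any(sel):
        raise ValueError("band outside the frequency axis")
    Xb = X[:, :, sel]
    C = np.einsum("ask,bsk->ab", np.conj(Xb), Xb) / (Xb.shape[1] * Xb.shape[2] * 2 * np.pi * L)
    C = 0.5 * (C + C.conj().T)                             # kill rounding asymmetry
    labels = labels or tuple(f"EEG{i:03d}" for i in range(n_ch - 1))
    return CSDMatrix(C=C, band=band, n_segments=n_seg, labels=tuple(labels) + ("EMG",))


def _regularized_inverse(C_real: np.ndarray, reg_fraction: float) -> np.ndarray:
    n = C_real.shape[0]
    Cr = C_real + reg_fraction * float(np.mean(np.diag(C_real))) * np.eye(n)
    if np.linalg.cond(Cr) > 1e12:
        raise np.linalg.LinAlgError(
            "sensor CSD/covariance is singular; increase reg_fraction above 0"
        )
    return np.linalg.inv(Cr)


def _resolve_orientations(gains: np.ndarray, Ci: np.ndarray) -> np.ndarray:
    """Reduce a free-orientation lead field (n_ch, n_src, 3) to fixed
    orientation by the power-maximizing direction per source: the minimal
    eigenvector of l^T Cr^-1 l (beamformer power = 1 / (eta^T A eta))."""
    n_ch, n_src, _ = gains.shape
    out = np.empty((n_ch, n_src))
    for j in range(n_src):
        Lj = gains[:, j, :]
        A = Lj.T @ Ci @ Lj
        w, v = np.linalg.eigh(A)
        out[:, j] = Lj @ v[:, 0]
    return out


def dics_scan(csd: CSDMatrix, leadfield: LeadField, reg_fraction: float = 0.05) -> DICSMap:
    """Source-EMG band coherence at every grid point.

    For each point the unit-gain filter W projects the sensor data onto the
    source; the map value is |W c_ref|^2 / ((W C_eeg W^H) C_ref,ref) -- the
    magnitude-squared coherence between the beamformed source and the EMG.
    """
    if leadfield.n_channels != csd.n_eeg:
        raise ValueError("lead field channel count does not match the CSD")
    C_eeg = csd.eeg_block
    Ci = _regularized_inverse(C_eeg.real, reg_fraction)
    gains = leadfield.gains
    if leadfield.is_free_orientation:
        gains = _resolve_orientations(gains, Ci)
    CiL = Ci @ gains                                       # (n_ch, n_src)
    denom_l = np.einsum("cs,cs->s", gains, CiL)            # l^T Ci l per source
    num = np.abs(CiL.T @ csd.cross_ref) ** 2 / denom_l ** 2
    src_power = np.einsum("cs,cd,ds->s", CiL, C_eeg, CiL).real / denom_l ** 2
    values = num / (src_power * csd.ref_power)
    values = np.clip(values, 0.0, 1.0)
    return DICSMap(grid=leadfield.grid, values=values, band=csd.band,
                   reg_fraction=reg_fraction)


def _grid_shape(grid: SourceGrid):
    """Dense-lattice embedding of the (possibly masked) grid."""
    mins = grid.positions.min(axis=0)
    ijk = np.round((grid.positions - mins) / grid.spacing).astype(int)
    shape = ijk.max(axis=0) + 1
    return ijk, shape, mins


def smooth_map(m: DICSMap, fwhm_mm: float = 10.0) -> DICSMap:
    """Gaussian smoothing with the stated FWHM per axis (sigma = FWHM/2.355),
    on the dense lattice embedding of the grid (off-grid voxels count as 0)."""
    ijk, shape, _ = _grid_shape(m.grid)
    vol = np.zeros(shape)
    vol[tuple(ijk.T)] = m.values
    sigma_vox = fwhm_mm / FWHM_TO_SIGMA / m.grid.spacing
    sm = ndimage.gaussian_filter(vol, sigma_vox, mode="constant")
    return replace(m, values=sm[tuple(ijk.T)], smoothed=True)


def threshold_map(m: DICSMap) -> DICSMap:
    """Zero out voxels not exceeding mean + 2 SD over all voxels."""
    mu, sd = float(m.values.mean()), float(m.values.std())
    out = np.where(m.values > mu + 2 * sd, m.values, 0.0)
    return replace(m, values=out, thresholded=True)


def postprocess_maps(maps: list[DICSMap], fwhm_mm: float = 10.0) -> tuple[list[DICSMap], DICSMap]:
    """Smooth and mean+2SD-threshold each individual map, then grand-average.

    Thresholding precedes averaging, so the grand average reflects only
    voxels that survived in each individual."""
    if not maps:
        raise ValueError("no maps to process")
    g0 = maps[0].grid
    for m in maps[1:]:
        if not np.array_equal(m.grid.positions, g0.positions):
            raise ValueError("maps are not on a common grid")
    processed = [threshold_map(smooth_map(m, fwhm_mm)) for m in maps]
    ga = replace(processed[0], values=np.mean([p.values for p in processed], axis=0))
    return processed, ga


def band_covariance(eeg: np.ndarray, fs: float,
                    band: tuple[float, float] | None = (15.0, 30.0)) -> np.ndarray:
    """Time-domain sensor covariance, band-limited (zero-phase Butterworth)
    by default; pass band=None for broadband."""
    data = np.asarray(eeg, float)
    if band is not None:
        sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=-1)
    data = data - data.mean(axis=-1, keepdims=True)
    return data @ data.T / data.shape[-1]


def lcmv_virtual_electrode(eeg: np.ndarray, covariance: np.ndarray,
                           leadfield: LeadField, position_mm,
                           reg_fraction: float = 0.05) -> VirtualElectrode:
    """Unit-gain minimum-variance source reconstruction at a coordinate.

    The position is snapped to the nearest grid point (error if farther than
    one grid spacing); W = (l^T Cr^-1 l)^-1 l^T Cr^-1 satisfies W l = 1.
    """
    j, dist = leadfield.grid.nearest(position_mm)
    if dist > leadfield.grid.spacing:
        raise ValueError(
            f"position {np.asarray(position_mm)} is {dist:.1f} mm from the nearest "
            f"grid point (> spacing {leadfield.grid.spacing} mm): outside the grid hull"
        )
    Ci = _regularized_inverse(np.asarray(covariance, float), reg_fraction)
    if leadfield.is_free_orientation:
        l = _resolve_orientations(leadfield.gains[:, [j], :], Ci)[:, 0]
    else:
        l = leadfield.column(j)
    w = (Ci @ l) / float(l @ Ci @ l)
    return VirtualElectrode(weights=w, position=leadfield.grid.positions[j],
                            timeseries=w @ np.asarray(eeg, float))


def map_to_nifti(m: DICSMap):
    """DICS map as a NIfTI image: dense lattice + affine encoding the 5-mm
    spacing and the grid origin in the stated RAS-like frame."""
    import nibabel as nib

    ijk, shape, mins = _grid_shape(m.grid)
    vol = np.zeros(shape)
    vol[tuple(ijk.T)] = m.values
    affine = np.diag([m.grid.spacing] * 3 + [1.0])
    affine[:3, 3] = mins
    return nib.Nifti1Image(vol, affine)


def map_table(m: DICSMap):
    """Map as a tidy (x, y, z, value) DataFrame."""
    import pandas as pd

    return pd.DataFrame({
        "x": m.grid.positions[:, 0], "y": m.grid.positions[:, 1],
        "z": m.grid.positions[:, 2], "value": m.values,
    })
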