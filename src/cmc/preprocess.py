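"""Conditioning of raw EEG/EMG records and segmentation for spectral analysis.

EEG is zero-phase band-passed 0.5--48 Hz and resampled to 256 Hz; EMG is
band-passed 5--120 Hz at the native rate, resampled to 256 Hz and (for
coherence analysis) full-wave rectified.  Records are then linearly
detrended, normalized to unit variance over the whole record, and cut into
non-overlapping 1-s segments.  All filtering is forward-backward so that no
filter delay leaks into the lag-based directionality estimates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

EEG_BAND = (0.5, 48.0)
EMG_BAND = (5.0, 120.0)
FS_OUT = 256.0


@dataclass(frozen=True)
class Recording:
    data: np.ndarray                 # (n_channels, n_samples)
    fs: float
    labels: tuple[str, ...]
    kinds: tuple[str, ...] = ()      # per channel: eeg | emg | force

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if len(self.labels) != d.shape[0]:
            raise ValueError("label count does not match channel count")
        kinds = self.kinds or tuple("eeg" for _ in self.labels)
        if len(kinds) != d.shape[0]:
            raise ValueError("kinds length does not match channel count")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "kinds", tuple(kinds))

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SegmentArray:
    """Non-overlapping, contiguous segments per channel."""

    segments: np.ndarray             # (n_channels, n_segments, segment_length)
    fs: float
    labels: tuple[str, ...]

    @property
    def n_segments(self) -> int:
        return self.segments.shape[1]

    @property
    def segment_length(self) -> int:
        return self.segments.shape[2]

    def channel(self, label: str) -> np.ndarray:
        return self.segments[self.labels.index(label)]


def _bandpass_sos(band: tuple[float, float], fs: float, order: int = 8):
    # order 8 (x2 from forward-backward application) gives > 30 dB rejection
    # one quarter-octave outside the band edge, e.g. mains at 60 Hz after a
    # 48-Hz edge; a gentler filter would leak line noise into the spectra
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz is at or above Nyquist for fs={fs} Hz")
    return signal.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")


def _resample(data: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling with an explicit zero-phase anti-alias guard at
    0.45 * fs_out applied first (the EMG band's 120-Hz edge sits marginally
    close to the 128-Hz output Nyquist, so the guard is always on)."""
    if fs_in == fs_out:
        return data
    guard = signal.butter(8, 0.45 * fs_out, btype="lowpass", fs=fs_in, output="sos")
    data = signal.sosfiltfilt(guard, data, axis=-1)
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)


def condition_eeg(rec: Recording, band: tuple[float, float] = EEG_BAND,
                  fs_out: float = FS_OUT, rereference: bool = False) -> Recording:
    """Zero-phase band-pass (0.5--48 Hz) then resample to 256 Hz.

    ``rereference`` subtracts the mean across channels first (off by default:
    synthetic lead fields carry no common reference artefact).
    """
    if rec.fs < fs_out:
        raise ValueError("input sampling rate below the output rate")
    data = rec.data
    if rereference:
        data = data - data.mean(axis=0, keepdims=True)
    sos = _bandpass_sos(band, rec.fs)
    out = signal.sosfiltfilt(sos, data, axis=-1)
    out = _resample(out, rec.fs, fs_out)
    return replace(rec, data=out, fs=fs_out)


def condition_emg(rec: Recording, band: tuple[float, float] = EMG_BAND,
                  fs_out: float = FS_OUT, rectify: bool = True) -> Recording:
    """Band-pass 5--120 Hz at the native rate, resample to 256 Hz, then
    (optionally) full-wave rectify: y[n] = |x[n]|."""
    if rec.fs < fs_out:
        raise ValueError("input sampling rate below the output rate")
    sos = _bandpass_sos(band, rec.fs)
    out = signal.sosfiltfilt(sos, rec.data, axis=-1)
    out = _resample(out, rec.fs, fs_out)
    if rectify:
        out = np.abs(out)
    return replace(rec, data=out, fs=fs_out)


def drop_artifact_segments(seg: SegmentArray, k_sd: float = 6.0) -> SegmentArray:
    """Drop segments where any channel exceeds k standard deviations of its
    own record -- a coarse stand-in for visual bad-segment rejection."""
    sd = seg.segments.std(axis=(1, 2), keepdims=True)
    bad = np.any(np.abs(seg.segments) > k_sd * sd, axis=(0, 2))
    if bad.all():
        raise ValueError("all segments flagged as artifacts")
    return replace(seg, segments=seg.segments[:, ~bad, :])


def epoch_and_normalize(rec: Recording, segment_seconds: float = 1.0,
                        per_segment: bool = False) -> SegmentArray:
    """Linearly detrend, scale to unit variance, cut into non-overlapping
    segments (trailing partial segment dropped).

    Detrending and variance normalization act on the whole record by default;
    per-segment normalization (``per_segment=True``) exists for sensitivity
    checks but distorts segment-averaged spectra.
    """
    seg_len = int(round(segment_seconds * rec.fs))
    if rec.n_samples < seg_len:
        raise ValueError("record shorter than one segment")
    n_seg = rec.n_samples // seg_len
    data = rec.data[:, : n_seg * seg_len]
    # a channel is "constant" when its detrended scatter is at rounding level
    # relative to its raw amplitude
    floor = 1e-10 * np.maximum(np.sqrt(np.mean(data ** 2, axis=-1, keepdims=True)), 1e-300)
    if not per_segment:
        data = signal.detrend(data, axis=-1, type="linear")
        sd = data.std(axis=-1, keepdims=True)
        if np.any(sd <= floor):
            dead = [rec.labels[i] for i in np.where(sd[:, 0] <= floor[:, 0])[0]]
            raise ValueError(f"constant channel(s) cannot be normalized: {dead}")
        data = data / sd
        segs = data.reshape(data.shape[0], n_seg, seg_len)
    else:
        segs = data.reshape(data.shape[0], n_seg, seg_len)
        segs = signal.detrend(segs, axis=-1, type="linear")
        sd = segs.std(axis=-1, keepdims=True)
        if np.any(sd <= floor[:, :, None]):
            raise ValueError("constant segment cannot be normalized")
        segs = segs / sd
    if np.any(~np.isfinite(segs)):
        raise ValueError("non-finite values after conditioning")
    return SegmentArray(segments=segs, fs=rec.fs, labels=rec.labels)


def segment_record(rec: Recording, segment_seconds: float = 1.0) -> SegmentArray:
    """Detrend and segment WITHOUT per-channel variance normalization.

    Beamforming needs the relative channel gains intact (unit-variance
    scaling would flatten the lead-field amplitude pattern), so the
    multichannel CSD path uses this instead of epoch_and_normalize."""
    seg_len = int(round(segment_seconds * rec.fs))
    if rec.n_samples < seg_len:
        raise ValueError("record shorter than one segment")
    n_seg = rec.n_samples // seg_len
    data = signal.detrend(rec.data[:, : n_seg * seg_len], axis=-1, type="linear")
    return SegmentArray(segments=data.reshape(data.shape[0], n_seg, seg_len),
                        fs=rec.fs, labels=rec.labels)


_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|Z|\d+)$")


def flip_midline(labels) -> dict[str, str]:
    """Left/right homologue swap for 10/20-style labels (C3<->C4, ...).

    Odd digits are left-hemisphere, even right; 'z' marks the midline and is
    a fixed point.  Used to mirror montages of left-handed participants so
    the dominant hemisphere aligns across the group.  The mapping is an
    involution: applying it twice is the identity.
    """
    labels = list(labels)
    mapping: dict[str, str] = {}
    lset = set(labels)
    for lab in labels:
        m = _LABEL_RE.match(lab)
        if not m:
            raise ValueError(f"label {lab!r} does not follow the 10/20 convention")
        stem, suffix = m.groups()
        if suffix in ("z", "Z"):
            mapping[lab] = lab
            continue
        num = int(suffix)
        partner = f"{stem}{num + 1 if num % 2 == 1 else num - 1}"
        if partner not in lset:
            raise ValueError(f"no homologue for lateral electrode {lab!r} (expected {partner!r})")
        mapping[lab] = partner
    return mapping


def read_biosignal(path: str, kinds: dict[str, str] | None = None) -> Recording:
    """Read a BDF/EDF file into a Recording (header supplies fs and labels)."""
    import mne

    reader = mne.io.read_raw_bdf if str(path).lower().endswith(".bdf") else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    labels = tuple(raw.ch_names)
    kindmap = kinds or {}
    return Recording(data=raw.get_data(), fs=float(raw.info["sfreq"]), labels=labels,
                     kinds=tuple(kindmap.get(l, "eeg") for l in labels))


def read_delimited(path: str, fs: float, delimiter: str = "\t") -> Recording:
    """Read a plain text array (one column per channel, optional # header)."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        labels = tuple(first.lstrip("#").split())
        data = np.loadtxt(path, delimiter=delimiter, skiprows=1)
    else:
        data = np.loadtxt(path, delimiter=delimiter)
        labels = tuple(f"ch{i}" for i in range(np.atleast_2d(data).shape[1]))
    return Recording(data=np.atleast_2d(data).T, fs=fs, labels=labels)
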