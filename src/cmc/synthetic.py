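"""Ground-truth simulation of coupled cortex--muscle recordings.

Everything downstream (coherence, directionality, beamforming) is validated
against datasets generated here, where the coupling band, direction, delay
and source location are known by construction.  The generative model is
deliberately minimal: a band-limited (default 15--30 Hz) cortical source is
projected to scalp channels through a lead field, and the EMG is a delayed
linear copy of that source plus independent noise.  A pure delay keeps the
directional ground truth unambiguous -- all cross-correlation mass sits at a
single signed lag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy import signal
from scipy.special import eval_legendre


@dataclass(frozen=True)
class SourceGrid:
    """Regular axis-aligned lattice of candidate source positions (mm)."""

    positions: np.ndarray  # (n_sources, 3) float, millimetres
    spacing: float = 5.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array of mm coordinates")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if len(np.unique(pos.round(9), axis=0)) != len(pos):
            raise ValueError("grid positions must be unique")
        # regularity: every coordinate is an integer multiple of the spacing
        # (up to a common offset)
        rel = (pos - pos[0]) / self.spacing
        if not np.allclose(rel, np.round(rel), atol=1e-6):
            raise ValueError("positions do not lie on a regular lattice of the stated spacing")
        object.__setattr__(self, "positions", pos)

    @property
    def n_sources(self) -> int:
        return len(self.positions)

    def nearest(self, position_mm) -> tuple[int, float]:
        """Index of the grid point nearest ``position_mm`` and its distance."""
        d = np.linalg.norm(self.positions - np.asarray(position_mm, float), axis=1)
        i = int(np.argmin(d))
        return i, float(d[i])

    @classmethod
    def regular(cls, shape=(5, 5, 5), spacing: float = 5.0, origin=(0.0, 0.0, 0.0)) -> "SourceGrid":
        """A full rectangular lattice of ``shape`` points."""
        ax = [origin[i] + spacing * np.arange(shape[i]) for i in range(3)]
        pos = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
        return cls(pos, spacing)

    @classmethod
    def hemisphere_shell(cls, sphere_radius: float = 85.0, spacing: float = 5.0,
                         r_min_frac: float = 0.45, r_max_frac: float = 0.85,
                         z_min: float = 0.0) -> "SourceGrid":
        """Lattice points in an upper-hemisphere shell of a sphere (a crude
        cortex stand-in for localization tests)."""
        r_max = r_max_frac * sphere_radius
        n = int(np.floor(r_max / spacing))
        ax = spacing * np.arange(-n, n + 1)
        pos = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
        r = np.linalg.norm(pos, axis=1)
        keep = (r >= r_min_frac * sphere_radius) & (r <= r_max) & (pos[:, 2] >= z_min)
        return cls(pos[keep], spacing)


@dataclass(frozen=True)
class LeadField:
    """Channels x sources gain matrix (fixed orientation) or
    channels x sources x 3 (free orientation)."""

    gains: np.ndarray
    grid: SourceGrid
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        g = np.asarray(self.gains, dtype=float)
        if g.ndim not in (2, 3):
            raise ValueError("gains must be 2-D (fixed orientation) or 3-D (free orientation)")
        if g.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if g.shape[1] != self.grid.n_sources:
            raise ValueError("gain matrix source count does not match the grid")
        if not np.all(np.isfinite(g)):
            raise ValueError("lead field contains non-finite entries")
        if np.any(np.linalg.norm(g.reshape(g.shape[0], g.shape[1], -1), axis=(0, 2)) == 0):
            raise ValueError("lead field has an all-zero source column")
        if len(self.channel_labels) != g.shape[0]:
            raise ValueError("channel_labels length does not match gains")
        object.__setattr__(self, "gains", g)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_channels(self) -> int:
        return self.gains.shape[0]

    @property
    def is_free_orientation(self) -> bool:
        return self.gains.ndim == 3

    def column(self, source_index: int) -> np.ndarray:
        """Fixed-orientation gain vector for one source."""
        if self.is_free_orientation:
            raise ValueError("free-orientation lead field: resolve orientation first")
        return self.gains[:, source_index]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic recording.

    ``delay`` is in milliseconds and signed: positive means the cortical
    source leads the muscle (the physiological descending direction).
    SNRs are 10*log10(signal variance / noise variance) per channel;
    ``None`` disables the corresponding noise entirely.
    """

    fs: float = 256.0
    duration: float = 120.0
    coupling_band: tuple[float, float] = (15.0, 30.0)
    delay: float = 25.0
    coupling_gain: float = 0.5
    source_index: int = 0
    sensor_snr: float | None = 5.0
    emg_noise_snr: float | None = 5.0
    seed: int = 0
    emg_model: Literal["additive", "modulated"] = "additive"

    def __post_init__(self) -> None:
        lo, hi = self.coupling_band
        if not (0 < lo < hi):
            raise ValueError("coupling_band must satisfy 0 < lo < hi")
        if self.fs <= 2 * hi:
            raise ValueError("fs must exceed twice the upper coupling-band edge")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9 or n < self.fs:
            raise ValueError("duration*fs must be an integer number of samples >= fs")
        if not (0.0 <= self.coupling_gain <= 1.0):
            raise ValueError("coupling_gain must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def delay_samples(self) -> int:
        return int(round(self.delay * self.fs / 1000.0))


@dataclass(frozen=True)
class SimulatedDataset:
    """EEG + EMG record with the noise-free source kept as ground truth."""

    eeg: np.ndarray          # (n_channels, n_samples)
    emg: np.ndarray          # (n_samples,)
    source: np.ndarray       # (n_samples,) noise-free cortical series
    config: SimulationConfig
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.eeg.shape[1] != self.emg.shape[0] or self.source.shape[0] != self.emg.shape[0]:
            raise ValueError("sample counts differ between eeg, emg and source")


@dataclass(frozen=True)
class ForceTrace:
    """Produced force during the tracing task, in consistent force units."""

    samples: np.ndarray
    fs: float
    target: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.target <= 0:
            raise ValueError("target force must be positive")


# ---------------------------------------------------------------------------
# lead fields


def _fibonacci_hemisphere(n: int, radius: float) -> np.ndarray:
    """n roughly uniform points on the upper half of a sphere surface."""
    i = np.arange(n)
    golden = (1 + 5 ** 0.5) / 2
    z = (i + 0.5) / n              # (0, 1): upper hemisphere only
    theta = 2 * np.pi * i / golden
    r_xy = np.sqrt(1 - z ** 2)
    pts = np.stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z], axis=1)
    return radius * pts


def _sphere_radial_leadfield(channels: np.ndarray, sources: np.ndarray,
                             radius: float, sigma: float = 1.0,
                             n_terms: int = 120) -> np.ndarray:
    """Surface potential of unit radial current dipoles in a homogeneous
    conducting sphere (Legendre series solution).

    For a radial dipole at eccentricity b = |r0| the potential at a surface
    point with angle gamma from the dipole axis is

        V = 1/(4 pi sigma R^2) * sum_{n>=1} (2n+1) (b/R)^(n-1) P_n(cos gamma)
    """
    b = np.linalg.norm(sources, axis=1)
    if np.any(b >= radius):
        raise ValueError("source grid extends outside the sphere head model")
    if np.any(b < 1e-9):
        raise ValueError(
            "degenerate geometry: source at the sphere centre has no defined "
            "radial orientation; remove the centre point from the grid"
        )
    cosg = (channels @ sources.T) / (radius * b[None, :])
    cosg = np.clip(cosg, -1.0, 1.0)
    f = b / radius                                   # (n_src,)
    out = np.zeros_like(cosg)
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) * f[None, :] ** (n - 1) * eval_legendre(n, cosg)
    return out / (4 * np.pi * sigma * radius ** 2)


def make_lead_field(n_channels: int, grid: SourceGrid,
                    mode: Literal["random_wellconditioned", "single_sphere_analytic"] = "random_wellconditioned",
                    seed: int = 0, sphere_radius: float | None = None,
                    max_condition: float = 1e3) -> LeadField:
    """Build a fixed-orientation lead field over ``grid``.

    ``random_wellconditioned`` draws a Gaussian gain matrix and redraws until
    its condition number is at most ``max_condition`` -- a geometry-free stand
    in used where only the algebra is under test.  ``single_sphere_analytic``
    places ``n_channels`` electrodes on the upper surface of a homogeneous
    conducting sphere and evaluates the closed-form potential of radial
    dipoles at the grid points.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    labels = tuple(f"EEG{i:03d}" for i in range(n_channels))
    if mode == "random_wellconditioned":
        rng = np.random.default_rng(seed)
        for _ in range(100):
            g = rng.standard_normal((n_channels, grid.n_sources))
            if np.linalg.cond(g) <= max_condition:
                return LeadField(g, grid, labels)
        raise RuntimeError("could not draw a well-conditioned gain matrix in 100 tries")
    if mode == "single_sphere_analytic":
        if sphere_radius is None:
            sphere_radius = 1.25 * float(np.max(np.linalg.norm(grid.positions, axis=1)))
        chans = _fibonacci_hemisphere(n_channels, sphere_radius)
        g = _sphere_radial_leadfield(chans, grid.positions, sphere_radius)
        if np.linalg.matrix_rank(g, tol=1e-12) < 2:
            raise ValueError("degenerate geometry: lead field columns are collinear")
        return LeadField(g, grid, labels)
    raise ValueError(f"unknown lead field mode {mode!r}")


# ---------------------------------------------------------------------------
# signal generation


def _band_limited_noise(n_samples: int, fs: float, band: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (zero phase)."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return x / x.std()


def _noise_at_snr(reference: np.ndarray, snr_db: float | None,
                  rng: np.random.Generator, shape=None) -> np.ndarray:
    """White Gaussian noise whose variance realizes ``snr_db`` against
    ``reference`` (per channel when reference is 2-D)."""
    shape = reference.shape if shape is None else shape
    if snr_db is None:
        return np.zeros(shape)
    sig_var = np.var(reference, axis=-1, keepdims=True)
    noise_var = sig_var / 10.0 ** (snr_db / 10.0)
    return np.sqrt(noise_var) * rng.standard_normal(shape)


def simulate_dataset(leadfield: LeadField, config: SimulationConfig) -> SimulatedDataset:
    """Simulate a scalp EEG + EMG recording with known coupling.

    The cortical source is band-limited Gaussian noise in
    ``config.coupling_band``; EEG is the lead-field projection of that source
    plus independent per-channel sensor noise; EMG is ``coupling_gain`` times
    the source delayed by ``config.delay`` plus independent broadband noise
    (additive model), or a broadband carrier amplitude-modulated by the
    delayed drive (modulated model).  A single seeded generator drives all
    randomness, so the dataset is bit-reproducible from the config.
    """
    if leadfield.is_free_orientation:
        raise ValueError("simulate_dataset requires a fixed-orientation lead field")
    if not 0 <= config.source_index < leadfield.grid.n_sources:
        raise IndexError("source_index outside the grid")
    d = config.delay_samples
    if abs(d) >= config.fs:  # one 1-s analysis segment
        raise ValueError("|delay| must be shorter than a 1-s segment for directionality to be detectable")

    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    pad = abs(d)
    long_src = _band_limited_noise(n + 2 * pad, config.fs, config.coupling_band, rng)
    source = long_src[pad:pad + n]
    # positive delay: muscle receives the source d samples later, i.e. the EMG
    # window is the source window shifted back in time by d
    drive = long_src[pad - d:pad - d + n]

    gains = leadfield.column(config.source_index)
    eeg_clean = gains[:, None] * source[None, :]
    eeg = eeg_clean + _noise_at_snr(eeg_clean, config.sensor_snr, rng)

    # EMG noise floor is fixed relative to the unit-variance source drive (not
    # to the coupled term), so raising coupling_gain genuinely raises the
    # EMG's coupled fraction and hence the measurable coherence
    coupled = config.coupling_gain * drive
    if config.emg_model == "additive":
        emg = coupled + _noise_at_snr(drive, config.emg_noise_snr, rng, shape=(n,))
    elif config.emg_model == "modulated":
        carrier = rng.standard_normal(n)
        emg = carrier * (1.0 + coupled)
        emg = emg + _noise_at_snr(emg, config.emg_noise_snr, rng, shape=(n,))
    else:
        raise ValueError(f"unknown emg_model {config.emg_model!r}")

    return SimulatedDataset(eeg=eeg, emg=emg, source=source, config=config,
                            channel_labels=leadfield.channel_labels)


def simulate_force_trace(mvc: float, target_fraction: float = 0.1,
                         noise_sd_fraction: float = 0.01, duration: float = 120.0,
                         fs: float = 1000.0, seed: int = 0) -> ForceTrace:
    """Force produced while tracking a constant target line.

    The trace is the target level (``target_fraction * mvc``) plus slow
    Gaussian drift: white noise low-pass filtered at 10 Hz and scaled to a
    standard deviation of ``noise_sd_fraction * mvc`` -- matching a force
    channel hardware-filtered at 10 Hz and digitized at 1000 Hz.
    """
    if mvc <= 0:
        raise ValueError("mvc must be positive")
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must lie in (0, 1)")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * fs))
    target = target_fraction * mvc
    if noise_sd_fraction == 0:
        return ForceTrace(np.full(n, target), fs, target)
    rng = np.random.default_rng(seed)
    sos = signal.butter(4, 10.0, btype="lowpass", fs=fs, output="sos")
    drift = signal.sosfiltfilt(sos, rng.standard_normal(n))
    drift *= noise_sd_fraction * mvc / drift.std()
    return ForceTrace(target + drift, fs, target)


# ---------------------------------------------------------------------------
# serialization


def save_dataset(dataset: SimulatedDataset, path_prefix: str) -> None:
    """Write a dataset as delimited text (one column per channel) with the
    ground truth serialized as JSON alongside."""
    cols = np.column_stack([dataset.eeg.T, dataset.emg, dataset.source])
    header = "\t".join(list(dataset.channel_labels) + ["EMG", "SOURCE"])
    np.savetxt(path_prefix + ".tsv", cols, delimiter="\t", header=header, fmt="%.10e")
    truth = asdict(dataset.config)
    truth["channel_labels"] = list(dataset.channel_labels)
    with open(path_prefix + ".json", "w") as fh:
        json.dump(truth, fh, indent=1)


def save_dataset_h5(dataset: SimulatedDataset, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("eeg", data=dataset.eeg)
        fh.create_dataset("emg", data=dataset.emg)
        fh.create_dataset("source", data=dataset.source)
        fh.attrs["config"] = json.dumps(asdict(dataset.config))
        fh.attrs["channel_labels"] = json.dumps(list(dataset.channel_labels))


def load_dataset_h5(path: str) -> SimulatedDataset:
    import h5py

    with h5py.File(path, "r") as fh:
        cfg = SimulationConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in json.loads(fh.attrs["config"]).items()})
        return SimulatedDataset(eeg=fh["eeg"][()], emg=fh["emg"][()],
                                source=fh["source"][()], config=cfg,
                                channel_labels=tuple(json.loads(fh.attrs["channel_labels"])))
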