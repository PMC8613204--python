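"""Per-subject analysis chain and group-level aggregation.

``run_subject`` composes the full analysis on one (synthetic) subject:
simulate -> condition/segment -> (optionally DICS scan + LCMV virtual
electrode) -> coherence + beta-band summary -> directional decomposition ->
force metrics.  Results are deterministic given the config and seed;
``run_group`` aggregates subject rows into group x hand means, SDs and the
proportion of subjects with significant beta-band coherence.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .synthetic import (SimulationConfig, make_lead_field, simulate_dataset,
                        simulate_force_trace, SourceGrid, LeadField)
from .preprocess import (Recording, condition_eeg, condition_emg,
                         epoch_and_normalize, segment_record)
from .spectra import (estimate_spectra, coherence, band_summary, correct_alpha,
                      spectra_table, average_coherence, BETA_BAND, N_BETA_COMPARISONS)
from .directionality import prewhiten_and_correlate, decompose_directions
from .beamform import csd_matrix, dics_scan, band_covariance, lcmv_virtual_electrode
from .metrics import performance_metrics

log = logging.getLogger("cmc.pipeline")


@dataclass(frozen=True)
class SubjectConfig:
    subject_id: str
    hand: str = "dominant"                  # dominant | non_dominant
    group: str = "adults"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    band: tuple[float, float] = BETA_BAND
    alpha: float = 0.05
    n_comparisons: int = N_BETA_COMPARISONS
    use_beamform: bool = False
    n_channels: int = 16
    leadfield_mode: str = "random_wellconditioned"
    reg_fraction: float = 0.05
    eeg_channel: int | None = None          # sensor-level analysis channel
    force_noise_sd_fraction: float = 0.02
    mvc: float = 100.0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not lo < hi:
            raise ValueError("band lo must be below hi")
        if self.hand not in ("dominant", "non_dominant"):
            raise ValueError("hand must be 'dominant' or 'non_dominant'")

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class SubjectResult:
    subject_id: str
    hand: str
    group: str
    beta_area: float
    beta_peak_value: float
    beta_peak_freq: float
    confidence_limit: float
    significant: bool
    descending_magnitude: float
    ascending_magnitude: float
    zero_magnitude: float
    dics_peak_position: tuple[float, float, float] | None
    dics_peak_value: float | None
    mvc: float
    precision: float
    variability: float
    coherence_spectrum: object = field(repr=False, default=None)
    provenance: dict = field(default_factory=dict, repr=False)

    def row(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "subject_id", "hand", "group", "beta_area", "beta_peak_value",
            "beta_peak_freq", "confidence_limit", "significant",
            "descending_magnitude", "ascending_magnitude", "zero_magnitude",
            "dics_peak_value", "mvc", "precision", "variability")}
        for f in ("beta_area", "beta_peak_value", "beta_peak_freq", "confidence_limit",
                  "descending_magnitude", "ascending_magnitude", "zero_magnitude",
                  "mvc", "precision", "variability"):
            if not np.isfinite(d[f]):
                raise ValueError(f"non-finite result field {f}")
        return d


def _build_leadfield(cfg: SubjectConfig) -> LeadField:
    if cfg.leadfield_mode == "single_sphere_analytic":
        grid = SourceGrid.hemisphere_shell(spacing=5.0)
    else:
        grid = SourceGrid.regular((4, 4, 4), spacing=5.0)
    return make_lead_field(cfg.n_channels, grid, mode=cfg.leadfield_mode, seed=cfg.seed + 1)


def run_subject(cfg: SubjectConfig, out_dir: str | Path | None = None,
                leadfield: LeadField | None = None) -> SubjectResult:
    """Run the full per-subject chain; optionally write artifacts + manifest.

    Stage errors propagate after being logged with the stage name.
    """
    stage = "setup"
    try:
        if leadfield is None:
            leadfield = _build_leadfield(cfg)
        sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        if sim.source_index >= leadfield.grid.n_sources:
            sim = dataclasses.replace(sim, source_index=leadfield.grid.n_sources // 2)

        stage = "simulate"
        ds = simulate_dataset(leadfield, sim)

        stage = "preprocess"
        eeg_rec = condition_eeg(Recording(ds.eeg, sim.fs, ds.channel_labels))
        emg_rec = condition_emg(Recording(ds.emg[None, :], sim.fs, ("EMG",), ("emg",)),
                                rectify=False)
        eeg_seg = epoch_and_normalize(eeg_rec)
        emg_seg = epoch_and_normalize(emg_rec)
        emg_segments = emg_seg.segments[0]

        dics_peak_position = dics_peak_value = None
        if cfg.use_beamform:
            stage = "dics"
            # unnormalized segments: the CSD must keep relative channel gains
            eeg_raw_seg = segment_record(eeg_rec)
            csd = csd_matrix(eeg_raw_seg.segments, emg_segments, eeg_seg.fs, cfg.band)
            dmap = dics_scan(csd, leadfield, cfg.reg_fraction)
            k = int(np.argmax(dmap.values))
            dics_peak_position = tuple(float(v) for v in leadfield.grid.positions[k])
            dics_peak_value = float(dmap.values[k])

            stage = "virtual_electrode"
            cov = band_covariance(eeg_rec.data, eeg_rec.fs, cfg.band)
            ve = lcmv_virtual_electrode(eeg_rec.data, cov, leadfield,
                                        leadfield.grid.positions[k], cfg.reg_fraction)
            cortical_rec = Recording(ve.timeseries[None, :], eeg_rec.fs, ("VE",))
            cortical_segments = epoch_and_normalize(cortical_rec).segments[0]
        else:
            ch = cfg.eeg_channel
            if ch is None:  # channel with the strongest projection of the source
                ch = int(np.argmax(np.abs(leadfield.column(sim.source_index))))
            cortical_segments = eeg_seg.segments[ch]

        stage = "spectra"
        sp = estimate_spectra(cortical_segments, emg_segments, eeg_seg.fs)
        coh = coherence(sp)
        summary = band_summary(coh, cfg.band, correct_alpha(cfg.alpha, cfg.n_comparisons))

        stage = "directionality"
        wh, lc = prewhiten_and_correlate(sp)
        decomp = decompose_directions(wh, lc, cfg.band, x_is_cortex=True)

        stage = "metrics"
        force = simulate_force_trace(cfg.mvc, 0.1, cfg.force_noise_sd_fraction,
                                     duration=sim.duration, seed=cfg.seed + 2)
        perf = performance_metrics(force)

        result = SubjectResult(
            subject_id=cfg.subject_id, hand=cfg.hand, group=cfg.group,
            beta_area=summary.area, beta_peak_value=summary.peak_value,
            beta_peak_freq=summary.peak_freq, confidence_limit=summary.confidence_limit,
            significant=summary.significant,
            descending_magnitude=decomp.descending_magnitude,
            ascending_magnitude=decomp.ascending_magnitude,
            zero_magnitude=decomp.zero_magnitude,
            dics_peak_position=dics_peak_position, dics_peak_value=dics_peak_value,
            mvc=cfg.mvc, precision=perf.precision, variability=perf.variability,
            coherence_spectrum=coh,
            provenance={"config_hash": cfg.content_hash(), "version": __version__,
                        "seed": cfg.seed},
        )
        if out_dir is not None:
            _write_artifacts(Path(out_dir), cfg, sp, result)
        return result
    except Exception:
        log.error("subject %s failed at stage %s", cfg.subject_id, stage)
        raise


def _write_artifacts(out: Path, cfg: SubjectConfig, sp, result: SubjectResult) -> None:
    sub = out / cfg.subject_id / cfg.hand
    sub.mkdir(parents=True, exist_ok=True)
    tab = spectra_table(sp)
    tab.to_csv(sub / "spectra.tsv", sep="\t", index=False, float_format="%.10e")
    with open(sub / "result.json", "w") as fh:
        row = result.row()
        row["provenance"] = result.provenance
        json.dump(row, fh, indent=1, default=lambda o: float(o) if isinstance(o, np.floating) else bool(o))
    manifest = {"files": ["spectra.tsv", "result.json"],
                "config_hash": cfg.content_hash(), "version": __version__}
    with open(sub / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    for p in ("spectra.tsv", "result.json"):
        log.info("subject=%s stage=write file=%s sha256=%s", cfg.subject_id, p,
                 hashlib.sha256((sub / p).read_bytes()).hexdigest()[:12])


@dataclass(frozen=True)
class GroupTable:
    subjects: pd.DataFrame               # one row per subject x hand
    groups: pd.DataFrame                 # group x hand means/SDs + prop. significant
    mean_spectra: dict                   # (group, hand) -> CoherenceSpectrum


def run_group(configs: list[SubjectConfig], out_dir: str | Path | None = None,
              leadfield: LeadField | None = None) -> GroupTable:
    """Process a cohort and aggregate per group x hand."""
    if not configs:
        raise ValueError("need at least one subject")
    ids = [(c.subject_id, c.hand) for c in configs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id x hand entries in the cohort")
    results = [run_subject(c, out_dir=out_dir, leadfield=leadfield) for c in configs]
    subjects = pd.DataFrame([r.row() for r in results])
    agg = subjects.groupby(["group", "hand"]).agg(
        n=("subject_id", "size"),
        beta_area_mean=("beta_area", "mean"), beta_area_sd=("beta_area", "std"),
        beta_peak_mean=("beta_peak_value", "mean"),
        descending_mean=("descending_magnitude", "mean"),
        descending_sd=("descending_magnitude", "std"),
        ascending_mean=("ascending_magnitude", "mean"),
        ascending_sd=("ascending_magnitude", "std"),
        prop_significant=("significant", "mean"),
        precision_mean=("precision", "mean"),
        variability_mean=("variability", "mean"),
    ).reset_index()
    mean_spectra = {}
    for (g, h), grp in subjects.groupby(["group", "hand"]):
        sel = [r.coherence_spectrum for r in results if r.group == g and r.hand == h]
        mean_spectra[(g, h)] = average_coherence(sel)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        subjects.to_csv(Path(out_dir) / "subjects.tsv", sep="\t", index=False,
                        float_format="%.10e")
    return GroupTable(subjects=subjects, groups=agg, mean_spectra=mean_spectra)


def load_cohort(path: str | Path) -> list[SubjectConfig]:
    """Read a YAML cohort file: top-level ``defaults`` block plus a
    ``subjects`` list of per-subject overrides; ``simulation`` sub-blocks map
    onto SimulationConfig."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    defaults = doc.get("defaults", {})
    configs = []
    for entry in doc["subjects"]:
        merged = {**defaults, **entry}
        sim_kwargs = {**defaults.get("simulation", {}), **entry.get("simulation", {})}
        if "coupling_band" in sim_kwargs:
            sim_kwargs["coupling_band"] = tuple(sim_kwargs["coupling_band"])
        merged.pop("simulation", None)
        if "band" in merged:
            merged["band"] = tuple(merged["band"])
        configs.append(SubjectConfig(simulation=SimulationConfig(**sim_kwargs), **merged))
    return configs
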