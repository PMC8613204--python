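import numpy as np
import pytest

from cmc.synthetic import (SourceGrid, make_lead_field, simulate_dataset,
                           SimulationConfig)
from cmc.preprocess import Recording, epoch_and_normalize, segment_record


@pytest.fixture(scope="session")
def small_grid():
    return SourceGrid.regular((3, 3, 3), spacing=5.0)


@pytest.fixture(scope="session")
def random_leadfield(small_grid):
    return make_lead_field(8, small_grid, "random_wellconditioned", seed=1)


@pytest.fixture(scope="session")
def sphere_grid():
    """Upper-hemisphere shell, ~900 points at 5-mm spacing."""
    return SourceGrid.hemisphere_shell(sphere_radius=85.0, spacing=5.0,
                                       r_min_frac=0.55, r_max_frac=0.8, z_min=45.0)


@pytest.fixture(scope="session")
def sphere_leadfield(sphere_grid):
    return make_lead_field(64, sphere_grid, "single_sphere_analytic",
                           sphere_radius=85.0)


@pytest.fixture(scope="session")
def coupled_dataset(random_leadfield):
    """120 s of cortex-leads data: gain 0.5, +25 ms delay, moderate noise."""
    cfg = SimulationConfig(duration=120.0, delay=25.0, coupling_gain=0.5,
                           source_index=13, seed=3)
    return simulate_dataset(random_leadfield, cfg)


def best_channel(leadfield, source_index):
    return int(np.argmax(np.abs(leadfield.column(source_index))))


@pytest.fixture(scope="session")
def coupled_segments(coupled_dataset, random_leadfield):
    """(cortical channel segments, EMG segments) of the coupled dataset."""
    ds = coupled_dataset
    eeg = epoch_and_normalize(Recording(ds.eeg, ds.config.fs, ds.channel_labels))
    emg = epoch_and_normalize(Recording(ds.emg[None, :], ds.config.fs, ("EMG",)))
    ch = best_channel(random_leadfield, ds.config.source_index)
    return eeg.segments[ch], emg.segments[0]
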