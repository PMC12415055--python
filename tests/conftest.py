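import numpy as np
import pytest

from culture_mmr import (
    CultureParams,
    ElectrodeGrid,
    build_raster,
    make_msc,
    make_oddball,
    simulate_spikes,
)


@pytest.fixture(scope="session")
def grid():
    return ElectrodeGrid()


@pytest.fixture(scope="session")
def small_grid():
    return ElectrodeGrid(n_cols=40, n_rows=30, pitch_um=17.5)


@pytest.fixture(scope="session")
def stim_sites(grid):
    return ((110, 60), (113, 60))


@pytest.fixture(scope="session")
def channels():
    # a compact strip of channels around the stimulation block
    return [(100 + 2 * i, 55) for i in range(12)]


@pytest.fixture(scope="session")
def oddball_seq(stim_sites):
    return make_oddball(stim_sites, n_events=600, p_deviant=0.1, isi_s=0.5, seed=1)


@pytest.fixture(scope="session")
def msc_sites(grid):
    return [(104 + 3 * i, 62) for i in range(10)]


@pytest.fixture(scope="session")
def simulated_oddball(grid, oddball_seq, channels):
    """One simulated oddball culture plus its raster (shared, read-only)."""
    params = CultureParams(seed=11)
    spikes = simulate_spikes(grid, oddball_seq, params, channels)
    raster = build_raster(spikes, oddball_seq, channels=channels)
    return spikes, raster
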