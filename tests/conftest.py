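"""Shared fixtures: synthetic sessions analyzed once per test run."""

import numpy as np
import pytest

import sepmap.preprocessing as pp
import sepmap.synthetic as syn
import sepmap.topography as topo
from sepmap.geometry import GridGeometry, ProbeGeometry

SIM_FS = 4000.0  # Hz; simulate above 2 kHz so the downsampling path is real


@pytest.fixture(scope="session")
def grid():
    return GridGeometry()


@pytest.fixture(scope="session")
def probe():
    return ProbeGeometry()


def analyze_grid_scenario(cfg, geometry, step=10.0):
    """simulate → preprocess → peaks → maps, returning everything."""
    rec = syn.simulate_grid_session(cfg, geometry, SIM_FS)
    avg = pp.preprocess(rec)
    peaks = topo.find_component_peaks(avg)
    out = {"recording": rec, "avg": avg, "peaks": peaks,
           "locations": {}, "regions": {}}
    for label in ("P", "N"):
        if peaks[label]:
            _, loc, region = topo.analyze_component(avg, peaks[label],
                                                    step=step)
            out["locations"][label] = loc
            out["regions"][label] = region
    return out


@pytest.fixture(scope="session")
def bc_analysis(grid):
    """Noise-free default BC scenario run through the full pipeline."""
    cfg = syn.bc_scenario(seed=11, n_trials=6, noise_free=True)
    return analyze_grid_scenario(cfg, grid)


@pytest.fixture(scope="session")
def asw_analysis(grid):
    cfg = syn.asw_scenario(seed=12, n_trials=6, noise_free=True)
    return analyze_grid_scenario(cfg, grid)


@pytest.fixture(scope="session")
def laminar_session(probe):
    cfg = syn.ScenarioConfig(components=(), n_trials=10, noise_sd=5.0,
                             rng_seed=13, laminar=syn.LaminarSpec())
    return syn.simulate_laminar_session(cfg, probe, 20000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
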