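import numpy as np
import pytest

import bundlescan as bs


@pytest.fixture(scope="session")
def small_array():
    return bs.make_array(8, 8, 60.0)


@pytest.fixture(scope="session")
def clean_sim():
    """Small effectively-noiseless simulated scan (evoked component only)."""
    return bs.SimulatedScan(bs.SimulationConfig.clean(seed=11))


@pytest.fixture(scope="session")
def fixture_sim():
    """Small moderate-noise simulated scan (all four signal components)."""
    return bs.SimulatedScan(bs.SimulationConfig.fixture(seed=11))


@pytest.fixture(scope="session")
def fixture_scan(fixture_sim):
    """The moderate fixture materialized as an in-memory ScanRecording."""
    scan, _ = bs.simulate_scan(fixture_sim.config)
    return scan


@pytest.fixture(scope="session")
def fixture_detection(fixture_scan):
    return bs.run_detection(fixture_scan)


@pytest.fixture(scope="session")
def tiny_scan():
    """Minimal 2x2 scan for I/O round-trip tests."""
    rng = np.random.default_rng(0)
    array = bs.make_array(2, 2, 60.0)
    grid = bs.AmplitudeGrid.geometric(n_levels=4)
    v = rng.normal(0, 5, size=(4, 4, 3, 4, 45)).astype(np.float32)
    return bs.ScanRecording(
        voltages=v, sampling_rate=20000.0, amplitude_grid=grid, array=array
    )
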