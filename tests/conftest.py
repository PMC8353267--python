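import numpy as np
import pytest

from srmkit.defaults import default_panel
from srmkit.quant import filter_peak_groups
from srmkit.simulate import SimulationConfig, generate_timecourse


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def sim_data():
    """One default-condition synthetic time-course (report, Ct, truth)."""
    return generate_timecourse(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def retained(sim_data):
    report, _, _ = sim_data
    kept, _ = filter_peak_groups(report)
    return kept


@pytest.fixture()
def rng():
    return np.random.default_rng(20210806)
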