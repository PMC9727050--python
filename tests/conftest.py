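import numpy as np
import pytest

try:
    from hypothesis import settings
    settings.register_profile("suite", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("suite")
except ImportError:
    pass

from tvdlnm import (RunConfig, ScenarioTruth, assemble_design, fit_tv_model,
                    simulate_city)


@pytest.fixture(scope="session")
def small_sim():
    """3-year mid-sized city with drifting MMT; shared across test modules."""
    truth = ScenarioTruth(deaths_per_day=200, mmt_drift=0.1)
    series, truth_mmt, truth_crr = simulate_city(truth, 3, seed=42)
    return truth, series, truth_mmt, truth_crr


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """Fitted tv-DLNM on the shared small city."""
    _, series, _, _ = small_sim
    config = RunConfig(seed=7, n_boot=150)
    design = assemble_design(series, "all", config)
    fit = fit_tv_model(design)
    return design, fit


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
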