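import numpy as np
import pytest

from cellhealth import build_dose_series
from cellhealth.classifier import EndpointFingerprinter
from cellhealth.simulate import SimulationConfig, simulate_training_library


@pytest.fixture(scope="session")
def series10():
    return build_dose_series(100.0, 10, 3.0)


@pytest.fixture()
def small_config():
    """Reduced event count keeps event-level tests quick."""
    return SimulationConfig(seed=2024, n_events_per_well=2000)


@pytest.fixture(scope="session")
def library_small():
    """A 120-compound strongly separated synthetic library."""
    return simulate_training_library(60, 60, config=SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def fingerprint_model(library_small):
    """Fingerprint (CHI + 8 endpoint sub-models) trained once per session."""
    return EndpointFingerprinter(cv=(5, 3), seed=7).fit(library_small)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
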