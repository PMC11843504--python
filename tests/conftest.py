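import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from cimpass import CompoundRef, sample_compounds, simulate_series


@pytest.fixture(scope="session")
def noiseless_sim():
    """Five lipid-like compounds simulated over the full schedule, no noise."""
    compounds = sample_compounds(5, seed=101)
    series, truth = simulate_series(compounds)
    refs = [CompoundRef(c.name, c.adduct, c.mz, class_tag=c.class_tag) for c in compounds]
    return compounds, series, truth, refs


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
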