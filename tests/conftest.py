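import numpy as np
import pytest

from featherpop.synthdata import SimulationConfig, simulate_feather_samples, \
    simulate_population


@pytest.fixture(scope="session")
def small_truth():
    """A small ground-truthed population with families."""
    cfg = SimulationConfig(seed=11, n_pairs_per_region=6, n_singles_per_region=15,
                           gosling_sample_fraction=1.0, brood_size_mean=2.5)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def small_samples(small_truth):
    return simulate_feather_samples(small_truth)


@pytest.fixture(scope="session")
def clean_truth():
    """Error-free study conditions: no ADO/FA/missing/null noise."""
    cfg = SimulationConfig(seed=7, n_pairs_per_region=4, n_singles_per_region=10,
                           ado_rate=0.0, fa_rate=0.0, missing_rate=0.0,
                           null_rate=0.0, sex_marker_missing_rate=0.0,
                           gosling_sample_fraction=1.0)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def clean_samples(clean_truth):
    return simulate_feather_samples(clean_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
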