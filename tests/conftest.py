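import numpy as np
import pytest

from dfcnet import AnalysisConfig, run_on_series
from dfcnet.synth import simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic cohort (21 subjects, 170 TRs, 17 nodes)."""
    return simulate_dataset(rng_seed=1)


@pytest.fixture(scope="session")
def default_result(default_dataset):
    """Full pipeline run on the default cohort (shared across tests)."""
    cfg = AnalysisConfig(master_seed=1)
    return run_on_series(default_dataset.subjects, default_dataset.group_labels, cfg)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A fast small cohort for smoke/determinism tests."""
    return simulate_dataset(
        n_group_a=3, n_group_b=3, n_timepoints=80, n_nodes=6, n_states=2,
        rng_seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
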