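import numpy as np
import pytest

from radioimpact import TrialDesignConfig, generate_dataset


@pytest.fixture(scope="session")
def trial_config():
    """Default emulated-trial design (7 pairs, 48 months, 6 categories)."""
    return TrialDesignConfig(seed=123)


@pytest.fixture(scope="session")
def trial_df(trial_config):
    """One synthetic trial dataset shared (read-only) across tests."""
    return generate_dataset(trial_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
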