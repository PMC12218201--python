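import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """One shared simulated study directory for recovery tests."""
    from sexstrata import SimConfig, simulate_study

    out = tmp_path_factory.mktemp("study")
    truth = simulate_study(SimConfig(seed=11), out)
    return out, truth
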