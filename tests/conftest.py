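import numpy as np
import pytest

from n2itomo import experiments


@pytest.fixture(scope="session")
def static_experiment():
    """Scaled static self-supervised run (the expensive system-level fixture)."""
    return experiments.run_static_experiment(seed=1)


@pytest.fixture(scope="session")
def inference_mode_comparison():
    """Ten small static runs comparing full vs split-average inference."""
    return experiments.compare_inference_modes(num_seeds=10, seed=1)


@pytest.fixture(scope="session")
def dynamic_experiment():
    return experiments.run_dynamic_experiment(seed=1)


@pytest.fixture(scope="session")
def multichannel_experiment():
    return experiments.run_multichannel_experiment(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
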