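import numpy as np
import pytest

from spinecreep import GeneratorConfig, HysteresisParams, build_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def base_params():
    """A representative flexion–extension loop."""
    return HysteresisParams(-6.5, 6.5, 1.3, -1.5, 1.1, 0.5, 1.3, -0.5, 1.1, 1.5)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small two-temperature dataset for pipeline/surrogate tests."""
    cycles = {"FE": 8, "LB": 8, "AR": 12}
    configs = [
        GeneratorConfig.for_temperature("BT", n_specimens=2, cycles_per_sequence=cycles, seed=7),
        GeneratorConfig.for_temperature("RT", n_specimens=2, cycles_per_sequence=cycles, seed=8),
    ]
    return build_dataset(configs, seed=7, n_train=40, n_validation=5)
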