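import numpy as np
import pytest

from ripplelabel.simulate import (
    CLASS1_SPEC,
    CLASS2_SPEC,
    SimConfig,
    generate_dataset,
    inject_label_noise,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def dataset_1k(sim_config):
    """Balanced two-class dataset, 1000 windows per class, clean labels."""
    return generate_dataset(1000, config=sim_config)


@pytest.fixture(scope="session")
def noisy_dataset_1k(dataset_1k):
    """The same dataset with 20% of each group's true classes swapped."""
    return inject_label_noise(dataset_1k, 0.2, np.random.default_rng(11))


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 windows per class for fast end-to-end plumbing tests."""
    return generate_dataset(60, config=SimConfig(seed=3))


@pytest.fixture(scope="session")
def class_specs():
    return CLASS1_SPEC, CLASS2_SPEC
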