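import numpy as np
import pytest

from migcn.synth import SynthSpec, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small, fast synthetic dataset: 8 channels, 10 trials/class."""
    spec = SynthSpec(
        n_channels=8,
        n_trials_per_class=10,
        bands={"L": (8, 12), "R": (14, 18), "B": (20, 24), "F": (26, 30)},
        seed=3,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_spec():
    return SynthSpec(n_channels=8, n_trials_per_class=4, seed=5)
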